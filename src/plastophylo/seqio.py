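"""Sequence I/O and small sequence utilities.

Readers/writers for FASTA, 4-line FASTQ, GenBank flat files and a
minimal JSON annotation dialect, plus CDS peptide extraction, GC
content, FASTQ subsetting and FASTQ statistics.

Coordinates are 0-based half-open internally; anything printed for a
user is 1-based inclusive.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio import SeqIO as _BioSeqIO

from plastophylo.errors import FormatError

DEFAULT_CODON_TABLE = 11  # bacterial/plastid
DEFAULT_SPECIES_REGEX = r"^(?P<species>[^@]+)@"

_IUPAC_NT = set("ACGTURYSWKMBDHVN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeqRecord:
    """A single sequence tagged with species and molecule type."""

    id: str
    seq: str
    species: str = ""
    moltype: str = "aa"  # {"nt", "aa"}

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())
        if self.moltype == "nt":
            bad = set(self.seq) - _IUPAC_NT
            if bad:
                raise ValueError(
                    f"non-IUPAC nucleotide codes in {self.id!r}: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CdsFeature:
    """One CDS feature: a gene name plus ordered genomic intervals."""

    gene: str
    intervals: list[tuple[int, int]]  # 0-based half-open, in join order
    strand: str  # "+" or "-"
    codon_table: int = DEFAULT_CODON_TABLE

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.intervals:
            if start < 0 or end <= start:
                raise ValueError(f"bad interval ({start}, {end}) in {self.gene}")

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.intervals)


@dataclass
class AnnotationRecord:
    """A genome sequence with its CDS features."""

    seq: str
    features: list[CdsFeature] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        for feat in self.features:
            for start, end in feat.intervals:
                if end > len(self.seq):
                    raise ValueError(
                        f"interval ({start}, {end}) of {feat.gene} exceeds "
                        f"sequence length {len(self.seq)}"
                    )


@dataclass
class FastqStats:
    read_count: int
    total_bases: int

    @property
    def mean_length(self) -> float:
        if self.read_count == 0:
            raise ValueError("mean length undefined for an empty FASTQ")
        return self.total_bases / self.read_count

    def fraction_of(self, other: "FastqStats") -> float:
        if other.total_bases == 0:
            raise ValueError("fraction undefined against zero total bases")
        return self.total_bases / other.total_bases


@dataclass
class ExtractionReport:
    """Outcome of peptide extraction over one annotation record."""

    n_features: int = 0
    n_extracted: int = 0
    skipped: list[str] = field(default_factory=list)  # not divisible by 3
    frameshift_candidates: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_species(header: str, species_regex: str = DEFAULT_SPECIES_REGEX) -> str:
    """Extract the species tag from a FASTA id via a named-group regex."""
    m = re.match(species_regex, header)
    return m.group("species") if m else ""


def read_fasta(
    path: str | Path,
    moltype: str = "aa",
    species_regex: str = DEFAULT_SPECIES_REGEX,
) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords.

    Raises FormatError (naming the offending line) for records with an
    empty sequence or content before the first header.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush(lineno: int) -> None:
        nonlocal header
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(
                f"{path}: empty sequence for record {header!r} at line {header_line}"
            )
        records.append(
            SeqRecord(id=header, seq=seq, species=parse_species(header, species_regex),
                      moltype=moltype)
        )

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                chunks.append(line)
        _flush(lineno if records or header else 0)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotations: GenBank flat file and JSON dialect
# ---------------------------------------------------------------------------

def read_genbank(path: str | Path) -> AnnotationRecord:
    """Read the first record of a GenBank flat file into an AnnotationRecord."""
    record = next(_BioSeqIO.parse(str(path), "genbank"))
    features: list[CdsFeature] = []
    for feat in record.features:
        if feat.type != "CDS":
            continue
        gene = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
        strand = "-" if feat.location.strand == -1 else "+"
        parts = sorted(feat.location.parts, key=lambda p: int(p.start))
        if strand == "-":
            parts = parts[::-1]
        intervals = [(int(p.start), int(p.end)) for p in parts]
        table = int(feat.qualifiers.get("transl_table", [DEFAULT_CODON_TABLE])[0])
        features.append(CdsFeature(gene=gene, intervals=intervals, strand=strand,
                                   codon_table=table))
    return AnnotationRecord(seq=str(record.seq), features=features, name=record.id)


def read_gbson(path: str | Path) -> AnnotationRecord:
    """Read the minimal JSON annotation dialect.

    Schema (unknown keys ignored)::

        {
          "sequence": "ACGT...",
          "name": "contig1",
          "features": [
            {"gene": "psbA", "type": "CDS", "strand": "-",
             "location": [{"start": 1, "end": 1062}],   # 1-based inclusive
             "codon_table": 11}
          ]
        }
    """
    with open(path) as fh:
        doc = json.load(fh)
    if "sequence" not in doc:
        raise FormatError(f"{path}: missing 'sequence' key")
    features = []
    for feat in doc.get("features", []):
        if feat.get("type", "CDS") != "CDS":
            continue
        intervals = [(loc["start"] - 1, loc["end"]) for loc in feat["location"]]
        features.append(
            CdsFeature(
                gene=feat.get("gene", "?"),
                intervals=intervals,
                strand=feat.get("strand", "+"),
                codon_table=int(feat.get("codon_table", DEFAULT_CODON_TABLE)),
            )
        )
    return AnnotationRecord(seq=doc["sequence"], features=features,
                            name=doc.get("name", ""))


# ---------------------------------------------------------------------------
# peptide extraction
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def cds_nucleotides(record: AnnotationRecord, feature: CdsFeature) -> str:
    """Join a feature's intervals into its coding-strand nucleotide sequence.

    Minus-strand features have each interval reverse-complemented and the
    intervals are joined in the listed order.
    """
    parts = []
    for start, end in feature.intervals:
        chunk = record.seq[start:end]
        if feature.strand == "-":
            chunk = reverse_complement(chunk)
        parts.append(chunk)
    return "".join(parts)


def translate_cds(nt: str, table: int = DEFAULT_CODON_TABLE) -> tuple[str, bool]:
    """Translate a CDS, stopping at the first stop codon.

    Returns (peptide, had_internal_stop) where the trailing stop is never
    part of the peptide and had_internal_stop is True when a stop codon
    occurs before the final codon (a frameshift candidate signal).
    """
    if len(nt) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    full = str(Seq(nt).translate(table=table))
    stop_at = full.find("*")
    if stop_at == -1:
        return full, False
    return full[:stop_at], stop_at < len(full) - 1


def extract_peptides(
    record: AnnotationRecord,
    species: str = "",
) -> list[SeqRecord]:
    """Extract one peptide per CDS feature; see extract_peptides_report."""
    peptides, _ = extract_peptides_report(record, species=species)
    return peptides


def extract_peptides_report(
    record: AnnotationRecord,
    species: str = "",
) -> tuple[list[SeqRecord], ExtractionReport]:
    """Extract peptides and an extraction report.

    Features whose joined length is not divisible by 3 are skipped and
    reported; features with an internal stop codon are translated up to
    the stop and flagged as frameshift candidates for the polish module.
    """
    report = ExtractionReport(n_features=len(record.features))
    peptides: list[SeqRecord] = []
    for feat in record.features:
        nt = cds_nucleotides(record, feat)
        if len(nt) % 3 != 0:
            report.skipped.append(feat.gene)
            continue
        pep, internal_stop = translate_cds(nt, table=feat.codon_table)
        if internal_stop:
            report.frameshift_candidates.append(feat.gene)
        if pep:
            rec_id = f"{species}@{feat.gene}" if species else feat.gene
            peptides.append(SeqRecord(id=rec_id, seq=pep, species=species,
                                      moltype="aa"))
            report.n_extracted += 1
    return peptides, report


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """GC percentage over unambiguous bases only.

    100*(G+C)/(A+C+G+T); ambiguity codes count toward neither numerator
    nor denominator.
    """
    if not seq:
        raise ValueError("GC content undefined for an empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases in sequence")
    return 100.0 * gc / (gc + at)


def at_content(seq: str) -> float:
    return 100.0 - gc_content(seq)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str, str]]:
    """Yield (header, seq, plus, qual) raw line tuples from a 4-line FASTQ."""
    path = Path(path)
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            if header.strip() == "":
                continue
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FormatError(f"{path}: truncated FASTQ record {header.strip()!r}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise FormatError(f"{path}: malformed FASTQ record {header.strip()!r}")
            s, q = seq.rstrip("\n"), qual.rstrip("\n")
            if len(s) != len(q):
                raise FormatError(
                    f"{path}: sequence/quality length mismatch in {header.strip()!r}"
                )
            yield header.rstrip("\n"), s, plus.rstrip("\n"), q


def subset_fastq(
    reads_path: str | Path,
    id_list: Sequence[str],
    out_path: str | Path,
) -> tuple[int, int]:
    """Write the reads whose ids occur in ``id_list`` to ``out_path``.

    Reads keep input order and each is emitted at most once even when the
    id list contains duplicates; quality lines are preserved bit-exact.
    Returns (written, missed) where missed counts requested ids that were
    not found.
    """
    if not id_list:
        raise ValueError("id list must be non-empty")
    wanted = set(id_list)
    seen: set[str] = set()
    written = 0
    with open(out_path, "w") as out:
        for header, seq, plus, qual in _iter_fastq(reads_path):
            read_id = header[1:].split()[0]
            if read_id in wanted and read_id not in seen:
                out.write(f"{header}\n{seq}\n{plus}\n{qual}\n")
                seen.add(read_id)
                written += 1
    return written, len(wanted - seen)


def fastq_stats(reads_path: str | Path) -> FastqStats:
    """Exact read and base counts for a 4-line FASTQ file."""
    count = 0
    bases = 0
    for _header, seq, _plus, _qual in _iter_fastq(reads_path):
        count += 1
        bases += len(seq)
    return FastqStats(read_count=count, total_bases=bases)
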