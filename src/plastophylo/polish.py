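"""Homopolymer frameshift detection and read-support-gated correction.

A draft assembly is scanned for homopolymer runs; each run's length
distribution is read off spanning alignments in a SAM file, and the run
is corrected to the best-supported alternative length only when that
length is backed by at least ``min_reads`` reads making up more than
``min_fraction`` of the spanning coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio.Seq import Seq

MIN_READS_DEFAULT = 10
MIN_FRACTION_DEFAULT = 0.25
MIN_RUN_DEFAULT = 3
MIN_ORF_AA_DEFAULT = 30


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class HomopolymerCandidate:
    """A maximal homopolymer run in the assembly (0-based half-open)."""

    contig: str
    start: int
    end: int
    base: str
    support: dict[int, int] = field(default_factory=dict)
    coverage: int = 0
    maximal: bool = True
    skipped_reads: int = 0

    @property
    def assembly_run_len(self) -> int:
        return self.end - self.start

    @property
    def position_1based(self) -> int:
        return self.start + 1


@dataclass
class CorrectionDecision:
    candidate: HomopolymerCandidate
    action: str  # "insert" | "delete" | "none"
    n: int = 0
    chosen_len: int | None = None
    support_count: int = 0
    support_fraction: float = 0.0
    reason: str = ""


# ---------------------------------------------------------------------------
# six-frame ORF scan
# ---------------------------------------------------------------------------

def six_frame_orfs(
    seq: str, min_aa: int = MIN_ORF_AA_DEFAULT, table: int = 11
) -> list[tuple[str, int, int, str]]:
    """Stop-to-stop ORFs of >= min_aa residues in all six frames.

    Returns (frame, start, end, peptide) tuples; frame is one of
    "+1".."+3"/"-1".."-3" and start/end are 0-based half-open coordinates
    on the forward strand.
    """
    seq = seq.upper()
    length = len(seq)
    out: list[tuple[str, int, int, str]] = []
    for strand, working in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for offset in range(3):
            frame = f"{strand}{offset + 1}"
            usable = working[offset:]
            usable = usable[: len(usable) - len(usable) % 3]
            if not usable:
                continue
            peptide = str(Seq(usable).translate(table=table))
            aa_pos = 0
            for stretch in peptide.split("*"):
                if len(stretch) >= min_aa:
                    nt_start = offset + 3 * aa_pos
                    nt_end = offset + 3 * (aa_pos + len(stretch))
                    if strand == "-":
                        nt_start, nt_end = length - nt_end, length - nt_start
                    out.append((frame, nt_start, nt_end, stretch))
                aa_pos += len(stretch) + 1  # +1 for the stop codon
    return out


# ---------------------------------------------------------------------------
# candidate discovery
# ---------------------------------------------------------------------------

def find_homopolymer_candidates(
    seq: str,
    contig: str = "contig",
    region: tuple[int, int] | None = None,
    min_run: int = MIN_RUN_DEFAULT,
) -> list[HomopolymerCandidate]:
    """All maximal runs of length >= min_run inside ``region``.

    Runs cut off by a region boundary are truncated there and flagged
    ``maximal=False``.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    seq = seq.upper()
    lo, hi = region if region is not None else (0, len(seq))
    if not (0 <= lo < hi <= len(seq)):
        raise ValueError(f"region ({lo}, {hi}) outside contig of length {len(seq)}")
    out: list[HomopolymerCandidate] = []
    i = lo
    while i < hi:
        base = seq[i]
        j = i
        while j < hi and seq[j] == base:
            j += 1
        if base in "ACGT" and j - i >= min_run:
            maximal = not (
                (i == lo and i > 0 and seq[i - 1] == base)
                or (j == hi and j < len(seq) and seq[j] == base)
            )
            out.append(
                HomopolymerCandidate(contig=contig, start=i, end=j, base=base,
                                     maximal=maximal)
            )
        i = j
    return out


# ---------------------------------------------------------------------------
# read support
# ---------------------------------------------------------------------------

def _alignment_files(sam_path: str | Path) -> pysam.AlignmentFile:
    return pysam.AlignmentFile(str(sam_path), "r", check_sq=False)


def count_run_support_bulk(
    candidates: Sequence[HomopolymerCandidate], sam_path: str | Path
) -> None:
    """Fill support/coverage for many candidates in one SAM pass.

    A read supports a candidate only when its alignment covers the full
    run plus one aligned anchor base on each side; the observed run
    length is the number of read bases between the two anchors.
    Secondary/supplementary and unmapped alignments are excluded.
    """
    by_contig: dict[str, list[HomopolymerCandidate]] = {}
    for c in candidates:
        c.support = {}
        c.coverage = 0
        c.skipped_reads = 0
        by_contig.setdefault(c.contig, []).append(c)
    for lst in by_contig.values():
        lst.sort(key=lambda c: c.start)

    with _alignment_files(sam_path) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            contig = read.reference_name
            if contig not in by_contig:
                continue
            ref_start, ref_end = read.reference_start, read.reference_end
            relevant: list[HomopolymerCandidate] = []
            touched: list[HomopolymerCandidate] = []
            for c in by_contig[contig]:
                if c.start >= ref_end:
                    break
                if c.end <= ref_start:
                    continue
                if c.start - 1 >= ref_start and c.end + 1 <= ref_end:
                    relevant.append(c)
                else:
                    touched.append(c)  # overlapped but not spanned
            if not relevant and not touched:
                continue
            ref_to_query: dict[int, int] | None = None
            if relevant:
                ref_to_query = {
                    rpos: qpos
                    for qpos, rpos in read.get_aligned_pairs()
                    if rpos is not None and qpos is not None
                }
            for c in relevant:
                ql = ref_to_query.get(c.start - 1)  # type: ignore[union-attr]
                qr = ref_to_query.get(c.end)  # type: ignore[union-attr]
                if ql is None or qr is None:
                    c.skipped_reads += 1
                    continue
                observed = qr - ql - 1
                c.coverage += 1
                c.support[observed] = c.support.get(observed, 0) + 1
            for c in touched:
                c.skipped_reads += 1


def count_run_support(
    candidate: HomopolymerCandidate, sam_path: str | Path
) -> HomopolymerCandidate:
    """Fill support and coverage for a single candidate (one SAM pass)."""
    count_run_support_bulk([candidate], sam_path)
    return candidate


# ---------------------------------------------------------------------------
# correction decisions
# ---------------------------------------------------------------------------

def decide_correction(
    candidate: HomopolymerCandidate,
    min_reads: int = MIN_READS_DEFAULT,
    min_fraction: float = MIN_FRACTION_DEFAULT,
) -> CorrectionDecision:
    """Correct only when the best alternative run length has enough reads.

    The chosen length L* maximizes support over lengths differing from
    the assembly run length (ties: closest to the assembly length, then
    smaller). A correction requires support[L*] >= min_reads and
    support[L*]/coverage strictly greater than min_fraction.
    """
    asm_len = candidate.assembly_run_len
    if candidate.coverage == 0:
        return CorrectionDecision(candidate, "none", reason="no coverage")
    alternatives = {L: n for L, n in candidate.support.items() if L != asm_len}
    if not alternatives:
        return CorrectionDecision(candidate, "none", reason="no alternative length")
    best_len = min(
        alternatives,
        key=lambda L: (-alternatives[L], abs(L - asm_len), L),
    )
    count = alternatives[best_len]
    fraction = count / candidate.coverage
    if count >= min_reads and fraction > min_fraction:
        action = "insert" if best_len > asm_len else "delete"
        return CorrectionDecision(
            candidate, action, n=abs(best_len - asm_len), chosen_len=best_len,
            support_count=count, support_fraction=fraction,
        )
    return CorrectionDecision(
        candidate, "none", chosen_len=best_len, support_count=count,
        support_fraction=fraction,
        reason=(
            f"support {count} < {min_reads} reads"
            if count < min_reads
            else f"fraction {fraction:.3f} not > {min_fraction}"
        ),
    )


# ---------------------------------------------------------------------------
# applying corrections
# ---------------------------------------------------------------------------

class ShiftTable:
    """Maps old contig coordinates to new ones after indel corrections."""

    def __init__(self, edits: list[tuple[int, int]]):
        # edits: (old position at/after which the shift applies, delta)
        self.edits = sorted(edits)

    def map(self, old_pos: int) -> int:
        shift = 0
        for pos, delta in self.edits:
            if old_pos >= pos:
                shift += delta
        return old_pos + shift


def apply_corrections(
    contig: str, decisions: Iterable[CorrectionDecision]
) -> tuple[str, ShiftTable, str]:
    """Apply accepted decisions right-to-left; return the corrected
    sequence, a coordinate shift table, and a one-line summary."""
    decisions = list(decisions)
    actionable = [d for d in decisions if d.action != "none"]
    spans = sorted((d.candidate.start, d.candidate.end) for d in actionable)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping corrections at ({s1},{e1}) and ({s2},{e2})")

    seq = contig
    edits: list[tuple[int, int]] = []
    for d in sorted(actionable, key=lambda d: d.candidate.start, reverse=True):
        c = d.candidate
        if d.action == "insert":
            seq = seq[: c.end] + c.base * d.n + seq[c.end :]
            edits.append((c.end, d.n))
        else:
            seq = seq[: c.end - d.n] + seq[c.end :]
            edits.append((c.end, -d.n))
    summary = f"{len(actionable)} of {len(decisions)} candidates corrected"
    return seq, ShiftTable(edits), summary


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------

@dataclass
class PolishResult:
    corrected: str
    decisions: list[CorrectionDecision]
    shift_table: ShiftTable
    summary: str


def polish_assembly(
    draft: str,
    sam_path: str | Path,
    contig: str = "contig",
    regions: Sequence[tuple[int, int]] | None = None,
    min_run: int = MIN_RUN_DEFAULT,
    min_reads: int = MIN_READS_DEFAULT,
    min_fraction: float = MIN_FRACTION_DEFAULT,
) -> PolishResult:
    """Scan, count support and correct in one call.

    ``regions`` restricts the candidate scan (e.g. to CDS features
    flagged with internal stops, or to externally supplied intervals);
    by default the whole contig is scanned.
    """
    candidates: list[HomopolymerCandidate] = []
    for region in regions or [None]:  # type: ignore[list-item]
        candidates.extend(
            find_homopolymer_candidates(draft, contig=contig, region=region,
                                        min_run=min_run)
        )
    count_run_support_bulk(candidates, sam_path)
    decisions = [
        decide_correction(c, min_reads=min_reads, min_fraction=min_fraction)
        for c in candidates
    ]
    corrected, shifts, summary = apply_corrections(draft, decisions)
    return PolishResult(corrected, decisions, shifts, summary)


def write_decision_report(decisions: Sequence[CorrectionDecision],
                          path: str | Path) -> None:
    """TSV report with 1-based run positions."""
    with open(path, "w") as fh:
        fh.write("contig\tposition\tbase\trun_len\taction\tn\t"
                 "support\tcoverage\tfraction\treason\n")
        for d in decisions:
            c = d.candidate
            fh.write(
                f"{c.contig}\t{c.position_1based}\t{c.base}\t{c.assembly_run_len}\t"
                f"{d.action}\t{d.n}\t{d.support_count}\t{c.coverage}\t"
                f"{d.support_fraction:.4f}\t{d.reason}\n"
            )
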