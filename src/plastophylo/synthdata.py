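"""Synthetic fixtures with known ground truth.

Two generators: peptide proteomes evolved down a species tree (for the
orthogroup-cleaning and supermatrix stages) and a plastome draft with
planted homopolymer indels plus simulated read alignments (for the
polish stage). Everything is deterministic under a fixed seed.

The substitution model is uniform residue replacement with per-site
substitution probability equal to the branch length — deliberately
non-biological, but sufficient to exercise filters and distance trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from plastophylo.orthofilter import GeneTree, Orthogroup, write_orthogroup_table
from plastophylo.seqio import SeqRecord, write_fasta
from plastophylo.supermatrix import nj_tree_from_distances, p_distance_matrix

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"

DEFAULT_TREE_8 = (
    "((((interest:0.04,reference:0.04):0.04,(rel1:0.05,rel2:0.05):0.03):0.04,"
    "(rel3:0.06,(rel4:0.05,rel5:0.05):0.02):0.04):0.08,outgroup:0.16);"
)


# ---------------------------------------------------------------------------
# specs and truth
# ---------------------------------------------------------------------------

@dataclass
class HomopolymerSite:
    """A planted homopolymer discrepancy between truth and draft."""

    base: str
    true_len: int
    draft_offset: int  # draft run length = true_len + draft_offset


@dataclass
class SimSpec:
    seed: int
    tree: str = DEFAULT_TREE_8
    n_genes: int = 20
    gene_len_range: tuple[int, int] = (80, 150)
    paralog_rate: float = 0.0
    loss_rate: float = 0.0
    outlier_rate: float = 0.0
    outliers_per_gene: int | None = None
    outlier_branch_multiplier: float = 8.0
    genome_len: int = 20000
    homopolymer_sites: list[HomopolymerSite] = field(default_factory=list)
    read_depth: int = 30
    read_len: int = 1000
    true_length_read_fraction: float = 1.0

    def __post_init__(self) -> None:
        for rate in (self.paralog_rate, self.loss_rate, self.outlier_rate,
                     self.true_length_read_fraction):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class OrthogroupTruth:
    og_id: str
    members: list[str]
    planted_outliers: set[str] = field(default_factory=set)
    planted_paralogs: set[str] = field(default_factory=set)


@dataclass
class ProteomeSim:
    seed: int
    species: list[str]
    records: list[SeqRecord]
    orthogroups: list[Orthogroup]
    truth: list[OrthogroupTruth]


@dataclass
class PlantedIndel:
    """Ground truth for one planted site, in draft coordinates."""

    draft_start: int
    draft_end: int
    base: str
    draft_len: int
    true_len: int

    @property
    def required_action(self) -> tuple[str, int]:
        delta = self.true_len - self.draft_len
        return ("insert", delta) if delta > 0 else ("delete", -delta)


@dataclass
class PlastomeSim:
    seed: int
    reference: str
    draft: str
    planted: list[PlantedIndel]
    sam_path: Path | None = None


# ---------------------------------------------------------------------------
# proteome simulation
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator,
            alphabet: str = AA_ALPHABET) -> np.ndarray:
    p = min(p, 0.95)
    hit = rng.random(seq.size) < p
    if not hit.any():
        return seq.copy()
    out = seq.copy()
    k = len(alphabet)
    # replace with a uniformly chosen *different* residue
    shifts = rng.integers(1, k, size=int(hit.sum()))
    out[hit] = (out[hit] + shifts) % k
    return out


def _decode(arr: np.ndarray, alphabet: str = AA_ALPHABET) -> str:
    return "".join(alphabet[i] for i in arr)


def simulate_proteomes(spec: SimSpec) -> ProteomeSim:
    """Evolve n_genes ancestral peptides down the species tree.

    Per (gene, species): the member may be lost (loss_rate), duplicated
    into a planted paralog (paralog_rate), or planted as a long-branch
    outlier — its pendant branch is multiplied by
    outlier_branch_multiplier. Truth tables record all plants.
    """
    rng = np.random.default_rng(spec.seed)
    tree = dendropy.Tree.get(data=spec.tree, schema="newick",
                             preserve_underscores=True)
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]

    records: list[SeqRecord] = []
    orthogroups: list[Orthogroup] = []
    truths: list[OrthogroupTruth] = []

    for g in range(spec.n_genes):
        og_id = f"OG{g:04d}"
        lo, hi = spec.gene_len_range
        gene_len = int(rng.integers(lo, hi + 1))
        ancestral = rng.integers(0, len(AA_ALPHABET), size=gene_len)

        outlier_species: set[str] = set()
        if spec.outliers_per_gene:
            picks = rng.choice(len(species), size=spec.outliers_per_gene,
                               replace=False)
            outlier_species = {species[int(i)] for i in picks}

        leaf_seqs: dict[str, np.ndarray] = {}

        def evolve(node: dendropy.Node, seq: np.ndarray) -> None:
            for child in node.child_nodes():
                bl = float(child.edge.length or 0.0)
                if child.is_leaf():
                    sp = child.taxon.label
                    planted = sp in outlier_species or (
                        spec.outliers_per_gene is None
                        and spec.outlier_rate > 0
                        and rng.random() < spec.outlier_rate
                    )
                    if planted:
                        outlier_species.add(sp)
                        bl *= spec.outlier_branch_multiplier
                    leaf_seqs[sp] = _mutate(seq, bl, rng)
                else:
                    evolve(child, _mutate(seq, bl, rng))

        evolve(tree.seed_node, ancestral)

        truth = OrthogroupTruth(og_id=og_id, members=[])
        members: list[SeqRecord] = []
        for sp in species:
            if spec.loss_rate > 0 and rng.random() < spec.loss_rate:
                continue
            member_id = f"{sp}@g{g:04d}"
            rec = SeqRecord(id=member_id, seq=_decode(leaf_seqs[sp]),
                            species=sp, moltype="aa")
            members.append(rec)
            truth.members.append(member_id)
            if sp in outlier_species:
                truth.planted_outliers.add(member_id)
            if spec.paralog_rate > 0 and rng.random() < spec.paralog_rate:
                para_id = f"{sp}@g{g:04d}_p1"
                para_seq = _mutate(leaf_seqs[sp], 0.02, rng)
                members.append(SeqRecord(id=para_id, seq=_decode(para_seq),
                                         species=sp, moltype="aa"))
                truth.members.append(para_id)
                truth.planted_paralogs.add(para_id)
        records.extend(members)
        orthogroups.append(Orthogroup(og_id=og_id, members=members))
        truths.append(truth)

    return ProteomeSim(seed=spec.seed, species=species, records=records,
                       orthogroups=orthogroups, truth=truths)


def nj_gene_tree(og: Orthogroup) -> GeneTree | None:
    """Build a gene tree for an orthogroup by NJ on member p-distances.

    Members of a simulated orthogroup all share the ancestral gene length,
    so the identity alignment is exact. Returns None below 3 members.
    """
    if len(og.members) < 3:
        return None
    ids = [m.id for m in og.members]
    rows = {m.id: m.seq for m in og.members}
    if len({len(s) for s in rows.values()}) != 1:
        raise ValueError(f"members of {og.og_id} differ in length; align first")
    phylo = nj_tree_from_distances(p_distance_matrix(rows, ids), ids)
    leaf_map = {m.id: (m.species, m.id) for m in og.members}
    return GeneTree(newick=phylo.newick, leaf_map=leaf_map)


def attach_gene_trees(sim: ProteomeSim) -> None:
    for og in sim.orthogroups:
        og.gene_tree = nj_gene_tree(og)


# ---------------------------------------------------------------------------
# plastome + read simulation
# ---------------------------------------------------------------------------

def _plant_sites(
    genome: np.ndarray, sites: Sequence[HomopolymerSite], rng: np.random.Generator
) -> list[tuple[int, HomopolymerSite]]:
    """Write each site's true-length run into the genome at evenly spaced
    positions; flanking bases are forced to differ from the run base."""
    n = len(sites)
    placements = []
    spacing = len(genome) // (n + 1)
    for k, site in enumerate(sites):
        pos = (k + 1) * spacing
        base_idx = NT_ALPHABET.index(site.base)
        genome[pos : pos + site.true_len] = base_idx
        for flank in (pos - 1, pos + site.true_len):
            if genome[flank] == base_idx:
                genome[flank] = (base_idx + 1 + int(rng.integers(0, 3))) % 4
        placements.append((pos, site))
    return placements


def simulate_plastome_reads(
    spec: SimSpec, outdir: str | Path, contig: str = "draft"
) -> PlastomeSim:
    """Simulate a reference genome, an erroneous draft, and read alignments.

    The draft equals the reference except at the planted homopolymer
    sites, where the run length is off by ``draft_offset``. Reads are
    error-free copies of the reference except that at each planted site a
    read reports the true run length with probability
    ``true_length_read_fraction`` and otherwise the draft's. The SAM
    (reads vs draft) is written with exact CIGARs by construction.
    """
    rng = np.random.default_rng(spec.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = rng.integers(0, 4, size=spec.genome_len)
    placements = _plant_sites(genome, spec.homopolymer_sites, rng)
    reference = _decode(genome, NT_ALPHABET)

    # draft coordinates: apply offsets left-to-right, tracking shift
    draft_parts: list[str] = []
    planted: list[PlantedIndel] = []
    prev = 0
    shift = 0
    for pos, site in placements:
        draft_parts.append(reference[prev : pos])
        draft_len = site.true_len + site.draft_offset
        if draft_len < 0:
            raise ValueError("draft run length cannot be negative")
        draft_parts.append(site.base * draft_len)
        d_start = pos + shift
        planted.append(PlantedIndel(
            draft_start=d_start, draft_end=d_start + draft_len,
            base=site.base, draft_len=draft_len, true_len=site.true_len,
        ))
        prev = pos + site.true_len
        shift += site.draft_offset
    draft_parts.append(reference[prev:])
    draft = "".join(draft_parts)

    sam_path = outdir / "reads_vs_draft.sam"
    _write_read_sam(
        draft=draft, planted=planted, contig=contig, rng=rng,
        depth=spec.read_depth, read_len=spec.read_len,
        true_fraction=spec.true_length_read_fraction, sam_path=sam_path,
    )

    write_fasta([SeqRecord(id="reference", seq=reference, moltype="nt")],
                outdir / "reference.fasta")
    write_fasta([SeqRecord(id=contig, seq=draft, moltype="nt")],
                outdir / "draft.fasta")
    return PlastomeSim(seed=spec.seed, reference=reference, draft=draft,
                       planted=planted, sam_path=sam_path)


def _write_read_sam(
    draft: str,
    planted: Sequence[PlantedIndel],
    contig: str,
    rng: np.random.Generator,
    depth: int,
    read_len: int,
    true_fraction: float,
    sam_path: Path,
) -> None:
    n_reads = max(1, int(round(depth * len(draft) / read_len)))
    sites = sorted(planted, key=lambda s: s.draft_start)
    # evenly spaced starts keep local coverage within ~1 of the nominal
    # depth, so depth thresholds in fixtures behave as constructed
    span = max(1, len(draft) - read_len)
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{contig}\tLN:{len(draft)}\n")
        for r in range(n_reads):
            start = (r * span) // max(1, n_reads - 1) if n_reads > 1 else 0
            end = min(start + read_len, len(draft))
            seq_parts: list[str] = []
            cigar: list[tuple[int, str]] = []

            def emit(n: int, op: str) -> None:
                if n <= 0:
                    return
                if cigar and cigar[-1][1] == op:
                    cigar[-1] = (cigar[-1][0] + n, op)
                else:
                    cigar.append((n, op))

            pos = start
            for site in sites:
                if site.draft_end > end or site.draft_start < start:
                    continue  # read does not fully span this run
                emit(site.draft_start - pos, "M")
                seq_parts.append(draft[pos : site.draft_start])
                use_true = rng.random() < true_fraction
                run_len = site.true_len if use_true else site.draft_len
                common = min(run_len, site.draft_len)
                emit(common, "M")
                seq_parts.append(site.base * run_len)
                if run_len > site.draft_len:
                    emit(run_len - site.draft_len, "I")
                elif run_len < site.draft_len:
                    emit(site.draft_len - run_len, "D")
                pos = site.draft_end
            emit(end - pos, "M")
            seq_parts.append(draft[pos:end])

            read_seq = "".join(seq_parts)
            cigar_str = "".join(f"{n}{op}" for n, op in cigar)
            fh.write(
                f"read{r:05d}\t0\t{contig}\t{start + 1}\t60\t{cigar_str}\t"
                f"*\t0\t0\t{read_seq}\t{'I' * len(read_seq)}\n"
            )


def write_perfect_read_sam(
    assembly: str,
    sam_path: str | Path,
    contig: str = "draft",
    depth: int = 30,
    read_len: int = 1000,
    seed: int = 0,
) -> Path:
    """Error-free reads sampled from ``assembly`` aligned back to it."""
    rng = np.random.default_rng(seed)
    sam_path = Path(sam_path)
    _write_read_sam(draft=assembly, planted=[], contig=contig, rng=rng,
                    depth=depth, read_len=read_len, true_fraction=1.0,
                    sam_path=sam_path)
    return sam_path


# ---------------------------------------------------------------------------
# fixture directory writer
# ---------------------------------------------------------------------------

def write_proteome_fixture(sim: ProteomeSim, outdir: str | Path) -> Path:
    """Write per-species FASTA, the orthogroup table, per-og newick gene
    trees and the truth tables into a fixture directory."""
    outdir = Path(outdir)
    (outdir / "peptides").mkdir(parents=True, exist_ok=True)
    (outdir / "trees").mkdir(exist_ok=True)
    for sp in sim.species:
        recs = [r for r in sim.records if r.species == sp]
        write_fasta(recs, outdir / "peptides" / f"{sp}.fasta")
    write_orthogroup_table(sim.orthogroups, outdir / "orthogroups.tsv")
    for og in sim.orthogroups:
        if og.gene_tree is not None:
            (outdir / "trees" / f"{og.og_id}.nwk").write_text(og.gene_tree.newick)
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("#og_id\tmember_id\tis_outlier\tis_paralog\n")
        for t in sim.truth:
            for mid in t.members:
                fh.write(
                    f"{t.og_id}\t{mid}\t{int(mid in t.planted_outliers)}\t"
                    f"{int(mid in t.planted_paralogs)}\n"
                )
    with open(outdir / "seed.txt", "w") as fh:
        fh.write(f"{sim.seed}\n")
    return outdir
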