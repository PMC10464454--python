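"""Orthogroup trimming and the four-step post-orthology cleaning.

The cleaning order is fixed: (1) branch-length outlier removal per gene
tree, (2) linked-presence filtering, (3) outgroup-count filtering,
(4) within-species paralog dedupe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from plastophylo.errors import TreeError
from plastophylo.seqio import SeqRecord

MIN_LEAVES_FOR_FLAGGING = 4


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneTree:
    """A per-orthogroup tree with branch lengths.

    ``leaf_map`` maps each leaf label to its (species, member id).
    """

    newick: str
    leaf_map: dict[str, tuple[str, str]]

    def _tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick, schema="newick", preserve_underscores=True
        )

    def pendant_lengths(self) -> dict[str, float]:
        """Terminal branch length per leaf label; error on a missing length."""
        lengths: dict[str, float] = {}
        for leaf in self._tree().leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else ""
            if leaf.edge.length is None:
                raise TreeError(f"leaf {label!r} has no branch length")
            lengths[label] = float(leaf.edge.length)
        return lengths


@dataclass
class Orthogroup:
    og_id: str
    members: list[SeqRecord]
    gene_tree: GeneTree | None = None

    @property
    def species_set(self) -> set[str]:
        return {m.species for m in self.members}


@dataclass
class RunConfig:
    species_of_interest: list[str] = field(default_factory=list)
    linked_groups: list[set[str]] = field(default_factory=list)
    outgroup: set[str] = field(default_factory=set)
    min_peptide_len: int = 10
    iqr_factor: float = 1.5
    two_sided_fence: bool = False

    def __post_init__(self) -> None:
        if self.min_peptide_len < 1:
            raise ValueError("min_peptide_len must be >= 1")
        if self.iqr_factor <= 0:
            raise ValueError("iqr_factor must be positive")


@dataclass
class PretrimReport:
    n_in: int = 0
    n_kept: int = 0
    duplicates_removed: int = 0
    asterisk_removed: int = 0
    short_removed: int = 0


@dataclass
class StepEvent:
    og_id: str
    step: int
    action: str  # "member_removed" | "og_discarded"
    detail: str


@dataclass
class PostprocessReport:
    events: list[StepEvent] = field(default_factory=list)
    ogs_in: int = 0
    ogs_kept: int = 0

    def removals(self, step: int) -> list[StepEvent]:
        return [e for e in self.events if e.step == step]


# ---------------------------------------------------------------------------
# pre-clustering trimming
# ---------------------------------------------------------------------------

def pretrim(
    records: Sequence[SeqRecord], cfg: RunConfig
) -> tuple[list[SeqRecord], PretrimReport]:
    """Trim peptides before orthology inference.

    Within each species, byte-identical sequences collapse to the
    lexicographically-first id; sequences containing ``*`` and sequences
    shorter than ``cfg.min_peptide_len`` are removed.
    """
    report = PretrimReport(n_in=len(records))

    best: dict[tuple[str, str], SeqRecord] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.species, rec.seq)
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            report.duplicates_removed += 1
            if rec.id < best[key].id:
                best[key] = rec

    kept: list[SeqRecord] = []
    for key in order:
        rec = best[key]
        if "*" in rec.seq:
            report.asterisk_removed += 1
        elif len(rec.seq) < cfg.min_peptide_len:
            report.short_removed += 1
        else:
            kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# step 1: branch-length outliers
# ---------------------------------------------------------------------------

def iqr_fences(values: Sequence[float], factor: float = 1.5) -> tuple[float, float]:
    """(lower, upper) Tukey fences with linear-interpolation quartiles."""
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(arr, [25.0, 75.0], method="linear")
    iqr = q3 - q1
    return q1 - factor * iqr, q3 + factor * iqr


def flag_branch_outliers(
    tree: GeneTree,
    outgroup: set[str],
    iqr_factor: float = 1.5,
    two_sided: bool = False,
) -> set[str]:
    """Member ids whose pendant branch length exceeds the IQR fence.

    Outgroup leaves contribute neither to the quartile statistics nor to
    the flags. With fewer than four usable leaves no flagging is done
    (the quartiles are too unstable to trust).
    """
    lengths = tree.pendant_lengths()
    usable: list[tuple[str, float]] = []
    for label, length in lengths.items():
        if label not in tree.leaf_map:
            raise TreeError(f"leaf {label!r} missing from leaf map")
        species, member_id = tree.leaf_map[label]
        if species in outgroup:
            continue
        usable.append((member_id, length))
    if len(usable) < MIN_LEAVES_FOR_FLAGGING:
        return set()
    lower, upper = iqr_fences([ln for _, ln in usable], factor=iqr_factor)
    flagged = {mid for mid, ln in usable if ln > upper}
    if two_sided:
        flagged |= {mid for mid, ln in usable if ln < lower}
    return flagged


# ---------------------------------------------------------------------------
# steps 2-4
# ---------------------------------------------------------------------------

def filter_linked_presence(og: Orthogroup, linked_groups: Iterable[set[str]]) -> bool:
    """True (keep) iff every linked group is entirely present or entirely absent."""
    present = og.species_set
    for group in linked_groups:
        hits = present & set(group)
        if hits and hits != set(group):
            return False
    return True


def filter_min_species(og: Orthogroup, outgroup: set[str]) -> bool:
    """True (keep) unless the group has fewer species than there are
    outgroup taxa; groups made up solely of outgroup species are exempt."""
    if not outgroup:
        raise ValueError("outgroup must be non-empty for the species-count filter")
    present = og.species_set
    if present and present <= outgroup:
        return True
    return len(present) >= len(outgroup)


def dedupe_paralogs(og: Orthogroup) -> Orthogroup:
    """Keep only the longest member per species (ties: smallest id)."""
    best: dict[str, SeqRecord] = {}
    for m in og.members:
        cur = best.get(m.species)
        if cur is None or (-len(m.seq), m.id) < (-len(cur.seq), cur.id):
            best[m.species] = m
    members = [m for m in og.members if best[m.species] is m]
    return Orthogroup(og_id=og.og_id, members=members, gene_tree=og.gene_tree)


def run_postprocessing(
    ogs: Sequence[Orthogroup], cfg: RunConfig
) -> tuple[list[Orthogroup], PostprocessReport]:
    """Apply the four cleaning steps in order and report every removal."""
    report = PostprocessReport(ogs_in=len(ogs))
    cleaned: list[Orthogroup] = []
    for og in ogs:
        # step 1: branch-length outliers
        members = list(og.members)
        if og.gene_tree is not None and len(members) >= MIN_LEAVES_FOR_FLAGGING:
            flagged = flag_branch_outliers(
                og.gene_tree, cfg.outgroup,
                iqr_factor=cfg.iqr_factor, two_sided=cfg.two_sided_fence,
            )
            if flagged:
                members = [m for m in members if m.id not in flagged]
                for mid in sorted(flagged):
                    report.events.append(
                        StepEvent(og.og_id, 1, "member_removed", mid)
                    )
        og1 = Orthogroup(og.og_id, members, og.gene_tree)

        # step 2: linked presence
        if not filter_linked_presence(og1, cfg.linked_groups):
            report.events.append(
                StepEvent(og.og_id, 2, "og_discarded", "linked-presence violation")
            )
            continue

        # step 3: outgroup-count threshold
        if cfg.outgroup and not filter_min_species(og1, cfg.outgroup):
            report.events.append(
                StepEvent(og.og_id, 3, "og_discarded", "fewer species than outgroup")
            )
            continue

        # step 4: paralog dedupe
        og4 = dedupe_paralogs(og1)
        for m in og1.members:
            if m not in og4.members:
                report.events.append(
                    StepEvent(og.og_id, 4, "member_removed", m.id)
                )
        cleaned.append(og4)
    report.ogs_kept = len(cleaned)
    return cleaned, report


# ---------------------------------------------------------------------------
# on-disk layout: TSV membership + per-og FASTA/newick
# ---------------------------------------------------------------------------

def read_orthogroup_table(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read a (og_id, species, member_id) TSV into og_id -> [(species, member)]."""
    table: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            og_id, species, member = line.split("\t")[:3]
            table.setdefault(og_id, []).append((species, member))
    return table


def write_orthogroup_table(ogs: Iterable[Orthogroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#og_id\tspecies\tmember_id\n")
        for og in ogs:
            for m in og.members:
                fh.write(f"{og.og_id}\t{m.species}\t{m.id}\n")


def load_orthogroups(
    table_path: str | Path,
    records: Sequence[SeqRecord],
    tree_dir: str | Path | None = None,
) -> list[Orthogroup]:
    """Assemble Orthogroups from a membership TSV, a record pool, and an
    optional directory of per-og newick files named ``<og_id>.nwk``."""
    by_id = {rec.id: rec for rec in records}
    ogs = []
    for og_id, pairs in read_orthogroup_table(table_path).items():
        members = [by_id[member] for _species, member in pairs if member in by_id]
        tree = None
        if tree_dir is not None:
            nwk = Path(tree_dir) / f"{og_id}.nwk"
            if nwk.exists():
                # map every leaf the tree may carry, including members the
                # pre-clustering trim already dropped from the record pool
                leaf_map = {member: (species, member) for species, member in pairs}
                tree = GeneTree(newick=nwk.read_text(), leaf_map=leaf_map)
        ogs.append(Orthogroup(og_id=og_id, members=members, gene_tree=tree))
    return ogs
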