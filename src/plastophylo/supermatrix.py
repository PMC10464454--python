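"""Alignment, supermatrix concatenation and desk-scale tree building.

The built-in aligner is a deterministic center-star progressive
alignment under BLOSUM62 with affine gaps; an external aligner can be
plugged in as a command template. Trees come from neighbor joining on
p-distances with pairwise gap deletion, with bootstrap support from
column resampling.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from plastophylo.errors import PlastophyloError
from plastophylo.orthofilter import Orthogroup
from plastophylo.seqio import SeqRecord, read_fasta, write_fasta

GAP = "-"
IQTREE_SEED = 291752


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    og_id: str
    rows: dict[str, str]  # species -> gapped sequence

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths in alignment {self.og_id}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, species: str) -> str:
        return self.rows[species].replace(GAP, "")


@dataclass
class SuperMatrix:
    taxa: list[str]
    matrix: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (og_id, start, end) half-open

    @property
    def length(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0


@dataclass
class Phylogeny:
    """An unrooted tree: newick plus its internal-edge bipartitions.

    Bipartitions are canonicalized as the frozenset of leaves on the side
    not containing the lexicographically smallest taxon. ``supports``
    maps each bipartition to a percentage in [0, 100].
    """

    newick: str
    taxa: list[str]
    bipartitions: set[frozenset[str]]
    supports: dict[frozenset[str], float] | None = None

    def is_sister_pair(self, a: str, b: str) -> bool:
        """True iff {a, b} form a cherry (a 2-leaf clade) in the tree."""
        side = frozenset({a, b})
        return _canonical(side, self.taxa) in self.bipartitions

    def support_for(self, a: str, b: str) -> float | None:
        if self.supports is None:
            return None
        return self.supports.get(_canonical(frozenset({a, b}), self.taxa))


def _canonical(side: frozenset[str], taxa: Sequence[str]) -> frozenset[str]:
    ref = min(taxa)
    return frozenset(set(taxa) - side) if ref in side else side


# ---------------------------------------------------------------------------
# built-in center-star aligner
# ---------------------------------------------------------------------------

def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def pairwise_align(a: str, b: str) -> tuple[str, str, float]:
    """Best global affine-gap BLOSUM62 alignment of two peptides."""
    aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def _merge_into_master(
    master_center: list[str],
    rows: dict[str, list[str]],
    center_aln: str,
    new_aln: str,
    new_key: str,
) -> tuple[list[str], dict[str, list[str]]]:
    # master_center and center_aln are both gapped spellings of the same
    # ungapped center; walk them in lockstep, inserting gap columns where
    # one side has a gap the other lacks ("once a gap, always a gap").
    out_center: list[str] = []
    out_rows: dict[str, list[str]] = {k: [] for k in rows}
    out_new: list[str] = []
    i = j = 0
    n, m = len(master_center), len(center_aln)
    while i < n or j < m:
        mc = master_center[i] if i < n else None
        ca = center_aln[j] if j < m else None
        if mc is not None and (ca is None or (mc == GAP and ca != GAP)):
            # master-only gap column
            out_center.append(mc)
            for k in rows:
                out_rows[k].append(rows[k][i])
            out_new.append(GAP)
            i += 1
        elif ca == GAP and (mc is None or mc != GAP):
            # the new pairwise alignment opened a gap in the center
            out_center.append(GAP)
            for k in rows:
                out_rows[k].append(GAP)
            out_new.append(new_aln[j])
            j += 1
        else:
            # both consume one center position (residue/residue or gap/gap)
            out_center.append(mc)  # type: ignore[arg-type]
            for k in rows:
                out_rows[k].append(rows[k][i])
            out_new.append(new_aln[j])
            i += 1
            j += 1
    out_rows[new_key] = out_new
    return out_center, out_rows


def align_orthogroup(og: Orthogroup, aligner_cmd: str | None = None) -> Alignment:
    """Align an orthogroup's members (one per species).

    With ``aligner_cmd`` (a template with ``{input}`` and ``{output}``
    placeholders) the alignment is delegated to that command; otherwise
    the built-in center-star alignment is used. Deterministic for fixed
    input in the built-in path.
    """
    members = sorted(og.members, key=lambda m: m.id)
    species = [m.species for m in members]
    if len(set(species)) != len(species):
        raise ValueError(
            f"orthogroup {og.og_id} has multiple members for one species; "
            "run paralog dedupe first"
        )
    if not members:
        raise ValueError(f"orthogroup {og.og_id} is empty")
    if len(members) == 1:
        return Alignment(og.og_id, {members[0].species: members[0].seq})
    if aligner_cmd is not None:
        return _align_external(og, members, aligner_cmd)

    # choose the center: max total pairwise score, ties to smallest id
    scores = np.zeros(len(members))
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            _, _, s = pairwise_align(members[i].seq, members[j].seq)
            scores[i] += s
            scores[j] += s
    center_idx = min(range(len(members)), key=lambda i: (-scores[i], members[i].id))
    center = members[center_idx]

    master_center: list[str] = list(center.seq)
    rows: dict[str, list[str]] = {center.species: list(center.seq)}
    for m in members:
        if m is center:
            continue
        c_aln, s_aln, _ = pairwise_align(center.seq, m.seq)
        master_center, rows = _merge_into_master(
            master_center, rows, c_aln, s_aln, m.species
        )
    return Alignment(og.og_id, {sp: "".join(chars) for sp, chars in rows.items()})


def _align_external(
    og: Orthogroup, members: list[SeqRecord], aligner_cmd: str
) -> Alignment:
    with tempfile.TemporaryDirectory() as tmp:
        in_fa = Path(tmp) / "in.fasta"
        out_fa = Path(tmp) / "out.fasta"
        write_fasta(members, in_fa)
        cmd = aligner_cmd.format(input=shlex.quote(str(in_fa)),
                                 output=shlex.quote(str(out_fa)))
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise PlastophyloError(
                f"external aligner failed for {og.og_id}: {proc.stderr.strip()}"
            )
        if out_fa.exists():
            aligned = read_fasta(out_fa, moltype="aa")
        else:  # aligner wrote to stdout
            out_fa.write_text(proc.stdout)
            aligned = read_fasta(out_fa, moltype="aa")
    species_of = {m.id: m.species for m in members}
    return Alignment(og.og_id, {species_of[r.id]: r.seq.upper() for r in aligned})


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

def concatenate(
    alignments: Sequence[Alignment], taxa: Sequence[str] | None = None
) -> SuperMatrix:
    """Concatenate alignments into a supermatrix, gap-filling absentees.

    Taxon order follows ``taxa`` where given, then lexicographic for the
    rest. Species names colliding across case variants are an error.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    seen: set[str] = set()
    for aln in alignments:
        seen |= set(aln.rows)
    folded: dict[str, str] = {}
    for name in seen:
        if name.casefold() in folded:
            raise ValueError(
                f"species name case collision: {name!r} vs {folded[name.casefold()]!r}"
            )
        folded[name.casefold()] = name

    ordered: list[str] = []
    if taxa:
        ordered = [t for t in taxa if t in seen]
    ordered += sorted(seen - set(ordered))

    parts: dict[str, list[str]] = {t: [] for t in ordered}
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for aln in alignments:
        length = aln.length
        for t in ordered:
            parts[t].append(aln.rows.get(t, GAP * length))
        partitions.append((aln.og_id, pos, pos + length))
        pos += length
    return SuperMatrix(
        taxa=ordered,
        matrix={t: "".join(parts[t]) for t in ordered},
        partitions=partitions,
    )


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

def p_distance_matrix(rows: dict[str, str], taxa: Sequence[str]) -> np.ndarray:
    """Pairwise p-distances with pairwise deletion of gapped columns."""
    arrays = {t: np.frombuffer(rows[t].encode(), dtype="S1") for t in taxa}
    gap = GAP.encode()
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrays[taxa[i]], arrays[taxa[j]]
            both = (a != gap) & (b != gap)
            comparable = int(both.sum())
            if comparable == 0:
                raise PlastophyloError(
                    f"no comparable columns between {taxa[i]} and {taxa[j]}"
                )
            d[i, j] = d[j, i] = float((a[both] != b[both]).sum()) / comparable
    return d


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name: str | None = None,
                 children: list[tuple["_Node", float]] | None = None):
        self.name = name
        self.children = children or []

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _bl in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, supports: dict[frozenset[str], float] | None = None,
               taxa: Sequence[str] | None = None) -> str:
        return self._nwk(supports, taxa) + ";"

    def _nwk(self, supports, taxa) -> str:
        if not self.children:
            return self.name  # type: ignore[return-value]
        inner = ",".join(
            f"{child._nwk(supports, taxa)}:{bl:.6f}" for child, bl in self.children
        )
        label = ""
        if supports is not None and taxa is not None:
            key = _canonical(frozenset(self.leaves()), taxa)
            if key in supports:
                label = f"{supports[key]:.0f}"
        return f"({inner}){label}"


def _nj(d: np.ndarray, taxa: Sequence[str]) -> _Node:
    n = len(taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[_Node] = [_Node(name=t) for t in taxa]
    dist = d.astype(float).copy()
    active = list(range(n))
    next_nodes = {i: nodes[i] for i in active}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best  # type: ignore[misc]
        li = dist[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = _Node(children=[(next_nodes[i], li), (next_nodes[j], lj)])
        # reuse slot i for the new node
        for k in active:
            if k in (i, j):
                continue
            dik = (dist[i, k] + dist[j, k] - dist[i, j]) / 2
            dist[i, k] = dist[k, i] = max(dik, 0.0)
        next_nodes[i] = parent
        active.remove(j)

    i, j, k = active
    li = (dist[i, j] + dist[i, k] - dist[j, k]) / 2
    lj = (dist[i, j] + dist[j, k] - dist[i, k]) / 2
    lk = (dist[i, k] + dist[j, k] - dist[i, j]) / 2
    return _Node(children=[
        (next_nodes[i], max(li, 0.0)),
        (next_nodes[j], max(lj, 0.0)),
        (next_nodes[k], max(lk, 0.0)),
    ])


def _bipartitions(root: _Node, taxa: Sequence[str]) -> set[frozenset[str]]:
    all_taxa = set(taxa)
    out: set[frozenset[str]] = set()

    def visit(node: _Node) -> None:
        for child, _bl in node.children:
            side = set(child.leaves())
            if 2 <= len(side) <= len(all_taxa) - 2:
                out.add(_canonical(frozenset(side), taxa))
            visit(child)

    visit(root)
    return out


def nj_tree_from_distances(d: np.ndarray, taxa: Sequence[str]) -> Phylogeny:
    root = _nj(d, taxa)
    return Phylogeny(
        newick=root.newick(),
        taxa=list(taxa),
        bipartitions=_bipartitions(root, taxa),
    )


def nj_tree(sm: SuperMatrix) -> Phylogeny:
    """Neighbor-joining tree on p-distances from the supermatrix."""
    for t in sm.taxa:
        if set(sm.matrix[t]) == {GAP}:
            raise PlastophyloError(f"all-gap row for taxon {t}")
    d = p_distance_matrix(sm.matrix, sm.taxa)
    return nj_tree_from_distances(d, sm.taxa)


def bootstrap_support(
    sm: SuperMatrix, n_replicates: int = 100, seed: int = 0
) -> Phylogeny:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; the support of
    each bipartition of the point estimate is the percentage of replicate
    trees containing it.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    point = nj_tree(sm)
    rng = np.random.default_rng(seed)
    length = sm.length
    cols = {t: np.frombuffer(sm.matrix[t].encode(), dtype="S1") for t in sm.taxa}
    counts = {bp: 0 for bp in point.bipartitions}
    for _ in range(n_replicates):
        idx = rng.integers(0, length, size=length)
        rows = {t: cols[t][idx].tobytes().decode() for t in sm.taxa}
        try:
            rep = nj_tree_from_distances(p_distance_matrix(rows, sm.taxa), sm.taxa)
        except PlastophyloError:
            continue  # replicate with an incomparable pair contributes nothing
        for bp in counts:
            if bp in rep.bipartitions:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    root = _nj(p_distance_matrix(sm.matrix, sm.taxa), sm.taxa)
    return Phylogeny(
        newick=root.newick(supports=supports, taxa=sm.taxa),
        taxa=list(sm.taxa),
        bipartitions=point.bipartitions,
        supports=supports,
    )


# ---------------------------------------------------------------------------
# export for external ML inference
# ---------------------------------------------------------------------------

def export_ml_inputs(sm: SuperMatrix, outdir: str | Path) -> dict[str, Path]:
    """Write relaxed PHYLIP + NEXUS partitions + a reproducible command line.

    Partition ranges in the NEXUS file are 1-based inclusive.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phy = outdir / "supermatrix.phy"
    nex = outdir / "partitions.nex"
    cmd = outdir / "ml_command.txt"

    with open(phy, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.length}\n")
        for t in sm.taxa:
            fh.write(f"{t} {sm.matrix[t]}\n")

    with open(nex, "w") as fh:
        fh.write("#nexus\nbegin sets;\n")
        for og_id, start, end in sm.partitions:
            fh.write(f"  charset {og_id} = {start + 1}-{end};\n")
        fh.write("end;\n")

    cmd.write_text(
        "iqtree -s supermatrix.phy -spp partitions.nex "
        f"-nt AUTO -bb 1000 -seed {IQTREE_SEED}\n"
    )
    return {"phylip": phy, "partitions": nex, "command": cmd}


def read_phylip(path: str | Path) -> SuperMatrix:
    """Read a relaxed PHYLIP file back into a (partition-less) SuperMatrix."""
    lines = Path(path).read_text().splitlines()
    ntax, ncols = (int(x) for x in lines[0].split())
    taxa, matrix = [], {}
    for line in lines[1 : ntax + 1]:
        name, seq = line.split(None, 1)
        taxa.append(name)
        matrix[name] = seq.strip()
    return SuperMatrix(taxa=taxa, matrix=matrix,
                       partitions=[("all", 0, ncols)])
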