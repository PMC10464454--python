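import itertools
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from plastophylo.errors import PlastophyloError
from plastophylo.orthofilter import Orthogroup
from plastophylo.seqio import SeqRecord
from plastophylo.supermatrix import (
    Alignment,
    SuperMatrix,
    align_orthogroup,
    bootstrap_support,
    concatenate,
    export_ml_inputs,
    nj_tree,
    nj_tree_from_distances,
    p_distance_matrix,
    pairwise_align,
    read_phylip,
    _canonical,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def rec(species, seq, gene="g"):
    return SeqRecord(id=f"{species}@{gene}", seq=seq, species=species)


# ---------------------------------------------------------------------------
# oracle: exhaustive affine-gap alignment scoring for short peptides
# ---------------------------------------------------------------------------

def oracle_best_score(a, b, open_=-10.0, extend=-1.0):
    """Enumerate every global alignment of two short strings and score it
    with BLOSUM62 + affine gaps (first gap residue `open_`, then `extend`)."""

    best = [-np.inf]

    def go(i, j, score, last_op):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, score + BLOSUM62[a[i], b[j]], "M")
        if i < len(a):
            go(i + 1, j, score + (extend if last_op == "D" else open_), "D")
        if j < len(b):
            go(i, j + 1, score + (extend if last_op == "I" else open_), "I")

    go(0, 0, 0.0, None)
    return best[0]


class TestPairwiseAlign:
    def test_matches_exhaustive_oracle_on_short_peptides(self):
        rnd = random.Random(5)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(25):
            a = "".join(rnd.choice(aa) for _ in range(rnd.randint(1, 5)))
            b = "".join(rnd.choice(aa) for _ in range(rnd.randint(1, 5)))
            _, _, score = pairwise_align(a, b)
            assert score == pytest.approx(oracle_best_score(a, b))

    def test_mkv_mv_single_gap(self):
        a_aln, b_aln, score = pairwise_align("MKV", "MV")
        assert a_aln == "MKV"
        assert b_aln.count("-") == 1
        assert score == pytest.approx(oracle_best_score("MKV", "MV"))


class TestAlignOrthogroup:
    def test_identical_pair(self):
        og = Orthogroup("og", [rec("A", "MK"), rec("B", "MK")])
        aln = align_orthogroup(og)
        assert aln.rows == {"A": "MK", "B": "MK"}
        assert aln.length == 2

    def test_single_member(self):
        aln = align_orthogroup(Orthogroup("og", [rec("A", "MKT")]))
        assert aln.rows == {"A": "MKT"} and aln.length == 3

    def test_rows_ungap_to_members(self):
        rnd = random.Random(9)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        base = "".join(rnd.choice(aa) for _ in range(40))
        members = []
        for i, sp in enumerate("ABCDE"):
            seq = list(base)
            for _ in range(rnd.randint(0, 4)):  # indels + substitutions
                pos = rnd.randrange(len(seq))
                op = rnd.choice("sdi")
                if op == "s":
                    seq[pos] = rnd.choice(aa)
                elif op == "d" and len(seq) > 10:
                    del seq[pos]
                else:
                    seq.insert(pos, rnd.choice(aa))
            members.append(rec(sp, "".join(seq)))
        aln = align_orthogroup(Orthogroup("og", members))
        for m in members:
            assert aln.ungapped(m.species) == m.seq
        assert len({len(r) for r in aln.rows.values()}) == 1

    def test_duplicate_species_rejected(self):
        og = Orthogroup("og", [rec("A", "MKTT", "g1"), rec("A", "MKTT", "g2")])
        with pytest.raises(ValueError, match="paralog"):
            align_orthogroup(og)

    def test_deterministic(self):
        members = [rec("A", "MKVILLW"), rec("B", "MKVLLW"), rec("C", "MKVILW")]
        a1 = align_orthogroup(Orthogroup("og", members))
        a2 = align_orthogroup(Orthogroup("og", list(members)))
        assert a1.rows == a2.rows

    def test_external_command_failure_reports_stderr(self):
        og = Orthogroup("og", [rec("A", "MKT"), rec("B", "MKT")])
        with pytest.raises(PlastophyloError, match="external aligner failed"):
            align_orthogroup(og, aligner_cmd="false {input} {output}")


class TestConcatenate:
    def test_gap_fill_for_missing_species(self):
        a1 = Alignment("og1", {"A": "M" * 10, "B": "K" * 10, "C": "L" * 10})
        a2 = Alignment("og2", {"A": "W" * 7, "B": "Y" * 7})
        sm = concatenate([a1, a2], taxa=["A", "B", "C"])
        assert sm.length == 17
        assert sm.matrix["C"] == "L" * 10 + "-" * 7
        assert sm.partitions == [("og1", 0, 10), ("og2", 10, 17)]

    def test_single_alignment_identity(self):
        a1 = Alignment("og1", {"A": "MK", "B": "ML"})
        sm = concatenate([a1])
        assert sm.matrix == a1.rows

    def test_partitions_tile_total_length(self):
        alns = [Alignment(f"og{i}", {"A": "M" * n, "B": "K" * n})
                for i, n in enumerate([3, 5, 2])]
        sm = concatenate(alns)
        assert sm.partitions[0][1] == 0
        for (_, _, e1), (_, s2, _) in zip(sm.partitions, sm.partitions[1:]):
            assert e1 == s2
        assert sm.partitions[-1][2] == sm.length == 10

    def test_zero_taxon_overlap(self):
        a1 = Alignment("og1", {"A": "MMM"})
        a2 = Alignment("og2", {"B": "KK"})
        sm = concatenate([a1, a2])
        assert sm.matrix["A"] == "MMM--"
        assert sm.matrix["B"] == "---KK"

    def test_ungap_recovers_members_per_partition(self):
        a1 = Alignment("og1", {"A": "MK-V", "B": "MKTV"})
        a2 = Alignment("og2", {"B": "WW"})
        sm = concatenate([a1, a2])
        for og_id, start, end in sm.partitions:
            src = a1 if og_id == "og1" else a2
            for t in sm.taxa:
                got = sm.matrix[t][start:end].replace("-", "")
                want = src.rows.get(t, "").replace("-", "")
                assert got == want

    def test_case_collision_rejected(self):
        with pytest.raises(ValueError, match="case"):
            concatenate([Alignment("og1", {"Abc": "M", "ABC": "K"})])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            concatenate([])


# ---------------------------------------------------------------------------
# oracle: enumerate unrooted topologies and additive distances
# ---------------------------------------------------------------------------

def enumerate_unrooted_trees(taxa):
    """All unrooted binary topologies as edge lists (leaf-addition walk)."""
    first = [("x0", taxa[0]), ("x0", taxa[1]), ("x0", taxa[2])]
    trees = [first]
    for k, leaf in enumerate(taxa[3:], start=1):
        new_node = f"x{k}"
        grown = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                g = edges[:i] + [(u, new_node), (new_node, v),
                                 (new_node, leaf)] + edges[i + 1:]
                grown.append(g)
        trees = grown
    return trees


def tree_distances_and_bipartitions(edges, taxa, rnd):
    lengths = {e: round(rnd.uniform(0.05, 0.5), 4) for e in edges}
    adj = {}
    for (u, v), ln in lengths.items():
        adj.setdefault(u, []).append((v, ln))
        adj.setdefault(v, []).append((u, ln))

    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nxt, ln in adj[node]:
                if nxt not in out:
                    out[nxt] = out[node] + ln
                    stack.append(nxt)
        return out

    n = len(taxa)
    d = np.zeros((n, n))
    for i, t in enumerate(taxa):
        row = dists_from(t)
        for j in range(n):
            d[i, j] = row[taxa[j]]

    biparts = set()
    for u, v in edges:
        # leaves on v's side with edge (u, v) removed
        side = set()
        stack = [v]
        seen = {u, v}
        while stack:
            node = stack.pop()
            if node in taxa:
                side.add(node)
            for nxt, _ in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 2 <= len(side) <= n - 2:
            biparts.add(_canonical(frozenset(side), taxa))
    return d, biparts


class TestNeighborJoining:
    def test_three_taxa_unique_topology(self):
        sm = SuperMatrix(
            taxa=["A", "B", "C"],
            matrix={"A": "MKMKMK", "B": "MKMKML", "C": "MKMLLL"},
            partitions=[("og", 0, 6)],
        )
        tree = nj_tree(sm)
        assert tree.bipartitions == set()
        assert sorted(tree.taxa) == ["A", "B", "C"]

    def test_recovers_all_4_and_5_taxon_shapes(self):
        rnd = random.Random(11)
        for taxa in (["a", "b", "c", "d"], ["a", "b", "c", "d", "e"]):
            for edges in enumerate_unrooted_trees(taxa):
                d, true_biparts = tree_distances_and_bipartitions(edges, taxa, rnd)
                got = nj_tree_from_distances(d, taxa)
                assert got.bipartitions == true_biparts

    def test_brute_force_four_point_oracle(self):
        # additive matrix for ((a,b),(c,d)); the generating topology is the
        # unique one satisfying the four-point condition
        d = np.array([[0, 3, 9, 10],
                      [3, 0, 10, 11],
                      [9, 10, 0, 7],
                      [10, 11, 7, 0]], float)
        taxa = ["a", "b", "c", "d"]
        sums = {
            frozenset({"a", "b"}): d[0, 1] + d[2, 3],
            frozenset({"a", "c"}): d[0, 2] + d[1, 3],
            frozenset({"a", "d"}): d[0, 3] + d[1, 2],
        }
        winner = min(sums, key=sums.get)
        tree = nj_tree_from_distances(d, taxa)
        assert tree.is_sister_pair(*sorted(winner))

    def test_identical_rows_are_zero_length_sisters(self):
        sm = SuperMatrix(
            taxa=["A", "B", "C", "D"],
            matrix={"A": "MKMKMKMKMK", "B": "MKMKMKMKMK",
                    "C": "LLLLLKMKMK", "D": "LLLLLLLKMK"},
            partitions=[("og", 0, 10)],
        )
        tree = nj_tree(sm)
        assert tree.is_sister_pair("A", "B")
        assert ("A:0.000000" in tree.newick) and ("B:0.000000" in tree.newick)

    def test_fewer_than_three_taxa_rejected(self):
        sm = SuperMatrix(taxa=["A", "B"], matrix={"A": "MK", "B": "ML"},
                         partitions=[("og", 0, 2)])
        with pytest.raises(ValueError):
            nj_tree(sm)

    def test_all_gap_row_rejected(self):
        sm = SuperMatrix(taxa=["A", "B", "C"],
                         matrix={"A": "--", "B": "ML", "C": "MK"},
                         partitions=[("og", 0, 2)])
        with pytest.raises(PlastophyloError):
            nj_tree(sm)

    def test_no_comparable_columns_rejected(self):
        rows = {"A": "MK--", "B": "--ML", "C": "MKML"}
        with pytest.raises(PlastophyloError, match="comparable"):
            p_distance_matrix(rows, ["A", "B", "C"])


def _strong_signal_sm():
    blocks = {
        "A": "AAAAAAAAAA" * 4, "B": "AAAAAAAAAC" * 4,
        "C": "DDDDDDDDDD" * 4, "D": "DDDDDDDDDE" * 4,
        "E": "GGGGGGGGGG" * 4,
    }
    return SuperMatrix(taxa=list(blocks), matrix=blocks,
                       partitions=[("og", 0, 40)])


class TestBootstrap:
    def test_strong_signal_gives_full_support(self):
        tree = bootstrap_support(_strong_signal_sm(), n_replicates=50, seed=3)
        assert tree.supports
        assert all(v == 100.0 for v in tree.supports.values())

    def test_single_replicate_supports_binary(self):
        tree = bootstrap_support(_strong_signal_sm(), n_replicates=1, seed=3)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_seed_determinism(self):
        sm = _strong_signal_sm()
        t1 = bootstrap_support(sm, n_replicates=20, seed=42)
        t2 = bootstrap_support(sm, n_replicates=20, seed=42)
        assert t1.newick == t2.newick and t1.supports == t2.supports

    def test_supports_annotated_in_newick(self):
        tree = bootstrap_support(_strong_signal_sm(), n_replicates=10, seed=0)
        assert ")100:" in tree.newick


class TestExportMlInputs:
    def _sm(self):
        a1 = Alignment("og1", {"A": "M" * 10, "B": "K" * 10, "C": "L" * 10})
        a2 = Alignment("og2", {"A": "W" * 7, "B": "Y" * 7})
        return concatenate([a1, a2], taxa=["A", "B", "C"])

    def test_phylip_header(self, tmp_path):
        paths = export_ml_inputs(self._sm(), tmp_path)
        header = paths["phylip"].read_text().splitlines()[0]
        assert header == "3 17"

    def test_partitions_one_based_inclusive_roundtrip(self, tmp_path):
        sm = self._sm()
        paths = export_ml_inputs(sm, tmp_path)
        text = paths["partitions"].read_text()
        assert "charset og1 = 1-10;" in text
        assert "charset og2 = 11-17;" in text
        # 1-based inclusive ranges tile the matrix exactly
        import re

        ranges = [(int(a), int(b)) for a, b in re.findall(r"= (\d+)-(\d+);", text)]
        assert ranges[0][0] == 1 and ranges[-1][1] == sm.length
        for (_, e1), (s2, _) in zip(ranges, ranges[1:]):
            assert s2 == e1 + 1

    def test_command_line_flags(self, tmp_path):
        paths = export_ml_inputs(self._sm(), tmp_path)
        cmd = paths["command"].read_text()
        assert "-bb 1000" in cmd and "-nt AUTO" in cmd and "291752" in cmd

    def test_phylip_roundtrip(self, tmp_path):
        sm = self._sm()
        paths = export_ml_inputs(sm, tmp_path)
        back = read_phylip(paths["phylip"])
        assert back.taxa == sm.taxa
        assert back.matrix == sm.matrix
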