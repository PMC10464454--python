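"""One-command orchestration: peptides -> cleaned orthogroups ->
supermatrix -> tree, with a reconciling report.

External tools (orthology inference, aligner, ML tree) are optional
command templates; when absent the built-ins are used so runs never need
network or extra binaries.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from plastophylo import __version__
from plastophylo.errors import ConfigError, PlastophyloError
from plastophylo.orthofilter import (
    Orthogroup,
    RunConfig,
    load_orthogroups,
    pretrim,
    run_postprocessing,
)
from plastophylo.seqio import SeqRecord, read_fasta
from plastophylo.supermatrix import (
    Phylogeny,
    SuperMatrix,
    align_orthogroup,
    bootstrap_support,
    concatenate,
    export_ml_inputs,
    nj_tree,
)
from plastophylo.synthdata import nj_gene_tree


@dataclass
class PipelineConfig:
    peptides_dir: Path
    species_of_interest: list[str] = field(default_factory=list)
    linked_groups: list[set[str]] = field(default_factory=list)
    outgroup: set[str] = field(default_factory=set)
    orthogroup_table: Path | None = None
    tree_dir: Path | None = None
    min_peptide_len: int = 10
    iqr_factor: float = 1.5
    aligner_cmd: str | None = None
    bootstrap_replicates: int = 100
    seed: int = 0
    outdir: Path | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        base = Path(path).parent

        def _p(key: str) -> Path | None:
            val = doc.get(key)
            return (base / val) if val else None

        return cls(
            peptides_dir=base / doc["peptides_dir"],
            species_of_interest=list(doc.get("species_of_interest", [])),
            linked_groups=[set(g) for g in doc.get("linked_groups", [])],
            outgroup=set(doc.get("outgroup", [])),
            orthogroup_table=_p("orthogroup_table"),
            tree_dir=_p("tree_dir"),
            min_peptide_len=int(doc.get("min_peptide_len", 10)),
            iqr_factor=float(doc.get("iqr_factor", 1.5)),
            aligner_cmd=doc.get("aligner_cmd"),
            bootstrap_replicates=int(doc.get("bootstrap_replicates", 100)),
            seed=int(doc.get("seed", 0)),
            outdir=_p("outdir"),
        )

    def run_config(self) -> RunConfig:
        return RunConfig(
            species_of_interest=self.species_of_interest,
            linked_groups=self.linked_groups,
            outgroup=self.outgroup,
            min_peptide_len=self.min_peptide_len,
            iqr_factor=self.iqr_factor,
        )


@dataclass
class PipelineReport:
    """Per-stage member counts; out of stage k must equal in of stage k+1."""

    stages: list[dict[str, Any]] = field(default_factory=list)
    seed: int = 0
    version: str = __version__
    config_echo: dict[str, Any] = field(default_factory=dict)

    def add(self, stage: str, n_in: int, n_out: int, **extra: Any) -> None:
        self.stages.append({"stage": stage, "in": n_in, "out": n_out, **extra})

    def reconciles(self) -> bool:
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev["out"] != nxt["in"]:
                return False
        return True

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "stages": self.stages,
                "reconciles": self.reconciles(),
                "config": self.config_echo,
            },
            indent=2,
            default=str,
        )


def _group_by_gene_tag(records: list[SeqRecord]) -> list[Orthogroup]:
    """Fallback orthology: group members by the gene tag after the '@'."""
    groups: dict[str, list[SeqRecord]] = {}
    for rec in records:
        tag = rec.id.split("@", 1)[1] if "@" in rec.id else rec.id
        # a planted paralog shares its parent's gene tag
        tag = tag.split("_p")[0]
        groups.setdefault(tag, []).append(rec)
    return [
        Orthogroup(og_id=f"OG_{tag}", members=members)
        for tag, members in sorted(groups.items())
    ]


def run_pipeline(
    cfg: PipelineConfig,
) -> tuple[SuperMatrix, Phylogeny, PipelineReport]:
    report = PipelineReport(seed=cfg.seed, config_echo={
        "peptides_dir": cfg.peptides_dir,
        "species_of_interest": cfg.species_of_interest,
        "linked_groups": [sorted(g) for g in cfg.linked_groups],
        "outgroup": sorted(cfg.outgroup),
        "min_peptide_len": cfg.min_peptide_len,
        "iqr_factor": cfg.iqr_factor,
        "bootstrap_replicates": cfg.bootstrap_replicates,
    })

    # --- load peptides (one FASTA per species)
    fasta_files = sorted(Path(cfg.peptides_dir).glob("*.fasta"))
    if not fasta_files:
        raise ConfigError(f"no FASTA files in {cfg.peptides_dir}")
    records: list[SeqRecord] = []
    species_seen: set[str] = set()
    for fa in fasta_files:
        recs = read_fasta(fa, moltype="aa")
        species = fa.stem
        records.extend(
            SeqRecord(id=r.id, seq=r.seq, species=r.species or species,
                      moltype="aa")
            for r in recs
        )
        species_seen.add(species)

    # --- role check before any compute
    roles = set(cfg.species_of_interest) | cfg.outgroup
    for group in cfg.linked_groups:
        roles |= set(group)
    missing = roles - species_seen
    if missing:
        raise ConfigError(f"role species missing from inputs: {sorted(missing)}")

    run_cfg = cfg.run_config()

    # --- pretrim
    kept, pre_report = pretrim(records, run_cfg)
    report.add("pretrim", len(records), len(kept),
               duplicates=pre_report.duplicates_removed,
               asterisks=pre_report.asterisk_removed,
               short=pre_report.short_removed)

    # --- orthogroups (provided table or gene-tag fallback)
    if cfg.orthogroup_table is not None:
        ogs = load_orthogroups(cfg.orthogroup_table, kept, tree_dir=cfg.tree_dir)
    else:
        ogs = _group_by_gene_tag(kept)
    n_members = sum(len(og.members) for og in ogs)
    report.add("group", len(kept), n_members, orthogroups=len(ogs))

    # --- gene trees for step 1 where missing and computable
    for og in ogs:
        if og.gene_tree is None and len(og.members) >= 3:
            if len({len(m.seq) for m in og.members}) == 1:
                og.gene_tree = nj_gene_tree(og)

    # --- four-step cleaning
    cleaned, post_report = run_postprocessing(ogs, run_cfg)
    cleaned = [og for og in cleaned if og.members]
    n_cleaned_members = sum(len(og.members) for og in cleaned)
    report.add(
        "postprocess", n_members, n_cleaned_members,
        ogs_in=len(ogs), ogs_kept=len(cleaned),
        step1_members_removed=len(post_report.removals(1)),
        step2_ogs_discarded=len(post_report.removals(2)),
        step3_ogs_discarded=len(post_report.removals(3)),
        step4_members_removed=len(post_report.removals(4)),
    )
    if not cleaned:
        raise PlastophyloError("empty supermatrix: no orthogroups survived filtering")

    # --- align + concatenate
    alignments = [align_orthogroup(og, aligner_cmd=cfg.aligner_cmd)
                  for og in cleaned]
    n_rows = sum(len(a.rows) for a in alignments)
    report.add("align", n_cleaned_members, n_rows)

    taxa_order = list(dict.fromkeys(
        cfg.species_of_interest
        + [sp for group in cfg.linked_groups for sp in sorted(group)]
        + sorted(cfg.outgroup)
    ))
    sm = concatenate(alignments, taxa=taxa_order)
    report.add("concatenate", n_rows, n_rows,
               taxa=len(sm.taxa), columns=sm.length)

    # --- tree
    if cfg.bootstrap_replicates > 0:
        tree = bootstrap_support(sm, n_replicates=cfg.bootstrap_replicates,
                                 seed=cfg.seed)
    else:
        tree = nj_tree(sm)

    # --- outputs
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        export_ml_inputs(sm, outdir)
        (outdir / "tree.nwk").write_text(tree.newick + "\n")
        (outdir / "report.json").write_text(report.to_json() + "\n")
    return sm, tree, report
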