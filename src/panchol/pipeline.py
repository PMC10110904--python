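"""End-to-end orchestration: simulate -> cluster -> partition -> profile ->
contrast -> screen -> ani -> tree, from a single YAML config.

A run config either names per-strain input files (protein FASTA + annotation
TSV, optional genome FASTA) or contains a ``simulate`` block with
:class:`~panchol.simulate.PangenomeConfig` fields. Stages run in dependency
order; the contrast stage is skipped with a warning when no group labels are
configured, and the screen/ANI stages when no panel/genomes are available.
Re-running with an identical config and seed reproduces byte-identical
outputs (the report records a config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .align import AlignParams
from .ani import AniParams, ani_matrix, divergence_matrix, neighbor_joining, write_newick
from .cog import abundance, fold_abundance, group_exclusive
from .io import (
    RunConfig,
    StrainProteome,
    logger,
    read_genome_fasta,
    read_proteome,
    write_json,
    write_matrix_tsv,
    write_summary,
)
from .markers import read_panel, screen
from .orthogroups import infer_orthogroups, orthogroups_to_frame
from .partition import classify, summarize
from .simulate import GroundTruth, PangenomeConfig, generate_genomes, generate_pangenome, write_pangenome


@dataclass
class RunReport:
    """Paths and provenance of one full run; all referenced files exist."""

    out_dir: Path
    artifacts: dict[str, str]
    config_hash: str
    seed: int
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "artifacts": dict(sorted(self.artifacts.items())),
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
        }


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "simulate" not in cfg and "strains" not in cfg:
        raise ValueError("run config needs either a 'simulate' block or a 'strains' table")
    return cfg


def _load_inputs(cfg: dict, out_dir: Path):
    """Resolve proteomes/genomes/groups either from disk or from simulation."""
    groups: dict[str, list[str]] = {}
    truth: Optional[GroundTruth] = None
    if "simulate" in cfg:
        sim_cfg = PangenomeConfig(**(cfg["simulate"] or {}))
        proteomes, truth = generate_pangenome(sim_cfg)
        write_pangenome(proteomes, truth, out_dir / "simulated")
        genomes, _ = generate_genomes(sim_cfg)
        groups = {g: list(m) for g, m in sim_cfg.groups.items()}
        return proteomes, genomes, groups, truth
    proteomes: list[StrainProteome] = []
    genomes = []
    missing = []
    for entry in cfg["strains"]:
        for key in ("fasta", "annotation", "genome"):
            p = entry.get(key)
            if p and not Path(p).exists():
                missing.append(p)
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    for entry in cfg["strains"]:
        prot = read_proteome(
            entry["fasta"],
            entry.get("annotation"),
            strain_id=entry["id"],
            group_label=entry.get("group"),
        )
        proteomes.append(prot)
        if entry.get("group"):
            groups.setdefault(entry["group"], []).append(entry["id"])
        if entry.get("genome"):
            genomes.append(read_genome_fasta(entry["genome"], entry["id"]))
    return proteomes, genomes, groups, truth


def run_all(config_path: str | Path, out_dir: str | Path) -> RunReport:
    """Run every stage and write the full report bundle under ``out_dir``."""
    cfg = load_run_config(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run_cfg = RunConfig(**(cfg.get("params") or {}))
    align_params = AlignParams(
        matrix=run_cfg.substitution_matrix,
        gap_open=run_cfg.gap_open,
        gap_extend=run_cfg.gap_extend,
    )
    artifacts: dict[str, str] = {}

    def record(name: str, path: Path) -> Path:
        artifacts[name] = str(path.relative_to(out_dir))
        return path

    stage = "inputs"
    try:
        proteomes, genomes, groups, truth = _load_inputs(cfg, out_dir)

        stage = "cluster"
        ogs, matrix, hits = infer_orthogroups(
            proteomes,
            align_params,
            min_rbh_identity_pct=run_cfg.min_rbh_identity_pct,
            min_rbh_coverage_pct=run_cfg.min_rbh_coverage_pct,
            prefilter_k=run_cfg.prefilter_k,
            prefilter_min_shared=run_cfg.prefilter_min_shared,
        )
        hits.to_tsv(record("hits", out_dir / "hits.tsv"))
        write_matrix_tsv(
            matrix.counts, record("matrix", out_dir / "presence_matrix.tsv"),
            index_name="orthogroup_id",
        )

        stage = "partition"
        labels = classify(matrix)
        summary = summarize(matrix, labels)
        write_summary(summary, record("summary_json", out_dir / "partition_summary.json"))
        write_summary(summary, record("summary_tsv", out_dir / "partition_summary.tsv"),
                      format="tsv")
        og_frame = orthogroups_to_frame(ogs)
        og_frame["partition"] = og_frame["orthogroup_id"].map(
            {k: v.value for k, v in labels.items()}
        )
        og_frame.to_csv(record("orthogroups", out_dir / "orthogroups.tsv"),
                        sep="\t", index=False, lineterminator="\n")

        stage = "profile"
        tables = [abundance(ogs, labels, scope) for scope in ("core", "accessory", "unique")]
        for g in sorted(groups):
            tables.append(
                abundance(ogs, labels, g, groups=groups, restrict_to="accessory")
            )
        profile = pd.concat(tables, ignore_index=True)
        profile.to_csv(record("abundance", out_dir / "abundance.tsv"),
                       sep="\t", index=False, float_format="%.4f", lineterminator="\n")

        stage = "contrast"
        if len(groups) >= 2:
            if "contrast" in cfg:
                ga, gb = cfg["contrast"]["group_a"], cfg["contrast"]["group_b"]
            elif "simulate" in cfg:
                sim = PangenomeConfig(**(cfg["simulate"] or {}))
                ga, gb = sim.marker_present_group, sim.marker_absent_group
            else:
                ga, gb = sorted(groups)[:2]
            contrast = group_exclusive(matrix, groups[ga], groups[gb])
            write_json(contrast.to_dict(), record("contrast", out_dir / "contrast.json"))
        else:
            logger.warning("contrast stage skipped: fewer than two strain groups configured")

        stage = "screen"
        if cfg.get("panel"):
            panel = read_panel(cfg["panel"].get("fasta"), cfg["panel"].get("categories"))
            for prot in proteomes:
                result = screen(
                    prot,
                    panel,
                    min_identity_pct=run_cfg.screen_min_identity_pct,
                    min_query_coverage_pct=run_cfg.screen_min_query_coverage_pct,
                    params=align_params,
                )
                result.to_frame().to_csv(
                    record(f"screen_{prot.strain_id}", out_dir / f"screen_{prot.strain_id}.tsv"),
                    sep="\t", index=False, lineterminator="\n",
                )

        stage = "ani"
        if genomes:
            ani_params = AniParams(
                fragment_length=run_cfg.ani_fragment_length,
                min_fragment_identity_pct=run_cfg.ani_min_fragment_identity_pct,
                min_fragment_coverage_pct=run_cfg.ani_min_fragment_coverage_pct,
            )
            dm = ani_matrix(genomes, ani_params)
            write_matrix_tsv(dm.ani.round(4), record("ani", out_dir / "ani.tsv"),
                             index_name="strain")
            div = divergence_matrix(dm)
            write_matrix_tsv(div.round(4), record("divergence", out_dir / "divergence.tsv"),
                             index_name="strain")

            stage = "tree"
            tree = neighbor_joining(div)
            write_newick(tree, record("tree", out_dir / "tree.nwk"))

    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = RunReport(
        out_dir=out_dir,
        artifacts=artifacts,
        config_hash=_config_hash(cfg),
        seed=int(cfg.get("simulate", {}).get("seed", run_cfg.seed)),
    )
    write_json(report.to_dict(), out_dir / "report.json")
    for rel in artifacts.values():
        if not (out_dir / rel).exists():
            raise RuntimeError(f"report references missing artifact {rel}")
    return report
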