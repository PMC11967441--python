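"""End-to-end orchestration: counts -> QC -> DE -> clustering -> phase ->
QTL/QTN integration -> report.

The pipeline reproduces the analysis flow of a two-line, five-stage ear
transcriptome comparison: quality-check replicates and drop outliers,
call line-specific DEGs per stage and development-specific DEGs between
consecutive stages, cluster line-specific DEG trajectories per line,
partition the stages into two phases, and intersect the Phase-I
line-specific DEG union with QTL hotspots and QTN flanking windows to call
candidate genes.  Every artifact is a TSV/JSON file and every count in the
report equals the corresponding artifact's row count.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, expression, qtl
from .clustering import FuzzyCMeans, score_phase_splits, standardize_profiles
from .synthdata import SimulationConfig, simulate_experiment, simulate_genetic_maps

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, code: str = "stage_failure"):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    outdir: str = "earphase_run"
    # inputs; when None the synthetic generator supplies them
    counts: str | None = None
    samples: str | None = None
    annotation: str | None = None
    qtl: str | None = None
    qtn: str | None = None
    tf_table: str | None = None
    chrom_lengths: str | None = None        # TSV chrom<TAB>length; synthetic default
    simulate: bool = True
    # thresholds
    min_fc: float = 2.0
    alpha: float = 0.05
    min_count: float = 10.0
    flank: int = 100_000
    min_support: int = 2
    require_distinct_studies: bool = True
    min_sibling_corr: float = 0.95
    # clustering
    n_clusters: int = 4
    fuzzifier: float = 2.0
    restarts: int = 10
    tol: float = 1e-6
    # phase: "auto" or e.g. "V6,V7,V8|V9,V10"
    phase: str = "auto"
    seed: int = 0

    def phase_override(self) -> list[str] | None:
        if self.phase == "auto":
            return None
        try:
            phase1, _ = self.phase.split("|")
            return [s.strip() for s in phase1.split(",") if s.strip()]
        except ValueError as exc:
            raise PipelineError("config", f"malformed phase spec {self.phase!r}", "config_error") from exc


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError("config", f"unknown config keys: {sorted(unknown)}", "config_error")
    return PipelineConfig(**raw)


def _read_tsv(path: str, stage: str, index_col=None) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=index_col)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, f"cannot parse {path}: {exc}", "input_parse_error") from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        sim = SimulationConfig(seed=config.seed)
        data = simulate_experiment(sim)
        maps = simulate_genetic_maps(sim)
        return data.counts, data.samples, data.annotation, maps.qtls, maps.qtns, dict(sim.chrom_lengths), None
    for name in ("counts", "samples", "annotation", "qtl", "qtn"):
        if getattr(config, name) is None:
            raise PipelineError("inputs", f"missing required input: {name}", "config_error")
    counts = _read_tsv(config.counts, "inputs", index_col=0)
    samples = _read_tsv(config.samples, "inputs")
    annotation = _read_tsv(config.annotation, "inputs")
    qtls = _read_tsv(config.qtl, "inputs")
    qtns = _read_tsv(config.qtn, "inputs")
    if config.chrom_lengths:
        cl = _read_tsv(config.chrom_lengths, "inputs")
        chrom_lengths = dict(zip(cl.iloc[:, 0], cl.iloc[:, 1].astype(int)))
    else:
        # infer lengths generously from every coordinate source supplied
        chrom_lengths: dict[str, int] = {}
        for frame, col in ((annotation, "end"), (qtls, "end")):
            for c, sub in frame.groupby("chrom"):
                chrom_lengths[c] = max(chrom_lengths.get(c, 0), int(sub[col].max()))
        for c, sub in qtns.groupby("chrom"):
            chrom_lengths[c] = max(chrom_lengths.get(c, 0), int(sub["pos"].max()))
    tf = _read_tsv(config.tf_table, "inputs") if config.tf_table else None
    return counts, samples, annotation, qtls, qtns, chrom_lengths, tf


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the report dict."""
    counts, sheet, annotation, qtls, qtns, chrom_lengths, tf = _load_inputs(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(dict.fromkeys(sheet["stage"]))
    lines = list(dict.fromkeys(sheet["line"]))
    if len(lines) != 2:
        raise PipelineError("inputs", f"need exactly two lines, got {lines}", "config_error")

    # ---- QC ----------------------------------------------------------------
    lengths = annotation.set_index("gene_id")["length"]
    fpkm = expression.compute_fpkm(counts, lengths)
    corr = expression.sample_correlation(fpkm, method="spearman")
    flagged = expression.flag_outlier_replicates(corr, sheet, config.min_sibling_corr)
    excluded = {f["sample"] for f in flagged}
    if excluded:
        logger.info("QC excluded replicates: %s", sorted(excluded))
    stage_means = expression.stage_mean_fpkm(fpkm, sheet, exclude=excluded)
    bins = expression.classify_expression(stage_means)
    pca_coords, var_explained = expression.pca_samples(fpkm)

    keep_sheet = sheet[~sheet["sample"].isin(excluded)]
    keep_counts = counts[keep_sheet["sample"].tolist()]
    size_factors = diffexp.median_of_ratios_size_factors(keep_counts)

    # ---- differential expression ------------------------------------------
    line_specific: dict[str, dict[str, set[str]]] = {}
    de_counts: dict[str, dict[str, int]] = {}
    for stage in stages:
        grp = keep_sheet[keep_sheet["stage"] == stage]
        cols = grp["sample"].tolist()
        res = diffexp.nb_wald_contrast(
            keep_counts[cols],
            grp["line"].to_numpy(),
            size_factors=size_factors[cols],
            min_count=config.min_count,
        )
        res.to_csv(outdir / f"de_line_{stage}.tsv", sep="\t")
        sets = diffexp.call_degs(res, min_fc=config.min_fc, alpha=config.alpha)
        line_specific[stage] = sets
        de_counts[stage] = {"up": len(sets["up"]), "down": len(sets["down"])}
        logger.info(
            "line contrast %s: %d up, %d down", stage, len(sets["up"]), len(sets["down"])
        )

    development_specific: dict[str, dict[str, set[str]]] = {}
    for line in lines:
        development_specific[line] = {}
        for s1, s2 in zip(stages[:-1], stages[1:]):
            grp = keep_sheet[(keep_sheet["line"] == line) & keep_sheet["stage"].isin([s1, s2])]
            cols = grp["sample"].tolist()
            res = diffexp.nb_wald_contrast(
                keep_counts[cols],
                grp["stage"].to_numpy(),
                size_factors=size_factors[cols],
                min_count=config.min_count,
            )
            sets = diffexp.call_degs(res, min_fc=config.min_fc, alpha=config.alpha)
            development_specific[line][f"{s1}|{s2}"] = sets

    union = set().union(
        *(line_specific[s]["up"] | line_specific[s]["down"] for s in stages)
    )

    # ---- trajectory clustering and phase partition -------------------------
    cluster_sizes: dict[str, dict[str, int]] = {}
    phase_inputs = []
    membership_frames = []
    for line in lines:
        cols = [f"{line}_{s}" for s in stages]
        prof_raw = stage_means.loc[sorted(union & set(stage_means.index)), cols]
        prof_raw.columns = stages
        profiles, _ = standardize_profiles(np.log2(prof_raw + 1.0))
        if len(profiles) >= config.n_clusters:
            model = FuzzyCMeans(
                n_clusters=config.n_clusters,
                m=config.fuzzifier,
                tol=config.tol,
                n_init=config.restarts,
                random_state=config.seed,
            ).fit(profiles)
            sizes = pd.Series(model.labels_).value_counts().sort_index()
            cluster_sizes[line] = {f"cluster{k + 1}": int(sizes.get(k, 0)) for k in range(config.n_clusters)}
            mem = model.membership_.copy()
            mem.insert(0, "line", line)
            membership_frames.append(mem)
        else:
            cluster_sizes[line] = {}
        phase_inputs.append(profiles.T)  # stages x genes

    override = config.phase_override()
    if override is not None:
        phase1 = [s for s in stages if s in override]
        partition_scores = None
    else:
        stage_vectors = pd.concat(phase_inputs, axis=1)
        stage_vectors.index = stages
        partition = score_phase_splits(stage_vectors)
        phase1 = partition.phase1
        partition_scores = partition.scores
    phase2 = [s for s in stages if s not in phase1]

    deg_sets = diffexp.build_deg_sets(line_specific, development_specific, stages, phase1)
    if membership_frames:
        pd.concat(membership_frames).to_csv(outdir / "memberships.tsv", sep="\t")

    # ---- QTL/QTN integration ----------------------------------------------
    validated = qtl.build_intervals(qtls, chrom_lengths)
    hotspots = qtl.merge_hotspots(
        validated,
        min_support=config.min_support,
        require_distinct_studies=config.require_distinct_studies,
    )
    windows = qtl.qtn_flanks(qtns, chrom_lengths, flank=config.flank)
    candidates = qtl.call_candidates(deg_sets.phase1_union, hotspots, windows, annotation)
    if tf is not None:
        annotated, tally = qtl.annotate_tfs(candidates.candidates, tf)
        annotated.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        tally.to_csv(outdir / "tf_tally.tsv", sep="\t", index=False)
    else:
        candidates.candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    hs_frame = pd.DataFrame(
        [
            (h.hotspot_id, h.chrom, h.start, h.end, h.support, h.n_studies,
             ",".join(h.member_qtls))
            for h in hotspots
        ],
        columns=["hotspot_id", "chrom", "start", "end", "support", "n_studies", "members"],
    )
    hs_frame.to_csv(outdir / "hotspots.tsv", sep="\t", index=False)
    windows.to_csv(outdir / "qtn_windows.tsv", sep="\t", index=False)

    # ---- report ------------------------------------------------------------
    report = {
        "config": asdict(config),
        "qc": {
            "n_samples": int(counts.shape[1]),
            "excluded_replicates": sorted(excluded),
            "expressed_genes_per_stage": {
                c: int(v) for c, v in bins.expressed_counts.items()
            },
            "pca_variance_explained": [float(v) for v in var_explained],
        },
        "degs": {
            "line_specific_per_stage": de_counts,
            "all_stage_union": len(deg_sets.all_stage_union),
            "phase1_union": len(deg_sets.phase1_union),
            "phase2_union": len(deg_sets.phase2_union),
            "venn_region_sizes": {k: len(v) for k, v in deg_sets.venn.items() if v},
        },
        "phase": {"phase1": phase1, "phase2": phase2,
                  "scores": partition_scores.to_dict(orient="records") if partition_scores is not None else None},
        "clusters": cluster_sizes,
        "integration": candidates.counts,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    manifest = {
        "seed": config.seed,
        "artifacts": {
            p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv")) if p.is_file()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    pca_coords.to_csv(outdir / "pca.tsv", sep="\t")
    return report
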