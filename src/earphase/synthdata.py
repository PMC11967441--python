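"""Synthetic two-line, five-stage ear transcriptome experiments with ground truth.

Generates negative-binomial count matrices shaped like the real study design
(2 inbred lines x 5 vegetative stages V6..V10 x 3 biological replicates = 30
libraries), gene annotations on synthetic chromosomes, and compiled QTL/QTN
maps with planted cross-study hotspot structure.  Every planted effect (line
fold change, temporal archetype, hotspot membership) is recorded in
:class:`TruthLabels` so downstream estimators can be scored against a known
answer.

All randomness flows from one integer seed through named substreams, so each
component (counts, annotation, genetic maps) can be regenerated independently
and reproducibly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "HotspotSpec",
    "TruthLabels",
    "ExperimentData",
    "GeneticMaps",
    "simulate_experiment",
    "simulate_genetic_maps",
    "write_experiment",
    "write_genetic_maps",
]

#: Temporal archetype shapes on the log2 scale, one row per archetype, one
#: column per stage.  The regime change sits between stage 3 (V8) and stage 4
#: (V9): archetypes 0 and 3 reverse direction there, archetypes 1 and 2 are
#: flat through the first phase and move only afterwards.
ARCHETYPE_SHAPES = np.array(
    [
        [0.0, 0.5, 1.0, -0.5, -1.0],   # rise to V8, then fall
        [-0.5, -0.5, -0.5, -0.5, 1.5],  # flat, spike at V10
        [-0.5, -0.5, -0.5, 1.5, 0.2],   # spike at V9
        [1.0, 0.5, 0.0, -1.0, -0.5],    # monotone decline, slight uptick
    ]
)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class HotspotSpec:
    """A planted hotspot: ``support`` QTLs from distinct studies overlap here."""

    chrom: str
    start: int
    end: int
    support: int = 2

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ConfigurationError(f"invalid hotspot span {self.start}-{self.end}")
        if self.support < 2:
            raise ConfigurationError("a planted hotspot needs support >= 2")


def _default_chrom_lengths() -> dict[str, int]:
    return {f"chr{i}": 20_000_000 for i in range(1, 11)}


def _default_hotspots() -> list[HotspotSpec]:
    return [
        HotspotSpec("chr1", 2_000_000, 4_500_000, support=3),
        HotspotSpec("chr4", 9_000_000, 10_200_000, support=2),
        HotspotSpec("chr5", 15_000_000, 16_800_000, support=4),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Counts follow NB(mean = s_j * q_g * 2^(archetype + line effect), alpha_g)
    with Var = mu + alpha * mu^2.  A ``de_fraction`` of genes carries a line
    effect with |log2FC| >= 1 drawn as 1 + Exponential(lfc_scale) with random
    sign; dispersions are log-normal; per-library size factors are realised by
    scaling each library's expected total into ``libsize_range``.
    """

    n_lines: int = 2
    line_names: tuple[str, ...] = ("PHG35", "Dan598")
    stages: tuple[str, ...] = ("V6", "V7", "V8", "V9", "V10")
    n_reps: int = 3
    n_genes: int = 2000
    de_fraction: float = 0.15
    lfc_scale: float = 0.7
    dispersion_meanlog: float = float(np.log(0.05))
    dispersion_sdlog: float = 0.5
    basemean_meanlog: float = float(np.log(50.0))
    basemean_sdlog: float = 1.5
    libsize_range: tuple[float, float] = (1_000_000.0, 2_000_000.0)
    archetype_weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    archetype_amplitude: float = 1.0
    phase_shift_stage: int = 3
    n_studies: int = 5
    n_qtl_per_study: int = 4
    qtl_length_range: tuple[int, int] = (500_000, 2_000_000)
    hotspot_spec: list[HotspotSpec] = field(default_factory=_default_hotspots)
    n_qtns: int = 30
    qtn_in_hotspot_fraction: float = 0.3
    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    gene_length_meanlog: float = float(np.log(3000.0))
    gene_length_sdlog: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lines, self.n_reps, self.n_genes, len(self.stages)) < 1:
            raise ConfigurationError("n_lines, n_reps, n_genes and stages must be positive")
        if self.n_lines != len(self.line_names):
            raise ConfigurationError("line_names must match n_lines")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError("de_fraction must lie in [0, 1]")
        if abs(sum(self.archetype_weights) - 1.0) > 1e-9:
            raise ConfigurationError("archetype_weights must sum to 1")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ConfigurationError("chromosome lengths must be positive")
        if not 1 <= self.phase_shift_stage < len(self.stages):
            raise ConfigurationError("phase_shift_stage must split the stages")
        for spec in self.hotspot_spec:
            if spec.chrom not in self.chrom_lengths:
                raise ConfigurationError(f"hotspot on unknown chromosome {spec.chrom}")
            if spec.end > self.chrom_lengths[spec.chrom]:
                raise ConfigurationError(
                    f"hotspot {spec.chrom}:{spec.start}-{spec.end} exceeds chromosome length"
                )


@dataclass
class TruthLabels:
    """Ground truth planted by the generator, used for parameter recovery."""

    is_de: pd.Series                      # per gene, line effect present
    true_log2fc: pd.Series                # second line over first; 0 where not DE
    archetype: pd.Series                  # archetype id per gene
    gene_spans: pd.DataFrame              # gene_id, chrom, start, end (1-based inclusive)
    planted_hotspots: list[dict] = field(default_factory=list)
    qtl_hotspot_membership: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "is_de": self.is_de.astype(bool).to_dict(),
            "true_log2fc": self.true_log2fc.to_dict(),
            "archetype": self.archetype.astype(int).to_dict(),
            "gene_spans": self.gene_spans.to_dict(orient="records"),
            "planted_hotspots": self.planted_hotspots,
            "qtl_hotspot_membership": self.qtl_hotspot_membership,
        }
        return json.dumps(payload, indent=1)


@dataclass
class ExperimentData:
    counts: pd.DataFrame        # genes x samples, integer
    samples: pd.DataFrame       # sample, line, stage, replicate
    annotation: pd.DataFrame    # gene_id, chrom, start, end, strand, length
    truth: TruthLabels


@dataclass
class GeneticMaps:
    qtls: pd.DataFrame          # qtl_id, study_id, chrom, start, end, lod, pve
    qtns: pd.DataFrame          # qtn_id, study_id, chrom, pos
    truth: TruthLabels


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: independent generator derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stream.encode())]))


def _place_nonoverlapping(rng: np.random.Generator, lengths: np.ndarray, chrom_len: int) -> np.ndarray:
    """Place intervals of given lengths without overlap; returns 1-based starts."""
    total = int(lengths.sum())
    free = chrom_len - total
    if free < len(lengths):
        raise ConfigurationError("chromosome too short for requested gene spans")
    gaps = rng.dirichlet(np.ones(len(lengths) + 1)) * free
    gaps = np.floor(gaps).astype(int)
    starts = np.empty(len(lengths), dtype=int)
    pos = 1
    for i, (gap, ln) in enumerate(zip(gaps[:-1], lengths)):
        pos += int(gap)
        starts[i] = pos
        pos += int(ln)
    return starts


def _make_annotation(config: SimulationConfig) -> pd.DataFrame:
    rng = _rng(config.seed, "annotation")
    chroms = list(config.chrom_lengths)
    assign = rng.integers(0, len(chroms), size=config.n_genes)
    lengths = np.maximum(
        200,
        rng.lognormal(config.gene_length_meanlog, config.gene_length_sdlog, config.n_genes),
    ).astype(int)
    gene_ids = np.array([f"gene{i:05d}" for i in range(config.n_genes)])
    rows = []
    for ci, chrom in enumerate(chroms):
        mask = assign == ci
        if not mask.any():
            continue
        starts = _place_nonoverlapping(rng, lengths[mask], config.chrom_lengths[chrom])
        for gid, st, ln in zip(gene_ids[mask], starts, lengths[mask]):
            rows.append((gid, chrom, int(st), int(st + ln - 1), "+" if rng.random() < 0.5 else "-", int(ln)))
    ann = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "length"])
    return ann.set_index("gene_id").loc[gene_ids].reset_index()


def simulate_experiment(config: SimulationConfig | None = None) -> ExperimentData:
    """Draw a full synthetic count experiment with ground-truth labels.

    Returns counts (genes x libraries), the sample sheet, a gene annotation on
    the synthetic chromosomes and :class:`TruthLabels`.  Deterministic given
    ``config.seed``.
    """
    config = config or SimulationConfig()
    n_stages = len(config.stages)
    gene_ids = [f"gene{i:05d}" for i in range(config.n_genes)]

    rng = _rng(config.seed, "counts")
    base_mean = rng.lognormal(config.basemean_meanlog, config.basemean_sdlog, config.n_genes)
    alpha = rng.lognormal(config.dispersion_meanlog, config.dispersion_sdlog, config.n_genes)
    archetype = rng.choice(len(config.archetype_weights), size=config.n_genes, p=config.archetype_weights)

    is_de = rng.random(config.n_genes) < config.de_fraction
    magnitude = 1.0 + rng.exponential(config.lfc_scale, config.n_genes)
    sign = rng.choice([-1.0, 1.0], size=config.n_genes)
    true_lfc = np.where(is_de, magnitude * sign, 0.0)

    shapes = ARCHETYPE_SHAPES[:, :n_stages] * config.archetype_amplitude
    stage_effect = shapes[archetype]                       # genes x stages, log2

    samples = []
    count_cols: dict[str, np.ndarray] = {}
    for li, line in enumerate(config.line_names):
        # second line carries the planted fold change (log2FC of line 2 over line 1)
        line_log2 = true_lfc if li == 1 else np.zeros(config.n_genes)
        for si, stage in enumerate(config.stages):
            mu_gene = base_mean * 2.0 ** (stage_effect[:, si] + line_log2)
            for rep in range(1, config.n_reps + 1):
                name = f"{line[0]}_{stage}_{rep}"
                target = rng.uniform(
                    config.libsize_range[0] * 1.15, config.libsize_range[1] * 0.85
                )
                s_j = target / mu_gene.sum()
                mu = s_j * mu_gene
                # NB(mean mu, dispersion alpha): gamma-Poisson mixture
                lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
                count_cols[name] = rng.poisson(lam)
                samples.append((name, line, stage, rep))

    counts = pd.DataFrame(count_cols, index=pd.Index(gene_ids, name="gene_id"))
    sheet = pd.DataFrame(samples, columns=["sample", "line", "stage", "replicate"])
    annotation = _make_annotation(config)

    truth = TruthLabels(
        is_de=pd.Series(is_de, index=gene_ids, name="is_de"),
        true_log2fc=pd.Series(true_lfc, index=gene_ids, name="true_log2fc"),
        archetype=pd.Series(archetype, index=gene_ids, name="archetype"),
        gene_spans=annotation[["gene_id", "chrom", "start", "end"]].copy(),
    )
    return ExperimentData(counts=counts, samples=sheet, annotation=annotation, truth=truth)


def _sample_background_qtl(
    rng: np.random.Generator,
    config: SimulationConfig,
    blocked: dict[str, list[tuple[int, int]]],
) -> tuple[str, int, int]:
    """One background QTL disjoint from every blocked interval (rejection)."""
    chroms = list(config.chrom_lengths)
    lo, hi = config.qtl_length_range
    for _ in range(10_000):
        chrom = chroms[rng.integers(0, len(chroms))]
        length = int(rng.integers(lo, hi + 1))
        chrom_len = config.chrom_lengths[chrom]
        if length >= chrom_len:
            continue
        start = int(rng.integers(1, chrom_len - length + 1))
        end = start + length - 1
        if all(end < b0 or start > b1 for b0, b1 in blocked.get(chrom, [])):
            blocked.setdefault(chrom, []).append((start, end))
            return chrom, start, end
    raise ConfigurationError("could not place background QTLs without overlap")


def simulate_genetic_maps(config: SimulationConfig | None = None) -> GeneticMaps:
    """Compile synthetic QTL and QTN tables with planted hotspots.

    Each planted hotspot is realised by ``support`` QTLs from distinct study
    ids, every one covering the planted span, so single-linkage merging must
    recover an interval containing it.  Background QTLs are placed pairwise
    disjoint and away from planted regions, so no accidental hotspot forms.
    QTNs land inside planted hotspots with probability
    ``qtn_in_hotspot_fraction``.
    """
    config = config or SimulationConfig()
    rng = _rng(config.seed, "genetic_maps")
    study_ids = [f"study{s + 1}" for s in range(config.n_studies)]

    qtl_rows: list[tuple] = []
    membership: dict[str, int] = {}
    planted: list[dict] = []
    blocked: dict[str, list[tuple[int, int]]] = {}
    qtl_counter = 0

    if config.n_studies > 0:
        for h_idx, spec in enumerate(config.hotspot_spec):
            if spec.support > config.n_studies:
                raise ConfigurationError(
                    f"hotspot support {spec.support} exceeds n_studies={config.n_studies}"
                )
            chrom_len = config.chrom_lengths[spec.chrom]
            members = rng.choice(config.n_studies, size=spec.support, replace=False)
            env_start, env_end = spec.start, spec.end
            for study_i in members:
                jitter_l = int(rng.integers(0, 200_001))
                jitter_r = int(rng.integers(0, 200_001))
                start = max(1, spec.start - jitter_l)
                end = min(chrom_len, spec.end + jitter_r)
                qtl_id = f"qtl{qtl_counter:03d}"
                qtl_counter += 1
                qtl_rows.append(
                    (qtl_id, study_ids[study_i], spec.chrom, start, end,
                     round(rng.uniform(2.6, 27.6), 2), round(rng.uniform(1.5, 28.4), 2))
                )
                membership[qtl_id] = h_idx
                env_start, env_end = min(env_start, start), max(env_end, end)
            blocked.setdefault(spec.chrom, []).append((env_start, env_end))
            planted.append(
                {"hotspot_idx": h_idx, "chrom": spec.chrom, "start": spec.start,
                 "end": spec.end, "support": spec.support}
            )

        n_planted = sum(s.support for s in config.hotspot_spec)
        n_background = max(0, config.n_studies * config.n_qtl_per_study - n_planted)
        for _ in range(n_background):
            chrom, start, end = _sample_background_qtl(rng, config, blocked)
            qtl_id = f"qtl{qtl_counter:03d}"
            qtl_counter += 1
            qtl_rows.append(
                (qtl_id, study_ids[rng.integers(0, config.n_studies)], chrom, start, end,
                 round(rng.uniform(2.6, 27.6), 2), round(rng.uniform(1.5, 28.4), 2))
            )
            membership[qtl_id] = -1

    qtls = pd.DataFrame(
        qtl_rows, columns=["qtl_id", "study_id", "chrom", "start", "end", "lod", "pve"]
    )

    qtn_rows = []
    planted_specs = config.hotspot_spec if config.n_studies > 0 else []
    for q in range(config.n_qtns):
        qtn_id = f"qtn{q:03d}"
        study = study_ids[rng.integers(0, config.n_studies)] if study_ids else "studyNA"
        if planted_specs and rng.random() < config.qtn_in_hotspot_fraction:
            spec = planted_specs[rng.integers(0, len(planted_specs))]
            pos = int(rng.integers(spec.start, spec.end + 1))
            qtn_rows.append((qtn_id, study, spec.chrom, pos))
        else:
            chroms = list(config.chrom_lengths)
            for _ in range(10_000):
                chrom = chroms[rng.integers(0, len(chroms))]
                pos = int(rng.integers(1, config.chrom_lengths[chrom] + 1))
                inside_planted = any(
                    s.chrom == chrom and s.start <= pos <= s.end for s in planted_specs
                )
                if not inside_planted:
                    qtn_rows.append((qtn_id, study, chrom, pos))
                    break
    qtns = pd.DataFrame(qtn_rows, columns=["qtn_id", "study_id", "chrom", "pos"])

    truth = TruthLabels(
        is_de=pd.Series(dtype=bool),
        true_log2fc=pd.Series(dtype=float),
        archetype=pd.Series(dtype=int),
        gene_spans=pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]),
        planted_hotspots=planted,
        qtl_hotspot_membership=membership,
    )
    return GeneticMaps(qtls=qtls, qtns=qtns, truth=truth)


def write_experiment(data: ExperimentData, outdir: str | Path) -> dict[str, Path]:
    """Write counts, sample sheet, annotation and truth to TSV/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.json",
    }
    data.counts.to_csv(paths["counts"], sep="\t")
    data.samples.to_csv(paths["samples"], sep="\t", index=False)
    data.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    paths["truth"].write_text(data.truth.to_json())
    return paths


def write_genetic_maps(maps: GeneticMaps, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"qtls": outdir / "qtls.tsv", "qtns": outdir / "qtns.tsv",
             "map_truth": outdir / "map_truth.json"}
    maps.qtls.to_csv(paths["qtls"], sep="\t", index=False)
    maps.qtns.to_csv(paths["qtns"], sep="\t", index=False)
    paths["map_truth"].write_text(maps.truth.to_json())
    return paths
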