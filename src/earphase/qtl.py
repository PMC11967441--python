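"""Genetic-architecture integration: QTL hotspots, QTN windows, candidates.

Compiled QTL intervals from multiple mapping studies are merged by single
linkage (>= 1 shared bp; pure abutment does not merge) into hotspots wherever
>= 2 QTLs from >= 2 distinct studies overlap — the unit of repeated genetic
evidence.  Trait-associated SNPs (QTNs) get +/- 100 kb flanking windows.
Phase-I line-specific DEGs are then intersected with both region types:
tier-1 candidates lie in a hotspot or a QTN window; "common region"
candidates lie in a hotspot that itself contains a QTN whose window also
covers the gene — genes carrying both linkage and association evidence.

All coordinates are 1-based inclusive (GFF3 convention) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "build_intervals",
    "merge_hotspots",
    "qtn_flanks",
    "overlap_genes",
    "call_candidates",
    "annotate_tfs",
    "Hotspot",
    "CandidateTable",
]

QTN_FLANK_BP = 100_000


@dataclass
class Hotspot:
    hotspot_id: str
    chrom: str
    start: int
    end: int
    member_qtls: list[str]
    studies: list[str]

    @property
    def support(self) -> int:
        return len(self.member_qtls)

    @property
    def n_studies(self) -> int:
        return len(set(self.studies))


@dataclass
class CandidateTable:
    candidates: pd.DataFrame      # gene_id, hotspot_ids, qtn_ids, common_region
    counts: dict[str, int] = field(default_factory=dict)


def build_intervals(
    qtl_table: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Validate an anchored QTL table (qtl_id, study_id, chrom, start, end...).

    Swapped coordinates are normalised with a warning; duplicate
    (study, chrom, start, end) rows collapse to one; rows missing coordinates
    are dropped and counted; a chromosome absent from ``chrom_lengths``
    raises.
    """
    df = qtl_table.copy()
    required = {"qtl_id", "study_id", "chrom", "start", "end"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"QTL table missing columns: {sorted(missing_cols)}")

    missing = df["start"].isna() | df["end"].isna() | df["chrom"].isna()
    if missing.any():
        logger.warning("dropping %d QTL records with missing coordinates", int(missing.sum()))
        df = df[~missing]
    df = df.astype({"start": int, "end": int})

    if chrom_lengths is not None:
        unknown = set(df["chrom"]) - set(chrom_lengths)
        if unknown:
            raise ValueError(f"QTL records on unknown chromosomes: {sorted(unknown)}")

    swapped = df["start"] > df["end"]
    if swapped.any():
        logger.warning("normalising %d QTL records with start > end", int(swapped.sum()))
        lo = df.loc[swapped, ["start", "end"]].min(axis=1)
        hi = df.loc[swapped, ["start", "end"]].max(axis=1)
        df.loc[swapped, "start"] = lo
        df.loc[swapped, "end"] = hi

    before = len(df)
    df = df.drop_duplicates(subset=["study_id", "chrom", "start", "end"])
    if len(df) < before:
        logger.warning("collapsed %d duplicate QTL records", before - len(df))
    return df.reset_index(drop=True)


def merge_hotspots(
    qtls: pd.DataFrame,
    min_support: int = 2,
    require_distinct_studies: bool = True,
) -> list[Hotspot]:
    """Single-linkage merge of overlapping QTLs into cross-study hotspots.

    Two intervals overlap when they share >= 1 bp (closed coordinates:
    start2 <= end1); abutting intervals (start2 = end1 + 1) do not merge.
    A merged cluster becomes a hotspot iff it has >= ``min_support`` member
    QTLs and, when required, members from >= 2 distinct studies.  The hotspot
    span is the min start / max end of its members.
    """
    hotspots: list[Hotspot] = []
    counter = 0
    for chrom in sorted(qtls["chrom"].unique()):
        sub = qtls[qtls["chrom"] == chrom].sort_values(["start", "end"], kind="mergesort")
        cluster: list[pd.Series] = []
        cur_end = None
        for _, row in sub.iterrows():
            if cluster and row["start"] <= cur_end:
                cluster.append(row)
                cur_end = max(cur_end, row["end"])
            else:
                counter = _emit(cluster, hotspots, counter, min_support, require_distinct_studies)
                cluster = [row]
                cur_end = row["end"]
        counter = _emit(cluster, hotspots, counter, min_support, require_distinct_studies)
    return hotspots


def _emit(
    cluster: list[pd.Series],
    out: list[Hotspot],
    counter: int,
    min_support: int,
    require_distinct_studies: bool,
) -> int:
    if not cluster:
        return counter
    studies = [r["study_id"] for r in cluster]
    if len(cluster) < min_support:
        return counter
    if require_distinct_studies and len(set(studies)) < 2:
        return counter
    out.append(
        Hotspot(
            hotspot_id=f"hotspot{counter + 1:02d}",
            chrom=cluster[0]["chrom"],
            start=int(min(r["start"] for r in cluster)),
            end=int(max(r["end"] for r in cluster)),
            member_qtls=[r["qtl_id"] for r in cluster],
            studies=studies,
        )
    )
    return counter + 1


def qtn_flanks(
    qtns: pd.DataFrame,
    chrom_lengths: dict[str, int],
    flank: int = QTN_FLANK_BP,
) -> pd.DataFrame:
    """Per-QTN flanking window [pos - flank, pos + flank], clamped to the
    chromosome, 1-based inclusive.  Windows are never merged, so each QTN's
    evidence stays attributable."""
    rows = []
    for _, row in qtns.iterrows():
        chrom = row["chrom"]
        if chrom not in chrom_lengths:
            raise ValueError(f"QTN {row['qtn_id']} on unknown chromosome {chrom}")
        pos = int(row["pos"])
        if not 1 <= pos <= chrom_lengths[chrom]:
            raise ValueError(f"QTN {row['qtn_id']} position {pos} outside {chrom}")
        rows.append(
            (row["qtn_id"], chrom, max(1, pos - flank), min(chrom_lengths[chrom], pos + flank), pos)
        )
    return pd.DataFrame(rows, columns=["qtn_id", "chrom", "start", "end", "pos"])


def overlap_genes(
    annotation: pd.DataFrame,
    regions: pd.DataFrame,
    region_id_col: str = "region_id",
) -> dict[str, list[str]]:
    """Map gene_id -> region ids sharing >= 1 bp with the gene span.

    ``annotation`` needs gene_id/chrom/start/end; ``regions`` needs
    ``region_id_col``/chrom/start/end, all 1-based inclusive on one build.
    """
    gene_chroms = set(annotation["chrom"])
    region_chroms = set(regions["chrom"])
    if regions.shape[0] and not (gene_chroms & region_chroms):
        raise ValueError(
            "no shared chromosome names between annotation and regions: "
            f"{sorted(gene_chroms)[:5]} vs {sorted(region_chroms)[:5]}"
        )
    trees: dict[str, IntervalTree] = {}
    for _, row in regions.iterrows():
        # half-open tree coordinates: [start, end+1) represents closed [start, end]
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]) + 1, row[region_id_col]
        )
    hits: dict[str, list[str]] = {}
    for _, gene in annotation.iterrows():
        tree = trees.get(gene["chrom"])
        if tree is None:
            continue
        found = tree.overlap(int(gene["start"]), int(gene["end"]) + 1)
        if found:
            hits[gene["gene_id"]] = sorted(iv.data for iv in found)
    return hits


def call_candidates(
    deg_set: set[str],
    hotspots: list[Hotspot],
    windows: pd.DataFrame,
    annotation: pd.DataFrame,
    common_region_mode: str = "same_hotspot",
) -> CandidateTable:
    """Candidate genes among Phase-I line-specific DEGs.

    Tier 1: the gene overlaps >= 1 hotspot OR >= 1 QTN flanking window.
    Common region: the gene overlaps a hotspot H and the window of a QTN
    located inside H (``same_hotspot``, the strict reading) or inside any
    hotspot (``any_hotspot``).
    """
    if common_region_mode not in {"same_hotspot", "any_hotspot"}:
        raise ValueError(f"unknown common_region_mode {common_region_mode!r}")
    known = set(annotation["gene_id"])
    missing = deg_set - known
    if missing:
        logger.warning("%d DEG ids missing from the annotation were skipped", len(missing))
    if not deg_set:
        logger.warning("empty DEG set: no candidates to call")
    genes = annotation[annotation["gene_id"].isin(deg_set)]

    hs_regions = pd.DataFrame(
        [(h.hotspot_id, h.chrom, h.start, h.end) for h in hotspots],
        columns=["region_id", "chrom", "start", "end"],
    )
    gene_hotspots = overlap_genes(genes, hs_regions) if len(hs_regions) else {}
    win_regions = windows.rename(columns={"qtn_id": "region_id"})[
        ["region_id", "chrom", "start", "end"]
    ]
    gene_windows = overlap_genes(genes, win_regions) if len(win_regions) else {}

    # QTNs located inside each hotspot
    hotspot_qtns: dict[str, set[str]] = {h.hotspot_id: set() for h in hotspots}
    for h in hotspots:
        inside = windows[
            (windows["chrom"] == h.chrom)
            & (windows["pos"] >= h.start)
            & (windows["pos"] <= h.end)
        ]
        hotspot_qtns[h.hotspot_id] = set(inside["qtn_id"])

    rows = []
    for gene_id in sorted(deg_set & known):
        hs = gene_hotspots.get(gene_id, [])
        qs = gene_windows.get(gene_id, [])
        if not hs and not qs:
            continue
        if common_region_mode == "same_hotspot":
            common = any(q in hotspot_qtns[h] for h in hs for q in qs)
        else:
            any_hotspot_qtns = set().union(*hotspot_qtns.values()) if hotspot_qtns else set()
            common = bool(hs) and any(q in any_hotspot_qtns for q in qs)
        rows.append((gene_id, ",".join(hs), ",".join(qs), common))

    table = pd.DataFrame(rows, columns=["gene_id", "hotspot_ids", "qtn_ids", "common_region"])
    counts = {
        "n_hotspots": len(hotspots),
        "n_qtn_windows": int(len(windows)),
        "n_deg_in_hotspots": int((table["hotspot_ids"] != "").sum()) if len(table) else 0,
        "n_deg_in_qtn_windows": int((table["qtn_ids"] != "").sum()) if len(table) else 0,
        "n_tier1": int(len(table)),
        "n_common_region": int(table["common_region"].sum()) if len(table) else 0,
    }
    return CandidateTable(candidates=table, counts=counts)


def annotate_tfs(
    candidates: pd.DataFrame,
    tf_table: pd.DataFrame,
    deg_direction: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join TF families onto candidates and tally families by stage/direction.

    ``tf_table`` maps gene_id -> family; unmatched genes are annotated as
    non-TF (empty family).  ``deg_direction`` (gene_id, stage, direction)
    feeds the per-family x per-stage up/down tally; without it the tally is a
    plain per-family count.
    """
    fam = tf_table.set_index("gene_id")["family"] if len(tf_table) else pd.Series(dtype=object)
    annotated = candidates.copy()
    annotated["tf_family"] = annotated["gene_id"].map(fam).fillna("")
    tf_only = annotated[annotated["tf_family"] != ""]
    if deg_direction is not None and len(tf_only):
        joined = tf_only.merge(deg_direction, on="gene_id", how="left")
        tally = (
            joined.groupby(["tf_family", "stage", "direction"], dropna=False)
            .size()
            .rename("n_genes")
            .reset_index()
        )
    else:
        tally = tf_only.groupby("tf_family").size().rename("n_genes").reset_index()
    return annotated, tally
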