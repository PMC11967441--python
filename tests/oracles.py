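"""Independent brute-force oracles used to cross-check the interval algebra.

Everything here works on explicit per-basepair integer sets (1-based
inclusive), so it is exact but only feasible on small chromosomes.  The
oracles deliberately share no code with the implementation under test.
"""

from __future__ import annotations

import itertools

import pandas as pd


def bp_set(start: int, end: int) -> set[int]:
    return set(range(int(start), int(end) + 1))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def oracle_merge(
    qtls: pd.DataFrame, min_support: int = 2, require_distinct_studies: bool = True
) -> list[dict]:
    """Single-linkage clusters via pairwise bp-set intersection tests."""
    out = []
    for chrom in sorted(qtls["chrom"].unique()):
        sub = qtls[qtls["chrom"] == chrom].reset_index(drop=True)
        sets = [bp_set(r["start"], r["end"]) for _, r in sub.iterrows()]
        uf = _UnionFind(len(sub))
        for i, j in itertools.combinations(range(len(sub)), 2):
            if sets[i] & sets[j]:
                uf.union(i, j)
        clusters: dict[int, list[int]] = {}
        for i in range(len(sub)):
            clusters.setdefault(uf.find(i), []).append(i)
        for members in clusters.values():
            studies = {sub.loc[m, "study_id"] for m in members}
            if len(members) < min_support:
                continue
            if require_distinct_studies and len(studies) < 2:
                continue
            union_bp = set().union(*(sets[m] for m in members))
            out.append(
                {
                    "chrom": chrom,
                    "start": min(union_bp),
                    "end": max(union_bp),
                    "members": sorted(sub.loc[m, "qtl_id"] for m in members),
                    "support": len(members),
                    "n_studies": len(studies),
                }
            )
    return sorted(out, key=lambda h: (h["chrom"], h["start"]))


def oracle_flank(pos: int, flank: int, chrom_len: int) -> tuple[int, int]:
    """Window as the bp set within distance <= flank of pos, clipped."""
    window = {b for b in range(pos - flank, pos + flank + 1) if 1 <= b <= chrom_len}
    return min(window), max(window)


def oracle_overlap(genes: pd.DataFrame, regions: pd.DataFrame, id_col: str) -> dict[str, list[str]]:
    """gene -> region ids with non-empty bp-set intersection."""
    hits: dict[str, list[str]] = {}
    for _, g in genes.iterrows():
        gset = bp_set(g["start"], g["end"])
        found = [
            r[id_col]
            for _, r in regions.iterrows()
            if r["chrom"] == g["chrom"] and gset & bp_set(r["start"], r["end"])
        ]
        if found:
            hits[g["gene_id"]] = sorted(found)
    return hits


def oracle_candidates(
    deg_genes: pd.DataFrame,
    hotspots: list[dict],
    qtns: pd.DataFrame,
    flank: int,
    chrom_lengths: dict[str, int],
) -> dict[str, dict]:
    """Direct evaluation of the candidate predicate on bp sets.

    ``hotspots`` entries need chrom/start/end and an ``id``; common-region
    binds the QTN to a hotspot containing its position (strict reading).
    """
    windows = []
    for _, q in qtns.iterrows():
        lo, hi = oracle_flank(int(q["pos"]), flank, chrom_lengths[q["chrom"]])
        windows.append({"id": q["qtn_id"], "chrom": q["chrom"], "start": lo, "end": hi,
                        "pos": int(q["pos"])})
    result = {}
    for _, g in deg_genes.iterrows():
        gset = bp_set(g["start"], g["end"])
        in_hs = [
            h["id"] for h in hotspots
            if h["chrom"] == g["chrom"] and gset & bp_set(h["start"], h["end"])
        ]
        in_win = [
            w["id"] for w in windows
            if w["chrom"] == g["chrom"] and gset & bp_set(w["start"], w["end"])
        ]
        common = False
        for hid in in_hs:
            h = next(h for h in hotspots if h["id"] == hid)
            for wid in in_win:
                w = next(w for w in windows if w["id"] == wid)
                if w["chrom"] == h["chrom"] and h["start"] <= w["pos"] <= h["end"]:
                    common = True
        if in_hs or in_win:
            result[g["gene_id"]] = {
                "hotspots": sorted(in_hs), "windows": sorted(in_win), "common": common
            }
    return result


def oracle_venn(sets: dict[str, set]) -> dict[str, set]:
    """Region = intersection of member sets minus union of the rest."""
    names = list(sets)
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo), set())
            regions["+".join(combo)] = inside - outside
    return regions
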