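"""Multi-tissue m6A site atlas.

Replicate intersection, tissue-common/unique classification,
reproductive/vegetative phasing, windowed cross-method overlap, per-bin
coefficient-of-variation profiles, rank normalization and two-condition
differential methylation.

A site key is (chrom, 1-based pos, strand).  A tissue's site set is the
intersection of the sites passing detection in both biological replicates,
with the retained fraction the mean of the replicate fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Region, TranscriptModel, metagene_coordinate

__all__ = [
    "TissueSiteSet",
    "merge_replicates",
    "classify_shared_unique",
    "phase_unique_sites",
    "overlap_with_window",
    "build_atlas",
    "cv_profile",
    "rank_normalize",
    "compare_conditions",
]

SiteKey = tuple[str, int, str]


@dataclass
class TissueSiteSet:
    """Replicate-intersected m6A sites of one tissue."""

    tissue_id: str
    table: pd.DataFrame = field(repr=False)  # chrom,pos,strand,fraction,depth_rep1,depth_rep2

    @property
    def keys(self) -> set[SiteKey]:
        return set(zip(self.table["chrom"], self.table["pos"], self.table["strand"]))

    def fractions(self) -> dict[SiteKey, float]:
        return dict(
            zip(
                zip(self.table["chrom"], self.table["pos"], self.table["strand"]),
                self.table["fraction"],
            )
        )


def merge_replicates(calls_rep1: pd.DataFrame, calls_rep2: pd.DataFrame, tissue_id: str = "tissue") -> TissueSiteSet:
    """Intersect passed sites of two replicates; fraction = replicate mean."""
    key = ["chrom", "pos", "strand"]
    r1 = calls_rep1.loc[calls_rep1["passed"], key + ["fraction", "depth"]]
    r2 = calls_rep2.loc[calls_rep2["passed"], key + ["fraction", "depth"]]
    if len(r1) == 0 or len(r2) == 0:
        warnings.warn(f"{tissue_id}: empty replicate call set; tissue site set is empty")
    merged = r1.merge(r2, on=key, suffixes=("_rep1", "_rep2"))
    merged["fraction"] = (merged["fraction_rep1"] + merged["fraction_rep2"]) / 2.0
    out = merged[key + ["fraction", "depth_rep1", "depth_rep2"]].reset_index(drop=True)
    return TissueSiteSet(tissue_id, out)


def classify_shared_unique(tissue_sets: list[TissueSiteSet]) -> pd.DataFrame:
    """Label every site in the union: common / unique:<tissue> / partial."""
    if len(tissue_sets) < 2:
        raise ValueError("need >= 2 tissues")
    membership: dict[SiteKey, list[str]] = {}
    for ts in tissue_sets:
        for k in ts.keys:
            membership.setdefault(k, []).append(ts.tissue_id)
    n = len(tissue_sets)
    rows = []
    for (chrom, pos, strand), tissues in membership.items():
        if len(tissues) == n:
            label = "common"
        elif len(tissues) == 1:
            label = f"unique:{tissues[0]}"
        else:
            label = "partial"
        rows.append((chrom, pos, strand, label, len(tissues)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "label", "n_tissues"])


def phase_unique_sites(
    tissue_sets: list[TissueSiteSet], grouping: dict[str, str]
) -> dict[str, set[SiteKey]]:
    """Split sites by life-cycle phase.

    ``grouping`` maps tissue_id -> 'reproductive' | 'vegetative' (the
    Arabidopsis convention groups flower, seed and silique as
    reproductive).  A site present only in reproductive tissues is
    reproductive_unique; symmetric for vegetative; present in both phases
    -> common.
    """
    for ts in tissue_sets:
        if ts.tissue_id not in grouping:
            raise ValueError(f"tissue {ts.tissue_id!r} missing from grouping")
        if grouping[ts.tissue_id] not in ("reproductive", "vegetative"):
            raise ValueError(f"unknown phase {grouping[ts.tissue_id]!r}")
    rep: set[SiteKey] = set()
    veg: set[SiteKey] = set()
    for ts in tissue_sets:
        (rep if grouping[ts.tissue_id] == "reproductive" else veg).update(ts.keys)
    return {
        "reproductive_unique": rep - veg,
        "vegetative_unique": veg - rep,
        "common": rep & veg,
    }


def overlap_with_window(
    sites_a: set[SiteKey] | list[SiteKey],
    sites_b: set[SiteKey] | list[SiteKey],
    w: int = 5,
) -> tuple[int, int, list[tuple[SiteKey, SiteKey]]]:
    """Directional overlap counts under a +/- w nt window.

    A site in A counts as overlapped iff some site in B on the same
    chrom+strand lies within w nt (and vice versa — the two counts are not
    symmetric).  Also returns the matched (a, b) pairs, pairing each
    overlapped A site with its nearest B site (ties toward the left).
    """
    if w < 0:
        raise ValueError("window must be >= 0")
    a_list = sorted(set(sites_a))
    b_list = sorted(set(sites_b))

    def index(sites):
        by: dict[tuple[str, str], np.ndarray] = {}
        tmp: dict[tuple[str, str], list[int]] = {}
        for chrom, pos, strand in sites:
            tmp.setdefault((chrom, strand), []).append(pos)
        for k, v in tmp.items():
            by[k] = np.asarray(sorted(v))
        return by

    def count(query, target_idx, collect_pairs):
        hits = 0
        pairs = []
        for chrom, pos, strand in query:
            arr = target_idx.get((chrom, strand))
            if arr is None or len(arr) == 0:
                continue
            i = int(np.searchsorted(arr, pos))
            best, bestd = None, None
            for j in (i - 1, i):
                if 0 <= j < len(arr):
                    d = abs(int(arr[j]) - pos)
                    if bestd is None or d < bestd:
                        best, bestd = int(arr[j]), d
            if bestd is not None and bestd <= w:
                hits += 1
                if collect_pairs:
                    pairs.append(((chrom, pos, strand), (chrom, best, strand)))
        return hits, pairs

    n_a, pairs = count(a_list, index(b_list), True)
    n_b, _ = count(b_list, index(a_list), False)
    return n_a, n_b, pairs


def build_atlas(tissue_sets: list[TissueSiteSet]) -> pd.DataFrame:
    """Wide site-by-tissue fraction matrix (NaN = unmeasured in that tissue)."""
    frames = []
    for ts in tissue_sets:
        f = ts.table[["chrom", "pos", "strand", "fraction"]].copy()
        f["tissue"] = ts.tissue_id
        frames.append(f)
    long = pd.concat(frames, ignore_index=True)
    return long.pivot_table(
        index=["chrom", "pos", "strand"], columns="tissue", values="fraction", aggfunc="mean"
    )


def cv_profile(
    atlas: pd.DataFrame,
    transcripts: dict[str, TranscriptModel],
    site_transcript: dict[SiteKey, str],
    bins_per_region: int = 20,
) -> pd.DataFrame:
    """SD/mean of per-bin m6A levels across tissues, along the metagene axis.

    Per tissue and metagene bin, site fractions are summed; the CV of the
    bin totals across tissues (sample SD over mean) quantifies how variable
    deposition in that part of the transcript is over the life cycle.
    Bins with zero mean are reported as NaN.
    """
    if atlas.shape[1] < 2:
        raise ValueError("need >= 2 tissues for a CV profile")
    regions = [Region.UTR5, Region.CDS, Region.UTR3]
    shape = (len(regions), bins_per_region, atlas.shape[1])
    totals = np.zeros(shape)
    region_ix = {r: i for i, r in enumerate(regions)}
    for row_i, (key, row) in enumerate(atlas.iterrows()):
        chrom, pos, strand = key
        tid = site_transcript.get((chrom, pos, strand))
        if tid is None or tid not in transcripts:
            continue
        t = transcripts[tid]
        try:
            mg = metagene_coordinate(pos - 1, t, bins_per_region)
        except ValueError:
            continue
        if mg is None or mg[0] not in region_ix:
            continue
        r, b = region_ix[mg[0]], mg[1]
        vals = row.to_numpy(dtype=float)
        totals[r, b, :] += np.nan_to_num(vals)
    rows = []
    for r, region in enumerate(regions):
        for b in range(bins_per_region):
            v = totals[r, b, :]
            mean = v.mean()
            cv = float(v.std(ddof=1) / mean) if mean > 0 else np.nan
            rows.append({"region": region.value, "bin": b, "mean_level": mean, "cv": cv})
    return pd.DataFrame(rows)


def rank_normalize(values: np.ndarray | pd.Series) -> np.ndarray:
    """Map a row of tissue fractions to [0,1] by within-row ranking.

    Average ranks for ties, scaled as (rank - 1) / (n - 1); missing entries
    stay missing.  Invariant under strictly monotone transforms of the
    inputs — the form used to make cross-species levels comparable before
    a PCA.
    """
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = np.isfinite(arr)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need >= 2 non-missing entries to rank-normalize")
    ranks = stats.rankdata(arr[mask], method="average")
    out[mask] = (ranks - 1.0) / (n - 1.0)
    return out


def rank_normalize_atlas(atlas: pd.DataFrame) -> pd.DataFrame:
    """Row-wise :func:`rank_normalize`, skipping rows with < 2 measurements."""
    keep = atlas.notna().sum(axis=1) >= 2
    sub = atlas.loc[keep]
    return pd.DataFrame(
        np.vstack([rank_normalize(row) for _, row in sub.iterrows()]) if len(sub) else np.empty((0, atlas.shape[1])),
        index=sub.index,
        columns=atlas.columns,
    )


def compare_conditions(
    calls_a: list[pd.DataFrame],
    calls_b: list[pd.DataFrame],
    cal_lookup,
    min_depth: int = 20,
    alpha: float = 0.05,
    min_delta: float = 0.1,
) -> pd.DataFrame:
    """Two-condition differential methylation (B = treatment vs A).

    Replicate pileups are pooled per condition; each shared site gets a
    two-sided Fisher's exact test on the pooled (mutated, unmutated)
    counts.  Verdicts: ``hyper`` if p < alpha and fraction_B - fraction_A
    >= min_delta, ``hypo`` symmetric, ``undertested`` if either pooled
    depth < min_depth, else ``unchanged``.

    ``cal_lookup(motif) -> (bg, full)`` converts pooled rates to fractions.
    """
    key = ["chrom", "pos", "strand"]

    def pool(calls: list[pd.DataFrame]) -> pd.DataFrame:
        cat = pd.concat(calls, ignore_index=True)
        agg = cat.groupby(key + ["motif"], as_index=False)[["depth", "mut_count"]].sum()
        return agg

    pa, pb = pool(calls_a), pool(calls_b)
    merged = pa.merge(pb, on=key + ["motif"], suffixes=("_a", "_b"))
    if len(merged) == 0:
        raise ValueError("no shared sites between conditions")

    rows = []
    for rec in merged.itertuples(index=False):
        da, ma = int(rec.depth_a), int(rec.mut_count_a)
        db, mb = int(rec.depth_b), int(rec.mut_count_b)
        bg, full = cal_lookup(rec.motif)
        fa = float(np.clip((ma / da - bg) / (full - bg), 0, 1)) if da else np.nan
        fb = float(np.clip((mb / db - bg) / (full - bg), 0, 1)) if db else np.nan
        if da < min_depth or db < min_depth:
            verdict, p = "undertested", np.nan
        else:
            _, p = stats.fisher_exact([[ma, da - ma], [mb, db - mb]])
            delta = fb - fa
            if p < alpha and delta >= min_delta:
                verdict = "hyper"
            elif p < alpha and delta <= -min_delta:
                verdict = "hypo"
            else:
                verdict = "unchanged"
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "strand": rec.strand,
                "fraction_a": fa,
                "fraction_b": fb,
                "delta": fb - fa,
                "p_value": p,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows)
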