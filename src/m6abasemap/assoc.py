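"""Functional association of m6A position/stoichiometry with phenotypes.

Relates per-transcript m6A profiles to mRNA lifetime or translation
efficiency: transcripts are grouped by where their sites sit (3'UTR-only
vs non-3'UTR), stratified into five bins by the sum of their site
fractions, and contrasted with one-tailed Wilcoxon rank-sum tests.  Also
provides writer-dependence classification (reduced / abolished in a
methyltransferase mutant) and signed distances from sites to reader CLIP
peak centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Region, TranscriptModel, assign_region

__all__ = [
    "classify_transcript_m6a",
    "transcript_profiles",
    "bin_by_fraction_sum",
    "association_test",
    "peak_site_distance",
    "mta_dependence",
    "FRACTION_SUM_EDGES",
]

#: Five-bin stratification of per-transcript fraction sums.
FRACTION_SUM_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def classify_transcript_m6a(site_regions: list[Region]) -> str:
    """Group a transcript by the regions of its passed sites.

    utr3_only — at least one site, all in the 3'UTR; non_utr3 — at least
    one site, none in the 3'UTR; mixed — sites on both sides of the
    dichotomy; none — no sites.
    """
    if not site_regions:
        return "none"
    in3 = [r is Region.UTR3 for r in site_regions]
    if all(in3):
        return "utr3_only"
    if not any(in3):
        return "non_utr3"
    return "mixed"


def transcript_profiles(
    sites: pd.DataFrame,
    transcripts: dict[str, TranscriptModel],
    site_transcript: dict[tuple[str, int, str], str],
) -> pd.DataFrame:
    """Per-transcript m6A profile: group, fraction sum, 3'UTR fraction sum.

    ``sites`` is a call table (1-based pos); only passed sites count.
    Transcripts with no passed site appear with group 'none' and zero sums.
    """
    rows = {
        tid: {"transcript_id": tid, "regions": [], "fraction_sum": 0.0, "fraction_sum_3utr": 0.0}
        for tid in transcripts
    }
    passed = sites.loc[sites["passed"]]
    for rec in passed.itertuples(index=False):
        tid = site_transcript.get((rec.chrom, rec.pos, rec.strand))
        if tid is None or tid not in transcripts:
            continue
        t = transcripts[tid]
        try:
            region = assign_region(rec.pos - 1, t)
        except ValueError:
            continue
        if region is Region.INTRON:
            continue
        entry = rows[tid]
        entry["regions"].append(region)
        entry["fraction_sum"] += rec.fraction
        if region is Region.UTR3:
            entry["fraction_sum_3utr"] += rec.fraction
    out = []
    for tid, entry in rows.items():
        out.append(
            {
                "transcript_id": tid,
                "group": classify_transcript_m6a(entry["regions"]),
                "n_sites": len(entry["regions"]),
                "fraction_sum": entry["fraction_sum"],
                "fraction_sum_3utr": entry["fraction_sum_3utr"],
            }
        )
    return pd.DataFrame(out)


def bin_by_fraction_sum(
    fraction_sums: pd.Series | np.ndarray,
    edges: tuple[float, ...] = FRACTION_SUM_EDGES,
) -> pd.DataFrame:
    """Assign positive fraction sums to five left-open right-closed bins.

    Bins are (0,0.2], (0.2,0.4], ... (0.8,1.0]; sums above the last edge
    are clamped into the top bin and flagged (``clamped``).  Zero or
    negative sums are excluded (bin -1).
    """
    x = np.asarray(fraction_sums, dtype=float)
    bins = np.full(x.shape, -1, dtype=int)
    clamped = np.zeros(x.shape, dtype=bool)
    pos = x > edges[0]
    # right-closed: searchsorted with side='left' on the interior edges
    idx = np.searchsorted(np.asarray(edges[1:-1]), x, side="left")
    bins[pos] = idx[pos]
    over = x > edges[-1]
    bins[over] = len(edges) - 2
    clamped[over] = True
    return pd.DataFrame({"fraction_sum": x, "bin": bins, "clamped": clamped})


@dataclass
class AssociationResult:
    summary: pd.DataFrame
    pairwise: pd.DataFrame
    ecdf: pd.DataFrame


def association_test(
    groups: dict[str, np.ndarray],
    alternative: str = "greater",
) -> AssociationResult:
    """Summaries + one-tailed pairwise Wilcoxon rank-sum tests across groups.

    ``alternative='greater'`` tests whether the first group of each pair is
    stochastically larger than the second.  Returns per-group quartiles, a
    pairwise p-value table (exact for small samples, normal approximation
    otherwise via scipy), and stacked ECDF tables for plotting cumulative
    curves.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    for lab in labels:
        if len(groups[lab]) < 3:
            raise ValueError(f"group {lab!r} has n < 3")
    summary = pd.DataFrame(
        {
            "group": labels,
            "n": [len(groups[g]) for g in labels],
            "mean": [float(np.mean(groups[g])) for g in labels],
            "median": [float(np.median(groups[g])) for g in labels],
            "q1": [float(np.percentile(groups[g], 25)) for g in labels],
            "q3": [float(np.percentile(groups[g], 75)) for g in labels],
        }
    )
    rows = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1 :]:
            x, y = np.asarray(groups[g1]), np.asarray(groups[g2])
            pooled = np.concatenate([x, y])
            method = (
                "exact"
                if max(len(x), len(y)) <= 25 and len(np.unique(pooled)) == len(pooled)
                else "asymptotic"
            )
            stat, p = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
            rows.append({"group1": g1, "group2": g2, "statistic": float(stat), "p_value": float(p)})
    ecdf_rows = []
    for g in labels:
        v = np.sort(np.asarray(groups[g], dtype=float))
        ecdf_rows.append(
            pd.DataFrame({"group": g, "value": v, "ecdf": np.arange(1, len(v) + 1) / len(v)})
        )
    return AssociationResult(summary, pd.DataFrame(rows), pd.concat(ecdf_rows, ignore_index=True))


def peak_site_distance(peaks: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Signed distance from each site to the nearest peak center.

    ``peaks`` is BED-like (chrom, start, end, strand[, center]); centers
    default to interval midpoints.  Distances are transcript-oriented:
    positive means the site lies 3' of the center (so the sign flips on the
    minus strand).  Sites on chromosome/strand combinations without peaks
    are dropped; the count is in ``attrs['n_excluded']``.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    pk = peaks.copy()
    if "center" not in pk.columns:
        pk["center"] = (pk["start"] + pk["end"]) // 2
    centers: dict[tuple[str, str], np.ndarray] = {
        (chrom, strand): np.sort(grp["center"].to_numpy())
        for (chrom, strand), grp in pk.groupby(["chrom", "strand"], sort=False)
    }
    rows, excluded = [], 0
    for rec in sites.itertuples(index=False):
        arr = centers.get((rec.chrom, rec.strand))
        if arr is None:
            excluded += 1
            continue
        pos0 = rec.pos - 1
        i = int(np.searchsorted(arr, pos0))
        cands = [int(arr[j]) for j in (i - 1, i) if 0 <= j < len(arr)]
        center = min(cands, key=lambda c: abs(c - pos0))
        d = pos0 - center
        if rec.strand == "-":
            d = -d
        rows.append({"chrom": rec.chrom, "pos": rec.pos, "strand": rec.strand, "distance": d})
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = excluded
    return out


def mta_dependence(
    calls_wt: pd.DataFrame,
    calls_mut: pd.DataFrame,
    min_depth: int = 20,
    alpha: float = 0.05,
    reduced_fc: float = 0.5,
    detection_rate: float = 0.05,
) -> pd.DataFrame:
    """Classify WT-passed sites by their dependence on the m6A writer.

    Per WT-passed site: ``undertested`` if mutant depth < min_depth;
    ``abolished`` if the mutant raw rate falls below the detection cutoff;
    ``reduced`` if the mutant still passes but the fraction fold-change
    (mut/WT) is <= ``reduced_fc`` with Fisher p < alpha; else
    ``independent``.  Verdicts are disjoint and exhaustive over WT-passed
    sites.
    """
    key = ["chrom", "pos", "strand"]
    wt = calls_wt.loc[calls_wt["passed"]]
    if len(wt) == 0:
        raise ValueError("no WT-passed sites")
    merged = wt.merge(calls_mut, on=key, suffixes=("_wt", "_mut"), how="left")
    rows = []
    for rec in merged.itertuples(index=False):
        if pd.isna(rec.depth_mut) or rec.depth_mut < min_depth:
            verdict, p = "undertested", np.nan
        elif rec.raw_rate_mut < detection_rate:
            verdict, p = "abolished", np.nan
        else:
            fc = rec.fraction_mut / rec.fraction_wt if rec.fraction_wt > 0 else np.inf
            table = [
                [int(rec.mut_count_wt), int(rec.depth_wt - rec.mut_count_wt)],
                [int(rec.mut_count_mut), int(rec.depth_mut - rec.mut_count_mut)],
            ]
            _, p = stats.fisher_exact(table)
            verdict = "reduced" if (fc <= reduced_fc and p < alpha) else "independent"
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "strand": rec.strand,
                "fraction_wt": rec.fraction_wt,
                "fraction_mut": getattr(rec, "fraction_mut", np.nan),
                "p_value": p,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows)
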