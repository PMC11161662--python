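"""Exon-architecture statistics for m6A deposition.

Implements the per-exon and junction-aligned metrics used to dissect how
exon structure shapes m6A deposition:

* **m6A level** of an exon — sum of calibrated fractions of passed sites in
  the exon.
* **m6A density** — level normalized by exon length and multiplied by
  1,000, removing the trivial "longer exons collect more sites" effect.
* **junction-aligned profiles** — exons aligned at internal/last junctions
  (or the stop codon) and the m6A level summed per sliding window.
* **m6A likelihood** — the windowed level normalized by the coverage of
  exons in that window.  Raw windowed levels fall off with distance from
  the anchor simply because fewer exons extend that far; dividing by
  coverage removes the confound, so a uniform deposition process yields a
  flat likelihood profile while the raw profile still decays.

Anchoring conventions: internal exons contribute two anchored copies (the
5' junction with positive offsets running into the exon, and the 3'
junction with negative offsets running into the exon); last exons anchor at
their 5' junction; the stop-codon anchor sits at the first base after the
stop.  All offsets are exon-relative (windows never extend across introns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ExonRecord, TranscriptModel

__all__ = [
    "ExonLevel",
    "ProfileTrack",
    "PeakCall",
    "exon_m6a_level",
    "m6a_density",
    "exon_levels_table",
    "bin_exons_by_length",
    "junction_profile",
    "detect_profile_peak",
]

ANCHORS = ("internal_junction", "last_junction", "stop_codon")


@dataclass(frozen=True)
class ExonLevel:
    exon: ExonRecord
    level: float
    density: float


def _sites_in_interval(sites: pd.DataFrame, chrom: str, strand: str, lo: int, hi: int) -> pd.DataFrame:
    sel = (
        (sites["chrom"] == chrom)
        & (sites["strand"] == strand)
        & sites["passed"]
        & (sites["pos0"] >= lo)
        & (sites["pos0"] < hi)
    )
    return sites.loc[sel]


def _with_pos0(sites: pd.DataFrame) -> pd.DataFrame:
    """Attach a 0-based position column (input tables are 1-based)."""
    if "pos0" in sites.columns:
        return sites
    out = sites.copy()
    out["pos0"] = out["pos"] - 1
    return out


def exon_m6a_level(exon: ExonRecord, sites: pd.DataFrame) -> float:
    """Sum of calibrated fractions of passed sites inside the exon.

    The exon's genomic interval is half-open; a site exactly at the end
    coordinate is excluded.
    """
    sites = _with_pos0(sites)
    lo, hi = exon.genomic_interval
    return float(_sites_in_interval(sites, exon.chrom, exon.strand, lo, hi)["fraction"].sum())


def m6a_density(exon: ExonRecord, sites: pd.DataFrame) -> float:
    """m6A level per exon, normalized by its length and multiplied by 1,000."""
    if exon.length <= 0:
        raise ValueError("exon length must be positive")
    return 1000.0 * exon_m6a_level(exon, sites) / exon.length


def exon_levels_table(exons: list[ExonRecord], sites: pd.DataFrame) -> pd.DataFrame:
    """Vectorized level/density for many exons at once.

    Equivalent to calling :func:`exon_m6a_level` per exon but linear in
    sites + exons; rows keep the exon's identity, class and length.
    """
    sites = _with_pos0(sites)
    passed = sites.loc[sites["passed"]]
    levels = np.zeros(len(exons))
    # bucket sites by (chrom, strand) once, then binary-search per exon
    grouped: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key, grp in passed.groupby(["chrom", "strand"], sort=False):
        order = np.argsort(grp["pos0"].to_numpy(), kind="stable")
        pos = grp["pos0"].to_numpy()[order]
        grouped[key] = (pos, np.cumsum(np.concatenate([[0.0], grp["fraction"].to_numpy()[order]])))
    for i, ex in enumerate(exons):
        hit = grouped.get((ex.chrom, ex.strand))
        if hit is None:
            continue
        pos, csum = hit
        lo, hi = ex.genomic_interval
        a, b = np.searchsorted(pos, lo, "left"), np.searchsorted(pos, hi, "left")
        levels[i] = csum[b] - csum[a]
    return pd.DataFrame(
        {
            "transcript_id": [e.transcript_id for e in exons],
            "index": [e.index for e in exons],
            "klass": [e.klass for e in exons],
            "length": [e.length for e in exons],
            "level": levels,
            "density": 1000.0 * levels / np.array([e.length for e in exons], dtype=float),
        }
    )


def bin_exons_by_length(exon_levels: pd.DataFrame, n_bins: int = 100) -> pd.DataFrame:
    """Group exons into ``n_bins`` equal-count bins by length.

    Exons are sorted by (length, transcript_id, index) and split into
    contiguous groups whose sizes differ by at most one (larger groups
    first).  Per bin: count, median length, mean level, mean density.
    """
    n = len(exon_levels)
    if n < n_bins:
        raise ValueError(f"only {n} exons for {n_bins} bins; reduce n_bins")
    df = exon_levels.sort_values(["length", "transcript_id", "index"], kind="stable").reset_index(
        drop=True
    )
    q, r = divmod(n, n_bins)
    sizes = [q + 1] * r + [q] * (n_bins - r)
    bounds = np.cumsum([0] + sizes)
    rows = []
    for b in range(n_bins):
        grp = df.iloc[bounds[b] : bounds[b + 1]]
        rows.append(
            {
                "bin_index": b,
                "n_exons": len(grp),
                "median_length": float(grp["length"].median()),
                "mean_level": float(grp["level"].mean()),
                "mean_density": float(grp["density"].mean()),
            }
        )
    out = pd.DataFrame(rows)
    df["bin_index"] = np.repeat(np.arange(n_bins), sizes)
    out.attrs["assignment"] = df[["transcript_id", "index", "bin_index"]]
    return out


@dataclass
class ProfileTrack:
    """Windowed m6A profile around an anchor.

    ``offsets[i]`` is the window start (nt, signed, 5'->3' relative to the
    anchor); ``raw_level`` sums site fractions per window over all anchored
    exon copies; ``coverage`` counts exon copies overlapping the window by
    >= 1 nt; ``covered_bases`` sums the overlapping bases.  ``likelihood``
    is raw_level / coverage (NaN where coverage is 0); in ``bases`` mode it
    is raw_level / covered_bases, a per-base modification rate.
    """

    anchor: str
    window: int
    step: int
    offsets: np.ndarray
    raw_level: np.ndarray
    coverage: np.ndarray
    covered_bases: np.ndarray
    coverage_mode: str = "count"
    n_copies: int = 0

    @property
    def likelihood(self) -> np.ndarray:
        denom = self.coverage if self.coverage_mode == "count" else self.covered_bases
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, self.raw_level / np.maximum(denom, 1e-300), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "anchor": self.anchor,
                "offset": self.offsets,
                "window": self.window,
                "raw_level": self.raw_level,
                "coverage": self.coverage,
                "covered_bases": self.covered_bases,
                "likelihood": self.likelihood,
            }
        )


def _anchored_copies(
    exons: list[ExonRecord],
    transcripts: dict[str, TranscriptModel] | None,
    anchor: str,
) -> list[tuple[int, int, ExonRecord]]:
    """(segment_start, segment_end) on the offset axis for each exon copy."""
    copies = []
    for ex in exons:
        L = ex.length
        if anchor == "internal_junction":
            copies.append((0, L, ex))  # 5' junction, offsets run into the exon
            copies.append((-L, 0, ex))  # 3' junction
        elif anchor == "last_junction":
            copies.append((0, L, ex))
        elif anchor == "stop_codon":
            if transcripts is None:
                raise ValueError("stop_codon anchor requires transcript models")
            t = transcripts[ex.transcript_id]
            if not t.is_coding:
                continue
            ts, te = ex.transcript_interval
            start = ts - t.cds_end  # first base after the stop is offset 0
            copies.append((start, start + L, ex))
        else:
            raise ValueError(f"unknown anchor {anchor!r}; expected one of {ANCHORS}")
    return copies


def _site_offsets_in_exon(ex: ExonRecord, sites_by_key, seg_start: int) -> list[tuple[int, float]]:
    hit = sites_by_key.get((ex.chrom, ex.strand))
    if hit is None:
        return []
    pos, frac = hit
    lo, hi = ex.genomic_interval
    a, b = np.searchsorted(pos, lo, "left"), np.searchsorted(pos, hi, "left")
    out = []
    for p, f in zip(pos[a:b], frac[a:b]):
        within = (p - lo) if ex.strand == "+" else (hi - 1 - p)  # 5'->3' inside exon
        out.append((seg_start + within, f))
    return out


def junction_profile(
    exons: list[ExonRecord],
    sites: pd.DataFrame,
    anchor: str,
    window: int = 25,
    step: int = 5,
    span: int = 1000,
    transcripts: dict[str, TranscriptModel] | None = None,
    coverage_mode: str = "count",
) -> ProfileTrack:
    """Sliding-window m6A profile of anchored exons.

    For each window [d, d+window) on the signed offset axis, sums the
    fractions of passed sites whose exon-relative offset falls in the
    window, counts the exon copies overlapping the window, and forms the
    coverage-normalized likelihood.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if coverage_mode not in ("count", "bases"):
        raise ValueError("coverage_mode must be 'count' or 'bases'")
    offsets = np.arange(-span, span + 1, step)
    n = len(offsets)
    raw = np.zeros(n)
    cov = np.zeros(n, dtype=np.int64)
    bases = np.zeros(n, dtype=np.int64)

    sites = _with_pos0(sites)
    passed = sites.loc[sites["passed"]]
    sites_by_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key, grp in passed.groupby(["chrom", "strand"], sort=False):
        order = np.argsort(grp["pos0"].to_numpy(), kind="stable")
        sites_by_key[key] = (
            grp["pos0"].to_numpy()[order],
            grp["fraction"].to_numpy()[order],
        )

    copies = _anchored_copies(exons, transcripts, anchor)
    lo_off, hi_off = offsets[0], offsets[-1]

    def idx_range(first_d: int, last_d: int) -> tuple[int, int]:
        """Indices of offsets d with first_d <= d <= last_d (clipped)."""
        i0 = max(0, -(-(first_d - lo_off) // step))  # ceil
        i1 = min(n - 1, (last_d - lo_off) // step)  # floor
        return i0, i1 + 1

    for seg_start, seg_end, ex in copies:
        # windows [d, d+window) overlapping [seg_start, seg_end) by >=1 nt
        i0, i1 = idx_range(seg_start - window + 1, seg_end - 1)
        if i0 < i1:
            cov[i0:i1] += 1
            d = offsets[i0:i1]
            bases[i0:i1] += np.minimum(d + window, seg_end) - np.maximum(d, seg_start)
        for off, frac in _site_offsets_in_exon(ex, sites_by_key, seg_start):
            j0, j1 = idx_range(off - window + 1, off)
            if j0 < j1:
                raw[j0:j1] += frac

    return ProfileTrack(
        anchor=anchor,
        window=window,
        step=step,
        offsets=offsets,
        raw_level=raw,
        coverage=cov,
        covered_bases=bases,
        coverage_mode=coverage_mode,
        n_copies=len(copies),
    )


@dataclass(frozen=True)
class PeakCall:
    peak_offset: int | None
    peak_value: float
    prominence: float
    breakpoint_offset: int
    breakpoint_magnitude: float


def detect_profile_peak(
    track: ProfileTrack, smooth_window: int = 5, min_prominence: float = 0.0
) -> PeakCall:
    """Locate the likelihood peak and the largest single-step discontinuity.

    The likelihood is smoothed with a centered, edge-truncated moving
    average over defined offsets; the smoothed maximum is reported as a
    peak if its prominence over the track median exceeds
    ``min_prominence`` (else ``peak_offset`` is None).  The breakpoint
    candidate is the offset at which the unsmoothed likelihood jumps most
    between consecutive defined windows.
    """
    lk = track.likelihood
    defined = np.isfinite(lk)
    if defined.sum() == 0:
        raise ValueError("all-undefined profile track")
    if defined.sum() < 2 * smooth_window:
        raise ValueError("too few defined offsets for smoothing")
    vals = lk[defined]
    offs = track.offsets[defined]

    half = smooth_window // 2
    smoothed = np.empty_like(vals)
    for i in range(len(vals)):
        a, b = max(0, i - half), min(len(vals), i + half + 1)
        smoothed[i] = vals[a:b].mean()

    imax = int(np.argmax(smoothed))
    prominence = float(smoothed[imax] - np.median(smoothed))
    peak_offset = int(offs[imax]) if prominence > min_prominence else None

    jumps = np.abs(np.diff(vals))
    ib = int(np.argmax(jumps)) + 1  # offset where the new value starts
    return PeakCall(
        peak_offset=peak_offset,
        peak_value=float(smoothed[imax]),
        prominence=prominence,
        breakpoint_offset=int(offs[ib]),
        breakpoint_magnitude=float(jumps[ib - 1]),
    )
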