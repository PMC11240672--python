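"""Per-SNP ROH incidence and ROH-island calling.

The incidence of a SNP is the fraction of genotyped individuals whose ROH
(any class, >= 2 Mb) cover its position.  Islands — candidate selection
signatures — are runs of SNPs whose incidence clears both an outlier
threshold (the empirical top 0.1% of the incidence distribution by default,
or a normal z-score equivalent) and an absolute floor (30% of the
population), merged across gaps of up to 1 Mb.

Island lengths are reported as ``end - start`` (the convention used for
published island coordinates), unlike gene lengths which are inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import ISLAND_COLUMNS, GenotypeDataset


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of closed intervals, assuming nothing about input order."""
    ivals = sorted(ivals)
    out: list[list[int]] = []
    for s, e in ivals:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def roh_incidence(
    segments: pd.DataFrame,
    markers: pd.DataFrame,
    n_samples: int,
    min_length_bp: int = 2_000_000,
) -> pd.DataFrame:
    """Fraction of individuals whose ROH cover each marker.

    A marker is "in ROH" for a sample iff its position lies within
    ``[start_bp, end_bp]`` of any of that sample's segments of at least
    ``min_length_bp``; physically overlapping segments of one sample (possible
    across detection passes) are counted once.

    Returns the marker table with added ``carrier_count`` and ``incidence``
    columns.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    out = markers.reset_index(drop=True).copy()
    counts = np.zeros(len(out), dtype=np.int64)

    chrom_index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in out.groupby("chromosome", sort=False):
        chrom_index[str(chrom)] = (grp.index.to_numpy(), grp["position_bp"].to_numpy())

    seg = segments.loc[segments["length_bp"] >= min_length_bp]
    for (sample, chrom), grp in seg.groupby(["sample_id", "chromosome"], sort=False):
        if str(chrom) not in chrom_index:
            continue
        idx, pos = chrom_index[str(chrom)]
        for s, e in _merge_intervals(
            list(zip(grp["start_bp"].tolist(), grp["end_bp"].tolist()))
        ):
            a = np.searchsorted(pos, s, side="left")
            b = np.searchsorted(pos, e, side="right")
            counts[idx[a:b]] += 1

    out["carrier_count"] = counts
    out["incidence"] = counts / n_samples
    return out


def smooth_incidence_maxpool(profile: pd.DataFrame, window_bp: int = 1_000_000) -> np.ndarray:
    """Max-pool incidence over a sliding window of ``window_bp`` per chromosome.

    Optional pre-thresholding smoothing: each SNP is assigned the highest
    incidence among SNPs within +-``window_bp``/2 on its chromosome.
    """
    inc = profile["incidence"].to_numpy(dtype=float)
    smoothed = inc.copy()
    half = window_bp // 2
    for _, grp in profile.groupby("chromosome", sort=False):
        pos = grp["position_bp"].to_numpy()
        vals = inc[grp.index.to_numpy()]
        res = np.empty_like(vals)
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        for k in range(len(pos)):
            res[k] = vals[lo[k]:hi[k]].max()
        smoothed[grp.index.to_numpy()] = res
    return smoothed


def incidence_threshold(
    incidence: np.ndarray, quantile: float = 0.999, method: str = "quantile"
) -> float:
    """Outlier threshold for island calling.

    ``method="quantile"`` takes the empirical ``quantile`` of the genome-wide
    incidence distribution; ``method="zscore"`` assumes normality and returns
    ``mean + Phi^{-1}(quantile) * sd``.
    """
    incidence = np.asarray(incidence, dtype=float)
    if incidence.size == 0:
        raise ValueError("empty incidence profile")
    if method == "quantile":
        return float(np.quantile(incidence, quantile))
    if method == "zscore":
        z = stats.norm.ppf(quantile)
        return float(incidence.mean() + z * incidence.std(ddof=0))
    raise ValueError(f"unknown thresholding method {method!r}")


def call_islands(
    profile: pd.DataFrame,
    quantile: float = 0.999,
    min_incidence: float = 0.30,
    merge_gap_bp: int = 1_000_000,
    method: str = "quantile",
    smooth_window_bp: int | None = None,
) -> pd.DataFrame:
    """Call ROH islands from an incidence profile.

    A SNP qualifies when its incidence reaches both the genome-wide outlier
    threshold (see :func:`incidence_threshold`) and ``min_incidence``.
    Consecutive qualifying SNPs on one chromosome separated by at most
    ``merge_gap_bp`` merge into one island; islands of a single SNP are
    dropped (an island must have physical extent).  An empty table is a valid
    result.

    Returns a table with columns ``chromosome, start_bp, end_bp, length_bp,
    n_snps, peak_incidence`` where ``length_bp = end_bp - start_bp``.
    """
    inc = profile["incidence"].to_numpy(dtype=float)
    scan = (
        smooth_incidence_maxpool(profile, smooth_window_bp)
        if smooth_window_bp
        else inc
    )
    thr = incidence_threshold(scan, quantile=quantile, method=method)
    qual = (scan >= thr) & (scan >= min_incidence)

    rows = []
    for chrom, grp in profile.groupby("chromosome", sort=False):
        gidx = grp.index.to_numpy()
        pos = grp["position_bp"].to_numpy()
        q = qual[gidx]
        hit = np.flatnonzero(q)
        if hit.size == 0:
            continue
        # split where non-qualifying SNPs intervene or the bp gap is too wide
        breaks = np.flatnonzero(
            (np.diff(hit) > 1) | (np.diff(pos[hit]) > merge_gap_bp)
        )
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [hit.size - 1]))
        for a, b in zip(starts, ends):
            i0, i1 = hit[a], hit[b]
            if i0 == i1:
                continue
            rows.append(
                (str(chrom), int(pos[i0]), int(pos[i1]), int(pos[i1] - pos[i0]),
                 int(i1 - i0 + 1), float(inc[gidx[i0]: gidx[i1] + 1].max()))
            )
    return pd.DataFrame(rows, columns=list(ISLAND_COLUMNS))


def island_span_length(start_bp: int, end_bp: int) -> int:
    """Island length convention: ``end - start`` (exclusive of the +1)."""
    if end_bp <= start_bp:
        raise ValueError("island end must exceed start")
    return int(end_bp - start_bp)


class IslandCaller(BaseEstimator):
    """Sklearn-style island caller.

    ``fit(X, segments=...)`` computes the incidence profile from a dataset
    and its classified segments, then calls islands.

    Attributes
    ----------
    profile_ : pandas.DataFrame
        Marker table with ``carrier_count`` and ``incidence``.
    threshold_ : float
    islands_ : pandas.DataFrame
    """

    def __init__(
        self,
        quantile: float = 0.999,
        min_incidence: float = 0.30,
        merge_gap_bp: int = 1_000_000,
        method: str = "quantile",
        smooth_window_bp: int | None = None,
        min_segment_bp: int = 2_000_000,
    ):
        self.quantile = quantile
        self.min_incidence = min_incidence
        self.merge_gap_bp = merge_gap_bp
        self.method = method
        self.smooth_window_bp = smooth_window_bp
        self.min_segment_bp = min_segment_bp

    def fit(self, X: GenotypeDataset, segments: pd.DataFrame | None = None,
            y=None) -> "IslandCaller":
        if segments is None:
            raise ValueError("IslandCaller.fit requires segments=")
        self.profile_ = roh_incidence(
            segments, X.markers, X.n_samples, min_length_bp=self.min_segment_bp
        )
        scan = (
            smooth_incidence_maxpool(self.profile_, self.smooth_window_bp)
            if self.smooth_window_bp
            else self.profile_["incidence"].to_numpy()
        )
        self.threshold_ = incidence_threshold(scan, self.quantile, self.method)
        self.islands_ = call_islands(
            self.profile_,
            quantile=self.quantile,
            min_incidence=self.min_incidence,
            merge_gap_bp=self.merge_gap_bp,
            method=self.method,
            smooth_window_bp=self.smooth_window_bp,
        )
        return self
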