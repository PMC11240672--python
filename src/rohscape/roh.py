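"""Sliding-window detection of runs of homozygosity (ROH).

The calling parameters are data-adaptive.  The minimum number of SNPs in the
scanning window (and in a final segment), ``L``, controls the genome-wide
type-I error of declaring a run autozygous by chance:

    L = ln(alpha / (n_s * n_i)) / ln(1 - het)

with ``n_s`` SNPs per individual, ``n_i`` individuals, ``het`` the mean
per-SNP heterozygosity and ``alpha`` the tolerated type-I error.  The
proportion-of-passing-windows threshold ``t`` that declares a single SNP to be
in ROH state allows ``N_out`` SNPs on the outer flanks of a true segment to be
excluded:

    t = floor((N_out + 1) / L, 3 decimals)

Detection itself follows the PLINK ``--homozyg`` window-scan semantics, made
fully explicit here: windows of ``L`` consecutive SNPs pass when they contain
at most the allowed numbers of heterozygous and missing calls; each SNP's hit
rate is the fraction of windows covering it that pass; runs of SNPs with hit
rate >= ``t`` become candidate segments, which are then split at large
inter-SNP gaps, trimmed so they start and end on a called homozygous SNP,
and filtered on SNP count, physical length, SNP density and their own
heterozygote/missing content.

Four detection passes with per-length-class allowances (the 50K-chip scheme of
0/0, 1/0, 2/0 and 4/1 missing/heterozygous calls for the 2-4, 4-8, 8-16 and
>16 Mb classes) are combined by :func:`run_class_scheme`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import MISSING, GenotypeDataset, empty_segment_table

logger = logging.getLogger(__name__)

#: (class label, lower bound bp inclusive, upper bound bp exclusive,
#:  missing allowed, heterozygotes allowed) — the 50K BeadChip scheme.
CLASS_SCHEME: tuple[tuple[str, float, float, int, int], ...] = (
    ("2-4", 2_000_000, 4_000_000, 0, 0),
    ("4-8", 4_000_000, 8_000_000, 1, 0),
    ("8-16", 8_000_000, 16_000_000, 2, 0),
    (">16", 16_000_000, math.inf, 4, 1),
)

CLASS_LABELS: tuple[str, ...] = tuple(c[0] for c in CLASS_SCHEME)


@dataclass(frozen=True)
class ROHCallingParams:
    """One detection pass's parameters.

    Defaults are the 50K-array settings: minimum segment length 1 Mb, maximum
    gap between consecutive SNPs 1 Mb, minimum density of one SNP per 150 kb.
    ``min_segment_snps`` defaults to ``window_snps`` (the same ``L`` governs
    the window and the final segment).
    """

    window_snps: int
    scan_threshold: float
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 1_000_000
    min_density_bp_per_snp: int = 150_000
    min_segment_snps: int | None = None
    het_allowed: int = 0
    missing_allowed: int = 0
    class_range_bp: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if not (0 < self.scan_threshold <= 1):
            raise ValueError("scan_threshold must lie in (0, 1]")
        if self.het_allowed < 0 or self.missing_allowed < 0:
            raise ValueError("allowances must be >= 0")

    @property
    def effective_min_snps(self) -> int:
        return self.window_snps if self.min_segment_snps is None else self.min_segment_snps


def compute_min_window_snps(
    alpha: float, n_snps: int, n_samples: int, mean_het: float
) -> int:
    """Minimum window / segment SNP count ``L`` for a genome-wide error alpha.

    ``L = ln(alpha / (n_snps * n_samples)) / ln(1 - mean_het)``, rounded to
    the nearest integer.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if not (0 < mean_het < 1):
        raise ValueError("mean_het must lie strictly in (0, 1); "
                         "it is undefined for monomorphic data")
    if n_snps < 1 or n_samples < 1:
        raise ValueError("n_snps and n_samples must be >= 1")
    return round(math.log(alpha / (n_snps * n_samples)) / math.log(1.0 - mean_het))


def compute_scan_threshold(n_out: int, window_snps: int) -> float:
    """Per-SNP hit-rate threshold ``t = floor((n_out + 1) / L, 3 decimals)``.

    ``n_out`` is the number of SNPs on each outer flank of a segment that may
    be left out of the call.  Integer arithmetic is used so the truncation to
    three decimals is exact (e.g. 3/50 -> 0.06, 3/48 -> 0.062).
    """
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    if n_out < 0:
        raise ValueError("n_out must be >= 0")
    return (1000 * (n_out + 1) // window_snps) / 1000


def mean_heterozygosity(ds: GenotypeDataset) -> float:
    """Mean across SNPs of the observed heterozygote frequency."""
    called = ds.genotypes != MISSING
    n = called.sum(axis=0)
    het = (ds.genotypes == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        per_snp = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return float(np.nanmean(per_snp))


# ---------------------------------------------------------------------------
# single detection pass
# ---------------------------------------------------------------------------

def _roh_state(
    g: np.ndarray, window_snps: int, threshold: float,
    het_allowed: int, missing_allowed: int,
) -> np.ndarray:
    """Boolean (n_samples, n_snps) matrix of per-SNP in-ROH state.

    Only full windows of ``window_snps`` SNPs are formed; SNPs near chromosome
    ends are judged over the (fewer) windows that actually contain them.
    """
    n, m = g.shape
    L = window_snps
    if m < L:
        return np.zeros((n, m), dtype=bool)
    het = g == 1
    mis = g == MISSING
    ch = np.zeros((n, m + 1), dtype=np.int32)
    cm = np.zeros((n, m + 1), dtype=np.int32)
    np.cumsum(het, axis=1, out=ch[:, 1:])
    np.cumsum(mis, axis=1, out=cm[:, 1:])
    w_het = ch[:, L:] - ch[:, :-L]
    w_mis = cm[:, L:] - cm[:, :-L]
    passing = (w_het <= het_allowed) & (w_mis <= missing_allowed)
    cp = np.zeros((n, passing.shape[1] + 1), dtype=np.int32)
    np.cumsum(passing, axis=1, out=cp[:, 1:])
    j = np.arange(m)
    lo = np.maximum(0, j - L + 1)
    hi = np.minimum(j, m - L)
    hits = cp[:, hi + 1] - cp[:, lo]
    n_win = (hi - lo + 1).astype(np.float64)
    return hits >= threshold * n_win - 1e-9


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


def _trim_to_allowances(
    het: np.ndarray, mis: np.ndarray, s: int, e: int,
    het_allowed: int, missing_allowed: int,
) -> tuple[int, int]:
    """Shrink candidate [s, e] until it satisfies the het/missing budget.

    A segment must start and end on a called homozygous SNP (hit-rate state
    can bleed onto flanking het/missing calls), and must contain at most the
    allowed numbers of heterozygous and missing calls.  Offending calls are
    removed from whichever end is cheaper (fewest SNPs lost), keeping the
    longest compliant interior.  Returns (s, e) with s > e when nothing
    compliant remains.
    """
    while s <= e:
        while s <= e and (het[s] or mis[s]):
            s += 1
        while e >= s and (het[e] or mis[e]):
            e -= 1
        if s > e:
            break
        off = np.flatnonzero(het[s : e + 1] | mis[s : e + 1])
        if (het[s : e + 1].sum() <= het_allowed
                and mis[s : e + 1].sum() <= missing_allowed):
            break
        if off[0] <= (e - s) - off[-1]:
            s = s + off[0] + 1
        else:
            e = s + off[-1] - 1
    return s, e


def detect_roh_single_pass(
    ds: GenotypeDataset, params: ROHCallingParams
) -> pd.DataFrame:
    """Detect ROH segments with one parameter set.

    Returns a segment table (``sample_id, chromosome, start_bp, end_bp,
    n_snps, length_bp, class_label``) sorted by (sample, chromosome, start).
    ``length_bp = end_bp - start_bp + 1`` (1-based inclusive SNP positions);
    ``class_label`` is empty here and filled by :func:`run_class_scheme`.
    """
    rows: list[tuple] = []
    sample_ids = ds.sample_ids.to_numpy()
    for chrom, midx in ds.iter_chromosomes():
        pos = ds.markers["position_bp"].to_numpy()[midx]
        g = ds.genotypes[:, midx]
        if g.shape[1] < params.window_snps:
            logger.warning(
                "chromosome %s has %d SNPs < window of %d; no calls made",
                chrom, g.shape[1], params.window_snps,
            )
            continue
        state = _roh_state(
            g, params.window_snps, params.scan_threshold,
            params.het_allowed, params.missing_allowed,
        )
        gap_break = np.diff(pos) > params.max_gap_bp
        het = g == 1
        mis = g == MISSING
        for i in range(ds.n_samples):
            for a, b in _runs_of_true(state[i]):
                # split candidate at inter-SNP gaps larger than max_gap_bp
                cut = a
                pieces = []
                for k in range(a, b):
                    if gap_break[k]:
                        pieces.append((cut, k))
                        cut = k + 1
                pieces.append((cut, b))
                for s, e in pieces:
                    s, e = _trim_to_allowances(
                        het[i], mis[i], s, e,
                        params.het_allowed, params.missing_allowed,
                    )
                    n_snps = e - s + 1
                    if n_snps < params.effective_min_snps:
                        continue
                    length = int(pos[e] - pos[s] + 1)
                    if length < params.min_length_bp:
                        continue
                    if length / n_snps > params.min_density_bp_per_snp:
                        continue
                    rows.append(
                        (sample_ids[i], chrom, int(pos[s]), int(pos[e]),
                         n_snps, length, "")
                    )
    if not rows:
        return empty_segment_table()
    out = pd.DataFrame(rows, columns=list(empty_segment_table().columns))
    return out.sort_values(
        ["sample_id", "chromosome", "start_bp"], kind="mergesort"
    ).reset_index(drop=True)


def classify_length(length_bp: int) -> str | None:
    """Class label for a segment length, or None below 2 Mb."""
    for label, lo, hi, _mis, _het in CLASS_SCHEME:
        if lo <= length_bp < hi:
            return label
    return None


def run_class_scheme(ds: GenotypeDataset, base: ROHCallingParams) -> pd.DataFrame:
    """Run the four-pass length-class scheme and return classified segments.

    Each pass uses its class's missing/heterozygote allowances and retains
    only segments whose length falls in that class's half-open interval
    ([2,4), [4,8), [8,16), [16,inf) Mb), so segments of 1-2 Mb — detectable
    under the 1 Mb floor — never enter the classified output.
    """
    parts = []
    for label, lo, hi, n_mis, n_het in CLASS_SCHEME:
        p = replace(
            base, missing_allowed=n_mis, het_allowed=n_het, class_range_bp=(lo, hi)
        )
        seg = detect_roh_single_pass(ds, p)
        keep = (seg["length_bp"] >= lo) & (seg["length_bp"] < hi)
        seg = seg.loc[keep].assign(class_label=label)
        parts.append(seg)
    out = pd.concat(parts, ignore_index=True)
    if out.empty:
        return empty_segment_table()
    return out.sort_values(
        ["sample_id", "chromosome", "start_bp", "class_label"], kind="mergesort"
    ).reset_index(drop=True)


def segment_class_summary(segments: pd.DataFrame) -> pd.DataFrame:
    """Per-class segment counts and proportions (the Table-1-style summary)."""
    counts = (
        segments["class_label"].value_counts().reindex(CLASS_LABELS, fill_value=0)
    )
    total = int(counts.sum())
    prop = counts / total if total else counts.astype(float)
    return pd.DataFrame(
        {"class_label": CLASS_LABELS, "n_segments": counts.to_numpy(),
         "proportion": prop.to_numpy()}
    )


class ROHDetector(BaseEstimator):
    """Data-adaptive ROH caller, sklearn-style.

    ``fit`` derives ``L`` and ``t`` from the dataset (unless given
    explicitly), runs the four-pass class scheme and stores the classified
    segment table.

    Parameters
    ----------
    alpha : float
        Genome-wide type-I error for the window-size formula.
    n_out : int
        Outer-flank SNPs excludable from a segment (threshold formula).
    mean_het : float or None
        Mean per-SNP heterozygosity; estimated from the data when None.
    window_snps, scan_threshold : int or float or None
        Explicit overrides for ``L`` and ``t``.
    min_length_bp, max_gap_bp, min_density_bp_per_snp : int
        Physical segment filters (1 Mb, 1 Mb, 150 kb defaults).

    Attributes
    ----------
    mean_het_ : float
    window_snps_ : int
    scan_threshold_ : float
    segments_ : pandas.DataFrame
        Classified ROH segments.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_out: int = 2,
        mean_het: float | None = None,
        window_snps: int | None = None,
        scan_threshold: float | None = None,
        min_length_bp: int = 1_000_000,
        max_gap_bp: int = 1_000_000,
        min_density_bp_per_snp: int = 150_000,
    ):
        self.alpha = alpha
        self.n_out = n_out
        self.mean_het = mean_het
        self.window_snps = window_snps
        self.scan_threshold = scan_threshold
        self.min_length_bp = min_length_bp
        self.max_gap_bp = max_gap_bp
        self.min_density_bp_per_snp = min_density_bp_per_snp

    def fit(self, X: GenotypeDataset, y=None) -> "ROHDetector":
        if not isinstance(X, GenotypeDataset):
            raise TypeError("ROHDetector expects a GenotypeDataset")
        self.mean_het_ = (
            mean_heterozygosity(X) if self.mean_het is None else float(self.mean_het)
        )
        self.window_snps_ = (
            compute_min_window_snps(self.alpha, X.n_markers, X.n_samples, self.mean_het_)
            if self.window_snps is None
            else int(self.window_snps)
        )
        self.scan_threshold_ = (
            compute_scan_threshold(self.n_out, self.window_snps_)
            if self.scan_threshold is None
            else float(self.scan_threshold)
        )
        base = ROHCallingParams(
            window_snps=self.window_snps_,
            scan_threshold=self.scan_threshold_,
            min_length_bp=self.min_length_bp,
            max_gap_bp=self.max_gap_bp,
            min_density_bp_per_snp=self.min_density_bp_per_snp,
        )
        self.segments_ = run_class_scheme(X, base)
        return self


def write_segments(segments: pd.DataFrame, path) -> None:
    """Write a segment table as TSV with header."""
    segments.to_csv(path, sep="\t", index=False)
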