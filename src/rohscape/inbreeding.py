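"""Genomic inbreeding coefficients F_HOM and F_ROH.

F_HOM measures the excess of observed over Hardy-Weinberg-expected homozygous
genotypes for one sample:

    F_HOM = (O_HOM - E_HOM) / (L - E_HOM)

where, over that sample's non-missing markers, ``O_HOM`` counts homozygous
genotypes, ``L`` counts markers, and ``E_HOM`` sums ``1 - 2pq * 2n/(2n-1)``
with ``p`` the dataset minor-allele frequency and ``n`` the number of
non-missing samples at the marker (the small-sample correction can be turned
off for the plain ``1 - 2pq`` form).

F_ROH is the fraction of the SNP-covered autosome that lies inside ROH:

    F_ROH = sum(L_ROH) / L_auto

with ``L_auto`` the summed per-chromosome span from first to last SNP.  The
headline coefficient F_ROH>2 uses segments >= 2 Mb; per-class coefficients
partition it by segment length class.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import MISSING, AutosomeSpan, GenotypeDataset
from .roh import CLASS_LABELS

logger = logging.getLogger(__name__)


def compute_f_hom(
    ds: GenotypeDataset, sample_size_correction: bool = True
) -> pd.DataFrame:
    """Per-sample excess-homozygosity inbreeding coefficient.

    Returns a DataFrame with columns ``sample_id`` and ``f_hom``.  Samples
    whose denominator ``L - E_HOM`` is exactly zero get NaN.  Monomorphic
    markers contribute an expectation of 1 homozygote and are retained.
    """
    if ds.n_samples < 2:
        raise ValueError("F_HOM needs >= 2 samples to estimate allele frequencies")
    g = ds.genotypes
    nonmiss = g != MISSING
    n = nonmiss.sum(axis=0)
    count = np.where(nonmiss, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, count / np.maximum(2 * n, 1), 0.0)
        corr = np.where(n > 0, 2 * n / np.maximum(2 * n - 1, 1), 1.0)
    if not sample_size_correction:
        corr = np.ones_like(corr)
    exp_hom = 1.0 - 2.0 * p * (1.0 - p) * corr

    o_hom = ((g == 0) | (g == 2)).sum(axis=1).astype(float)
    e_hom = nonmiss.astype(float) @ exp_hom
    l_called = nonmiss.sum(axis=1).astype(float)
    denom = l_called - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(np.abs(denom) > 1e-12, (o_hom - e_hom) / denom, np.nan)
    n_undef = int(np.isnan(f).sum())
    if n_undef:
        logger.warning("F_HOM undefined (L == E_HOM) for %d samples", n_undef)
    return pd.DataFrame({"sample_id": ds.sample_ids.to_numpy(), "f_hom": f})


def autosome_coverage_length(markers: pd.DataFrame) -> AutosomeSpan:
    """SNP-covered length per chromosome: ``max(pos) - min(pos) + 1``.

    A chromosome carrying a single SNP contributes 1 bp (logged as a warning).
    """
    per: dict[str, int] = {}
    for chrom, grp in markers.groupby("chromosome", sort=False):
        span = int(grp["position_bp"].max() - grp["position_bp"].min() + 1)
        if len(grp) == 1:
            logger.warning("chromosome %s has a single SNP; span counted as 1 bp", chrom)
        per[str(chrom)] = span
    return AutosomeSpan(per_chromosome=per)


def compute_f_roh(
    segments: pd.DataFrame,
    span: AutosomeSpan,
    sample_ids: Sequence[str] | None = None,
    min_length_bp: int = 2_000_000,
) -> pd.DataFrame:
    """Per-sample overall and per-class F_ROH.

    Parameters
    ----------
    segments
        Classified segment table (see :mod:`rohscape.roh`).
    span
        SNP-covered autosome length; ``span.total_bp`` is the denominator.
    sample_ids
        Samples to report; defaults to those present in ``segments``.
        Samples without segments get zeros.
    min_length_bp
        Floor for the overall coefficient (2 Mb: the headline F_ROH>2).

    Returns
    -------
    DataFrame with ``sample_id``, ``f_roh_overall`` and one
    ``f_roh_<class>`` column per length class, as fractions of ``L_auto``.

    Notes
    -----
    The overall coefficient is computed on the per-sample interval *union* of
    qualifying segments: detection passes with different het/missing
    allowances can call physically overlapping segments of different length
    classes, and summing them would count the shared base pairs twice (and
    could exceed 1).  Per-class coefficients sum each class's segments as
    reported, so their total may legitimately exceed ``f_roh_overall``.
    """
    if span.total_bp <= 0:
        raise ValueError("autosome span must be positive")
    if sample_ids is None:
        sample_ids = segments["sample_id"].unique()
    index = pd.Index(sample_ids, name="sample_id")

    kept = segments.loc[segments["length_bp"] >= min_length_bp]
    union_bp = {}
    for (sid, _chrom), grp in kept.groupby(["sample_id", "chromosome"], sort=False):
        total = 0
        last_end = -1
        for s, e in sorted(zip(grp["start_bp"], grp["end_bp"])):
            s = max(s, last_end + 1)
            if e >= s:
                total += e - s + 1
                last_end = max(last_end, e)
        union_bp[sid] = union_bp.get(sid, 0) + total
    overall = pd.Series(union_bp, dtype=float).reindex(index, fill_value=0)
    out = pd.DataFrame({"sample_id": index.to_numpy()})
    out["f_roh_overall"] = (overall / span.total_bp).to_numpy()
    for label in CLASS_LABELS:
        cls = segments.loc[segments["class_label"] == label]
        tot = cls.groupby("sample_id")["length_bp"].sum().reindex(index, fill_value=0)
        out[f"f_roh_{label}"] = (tot / span.total_bp).to_numpy()
    return out


def correlate_inbreeding(f_hom: Sequence[float], f_roh: Sequence[float]) -> float:
    """Pearson correlation between two inbreeding coefficient vectors.

    Pairs with a NaN in either vector are dropped; returns NaN (with a
    warning) if fewer than 3 pairs remain or either vector has zero variance.
    """
    x = np.asarray(f_hom, dtype=float)
    y = np.asarray(f_roh, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        warnings.warn("fewer than 3 complete pairs; correlation undefined")
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in an inbreeding vector; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


class InbreedingEstimator(BaseEstimator):
    """Compute F_HOM and F_ROH for every sample of a dataset.

    ``fit(X, segments=...)`` takes the genotype dataset (for F_HOM and the
    autosome span) and a classified ROH segment table (for F_ROH).

    Attributes
    ----------
    span_ : AutosomeSpan
    records_ : pandas.DataFrame
        ``sample_id, f_hom, f_roh_overall, f_roh_<class>...``
    correlation_ : float
        Pearson r between F_HOM and F_ROH>2 across samples.
    """

    def __init__(self, sample_size_correction: bool = True,
                 min_length_bp: int = 2_000_000):
        self.sample_size_correction = sample_size_correction
        self.min_length_bp = min_length_bp

    def fit(self, X: GenotypeDataset, segments: pd.DataFrame | None = None,
            y=None) -> "InbreedingEstimator":
        if segments is None:
            raise ValueError("InbreedingEstimator.fit requires segments=")
        f_hom = compute_f_hom(X, self.sample_size_correction)
        self.span_ = autosome_coverage_length(X.markers)
        f_roh = compute_f_roh(
            segments, self.span_, sample_ids=X.sample_ids.tolist(),
            min_length_bp=self.min_length_bp,
        )
        self.records_ = f_hom.merge(f_roh, on="sample_id")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.correlation_ = correlate_inbreeding(
                self.records_["f_hom"], self.records_["f_roh_overall"]
            )
        return self


def write_inbreeding(records: pd.DataFrame, path) -> None:
    """Write the per-sample inbreeding report as TSV (class columns in %)."""
    out = records.copy()
    for col in out.columns:
        if col.startswith("f_roh_") and col != "f_roh_overall":
            out[col] = out[col] * 100.0
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
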