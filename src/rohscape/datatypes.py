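"""Core data containers shared across the package.

Genotypes are stored as a dense ``(n_samples, n_markers)`` ``int8`` matrix of
minor-allele dosages: 0 (homozygous major), 1 (heterozygous), 2 (homozygous
minor) and :data:`MISSING` (= -1) for no-calls.  Marker and sample metadata
travel alongside the matrix as :class:`pandas.DataFrame` tables, mirroring how
AnnData keeps ``var``/``obs`` next to ``X``.

Segment-shaped results (ROH calls, islands, annotation hits) are plain
DataFrames with documented column schemas rather than bespoke classes, so they
compose directly with pandas group-bys and writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING: int = -1

#: Ovis aries autosome labels (1-26); anything else is treated as
#: non-autosomal by the QC filter.
OVINE_AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 27))

#: Column schema of an ROH segment table.
SEGMENT_COLUMNS: tuple[str, ...] = (
    "sample_id", "chromosome", "start_bp", "end_bp",
    "n_snps", "length_bp", "class_label",
)

#: Column schema of an ROH island table.
ISLAND_COLUMNS: tuple[str, ...] = (
    "chromosome", "start_bp", "end_bp", "length_bp", "n_snps", "peak_incidence",
)

MARKER_COLUMNS: tuple[str, ...] = (
    "chromosome", "position_bp", "snp_id", "allele1", "allele2",
)


def chromosome_sort_key(label: str) -> tuple[int, int, str]:
    """Sort key putting numeric chromosome labels first, in numeric order."""
    s = str(label)
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


def sort_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """Return ``markers`` sorted by (chromosome, position_bp), index reset."""
    key = markers["chromosome"].map(chromosome_sort_key)
    order = pd.DataFrame({"k": key, "p": markers["position_bp"]}).sort_values(
        ["k", "p"], kind="mergesort"
    ).index
    return markers.loc[order].reset_index(drop=True)


class RohscapeError(Exception):
    """Base class for fatal errors raised by this package."""


class ParseError(RohscapeError):
    """Malformed or mutually inconsistent input files."""


class QCError(RohscapeError):
    """Quality control removed every sample or every marker."""


@dataclass
class GenotypeDataset:
    """Samples x markers minor-allele dosage matrix with metadata.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_markers)`` integer matrix; entries in {0, 1, 2} or
        :data:`MISSING`.
    markers
        One row per marker with columns ``chromosome`` (str label),
        ``position_bp`` (1-based int), ``snp_id`` (unique str), ``allele1``,
        ``allele2``.  ``allele1`` is the allele counted by the dosage and is
        recoded to the dataset minor allele by the PLINK readers.
    samples
        One row per sample with columns ``sample_id`` (unique str) and
        ``population`` (str label used to analyse breeds separately).
    """

    genotypes: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        n, m = self.genotypes.shape
        if len(self.samples) != n or len(self.markers) != m:
            raise ValueError(
                f"genotype matrix is {n}x{m} but metadata describe "
                f"{len(self.samples)} samples and {len(self.markers)} markers"
            )
        for col in ("chromosome", "position_bp", "snp_id"):
            if col not in self.markers.columns:
                raise ValueError(f"markers table lacks required column {col!r}")
        if "sample_id" not in self.samples.columns:
            raise ValueError("samples table lacks required column 'sample_id'")
        if "population" not in self.samples.columns:
            self.samples = self.samples.assign(population="pop")
        self.markers = self.markers.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> pd.Series:
        return self.samples["sample_id"]

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on violation."""
        g = self.genotypes
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype entries outside {{0,1,2,missing}}")
        if self.markers["snp_id"].duplicated().any():
            dups = self.markers.loc[self.markers["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicated snp_ids: {sorted(set(dups))[:5]} ...")
        if (self.markers["position_bp"] < 1).any():
            raise ValueError("marker positions must be >= 1 (1-based)")
        srt = sort_markers(self.markers)
        if not (srt["snp_id"].to_numpy() == self.markers["snp_id"].to_numpy()).all():
            raise ValueError("markers are not sorted by (chromosome, position)")

    # -- subsetting -------------------------------------------------------
    def subset(
        self,
        sample_idx: np.ndarray | Sequence[int] | None = None,
        marker_idx: np.ndarray | Sequence[int] | None = None,
    ) -> "GenotypeDataset":
        """Return a new dataset restricted to the given positional indices."""
        g = self.genotypes
        samples = self.samples
        markers = self.markers
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            g = g[sample_idx]
            samples = samples.iloc[sample_idx]
        if marker_idx is not None:
            marker_idx = np.asarray(marker_idx)
            g = g[:, marker_idx]
            markers = markers.iloc[marker_idx]
        return GenotypeDataset(g.copy(), markers.reset_index(drop=True),
                               samples.reset_index(drop=True))

    def split_by_population(self) -> Iterator[tuple[str, "GenotypeDataset"]]:
        """Yield ``(population, dataset)`` pairs, one per population label."""
        for pop in self.samples["population"].unique():
            idx = np.flatnonzero((self.samples["population"] == pop).to_numpy())
            yield str(pop), self.subset(sample_idx=idx)

    def iter_chromosomes(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield ``(chromosome, marker positional indices)`` in map order."""
        chroms = self.markers["chromosome"].to_numpy()
        # markers are sorted, so each chromosome is one contiguous block
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                yield str(chroms[start]), np.arange(start, i)
                start = i


@dataclass(frozen=True)
class AutosomeSpan:
    """Length of autosome covered by SNPs, per chromosome and in total.

    The per-chromosome covered length is ``max(position) - min(position) + 1``;
    the total (``L_auto``) is their sum and is the denominator of F_ROH.
    """

    per_chromosome: Mapping[str, int]
    total_bp: int = field(default=0)

    def __post_init__(self) -> None:
        total = int(sum(self.per_chromosome.values()))
        if self.total_bp == 0:
            object.__setattr__(self, "total_bp", total)
        elif int(self.total_bp) != total and self.per_chromosome:
            raise ValueError("total_bp does not equal the sum of per-chromosome spans")

    @classmethod
    def from_total(cls, total_bp: int) -> "AutosomeSpan":
        """Build a span carrying only a known total length (single pseudo-entry)."""
        return cls(per_chromosome={"all": int(total_bp)}, total_bp=int(total_bp))


def empty_segment_table() -> pd.DataFrame:
    """An empty ROH segment table with the canonical schema."""
    return pd.DataFrame(
        {
            "sample_id": pd.Series(dtype=str),
            "chromosome": pd.Series(dtype=str),
            "start_bp": pd.Series(dtype=np.int64),
            "end_bp": pd.Series(dtype=np.int64),
            "n_snps": pd.Series(dtype=np.int64),
            "length_bp": pd.Series(dtype=np.int64),
            "class_label": pd.Series(dtype=str),
        }
    )
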