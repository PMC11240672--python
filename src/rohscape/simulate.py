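"""Synthetic diploid SNP-array populations with planted autozygosity.

The generator emulates the shape of a 50K-chip sheep dataset: ~1000 diploid
samples x ~34,000 autosomal SNPs on 26 chromosomes, mean per-SNP
heterozygosity around 0.36, and per-animal autozygous segments drawn from the
2-4 / 4-8 / 8-16 / >16 Mb length classes to reach a target genomic fraction
(F_ROH around 0.05).  An optional "island" plants an identical autozygous
segment at one fixed region in a random subset of the population, giving the
island-calling stage a known selection-signature-like target.

Baseline genotypes are independent across markers (Hardy-Weinberg at each
marker's allele frequency); there is no background linkage disequilibrium.
Every draw flows from the single ``seed``, so a config reproduces its dataset
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset
from .roh import classify_length

__all__ = ["IslandSpec", "SimulationConfig", "SimulationTruth", "simulate_population"]


@dataclass(frozen=True)
class IslandSpec:
    """A fixed autozygous region carried by a fraction of the population."""

    chromosome: int
    start_bp: int
    end_bp: int
    carrier_fraction: float

    def __post_init__(self) -> None:
        if not (0 <= self.carrier_fraction <= 1):
            raise ValueError("carrier_fraction must lie in [0, 1]")
        if self.end_bp <= self.start_bp:
            raise ValueError("island end must exceed start")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults: 1047 samples, 33,965 SNPs on 26 x 101 Mb.

    ``target_f_roh`` is the planted autozygous genome fraction per sample
    (scalar for all samples or one value per sample); ``class_mix`` gives the
    probability of drawing each planted-segment length class (2-4, 4-8, 8-16,
    >16 Mb, the latter capped at 32 Mb).  ``segment_lengths_bp``, when given,
    overrides both and plants exactly those lengths in every sample.
    ``het_error_rate`` flips planted homozygous calls to heterozygous;
    ``missing_rate`` applies genome-wide.
    """

    n_samples: int = 1047
    n_chromosomes: int = 26
    chrom_length_bp: int = 101_000_000
    n_snps: int = 33_965
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_f_roh: float | Sequence[float] = 0.05
    class_mix: tuple[float, float, float, float] = (0.15, 0.43, 0.26, 0.16)
    segment_lengths_bp: tuple[int, ...] | None = None
    island: IslandSpec | None = None
    het_error_rate: float = 0.0
    missing_rate: float = 0.005
    #: minimum bp between two planted segments of one sample, so distinct
    #: true runs stay distinct to a window-based caller
    min_separation_bp: int = 1_000_000
    population: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_samples < 1 or self.n_snps < 1 or self.n_chromosomes < 1:
            raise ValueError("population dimensions must be positive")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")

    @property
    def genome_bp(self) -> int:
        return self.n_chromosomes * self.chrom_length_bp


@dataclass
class SimulationTruth:
    """Ground truth of a simulated population.

    ``segments`` has columns ``sample_id, chromosome, start_bp, end_bp,
    length_bp, class_label`` (planted coordinates, including island copies);
    ``true_fraction`` maps sample_id -> planted autozygous genome fraction;
    ``island_carriers`` lists the samples carrying the island.
    """

    segments: pd.DataFrame
    true_fraction: pd.Series
    island_carriers: list[str] = field(default_factory=list)


_CLASS_RANGES = ((2_000_000, 4_000_000), (4_000_000, 8_000_000),
                 (8_000_000, 16_000_000), (16_000_000, 32_000_000))


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def _overlaps(occupied: list[tuple[int, int]], start: int, end: int,
              margin: int = 0) -> bool:
    return any(s - margin <= end and start <= e + margin for s, e in occupied)


def _plan_sample_segments(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    target_bp: int,
    occupied: dict[int, list[tuple[int, int]]],
) -> list[tuple[int, int, int]]:
    """Plan (chrom, start, end) planted segments totalling >= target_bp."""
    if cfg.segment_lengths_bp is not None:
        lengths = list(cfg.segment_lengths_bp)
    else:
        lengths = []
        total = 0
        while total < target_bp:
            c = rng.choice(4, p=np.asarray(cfg.class_mix))
            lo, hi = _CLASS_RANGES[c]
            hi = min(hi, cfg.chrom_length_bp)  # long class capped by genome shape
            if lo >= hi:
                raise ValueError(
                    f"chromosomes of {cfg.chrom_length_bp} bp cannot hold "
                    f"segments of the {lo}-bp class"
                )
            ln = int(rng.integers(lo, hi))
            lengths.append(ln)
            total += ln
    placed = []
    for ln in lengths:
        if ln >= cfg.chrom_length_bp:
            raise ValueError(
                f"segment of {ln} bp does not fit a {cfg.chrom_length_bp} bp chromosome"
            )
        for _try in range(1000):
            chrom = int(rng.integers(1, cfg.n_chromosomes + 1))
            start = int(rng.integers(1, cfg.chrom_length_bp - ln + 1))
            end = start + ln - 1
            if not _overlaps(occupied[chrom], start, end, cfg.min_separation_bp):
                occupied[chrom].append((start, end))
                placed.append((chrom, start, end))
                break
        else:
            raise ValueError(
                "could not place planted segments; requested autozygosity too "
                "dense for the genome"
            )
    return placed


def simulate_population(cfg: SimulationConfig) -> tuple[GenotypeDataset, SimulationTruth]:
    """Simulate a genotype dataset plus its ground truth.

    Raises
    ------
    ValueError
        If the requested planted length cannot be placed in the genome.
    """
    rng = np.random.default_rng(cfg.seed)

    # marker map
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    chrom_pos: list[np.ndarray] = [
        _draw_positions(rng, int(k), cfg.chrom_length_bp) for k in per_chrom
    ]
    markers = pd.DataFrame(
        {
            "chromosome": np.repeat(
                [str(c + 1) for c in range(cfg.n_chromosomes)], per_chrom
            ),
            "position_bp": np.concatenate(chrom_pos).astype(np.int64),
        }
    )
    markers["snp_id"] = [
        f"snp_{c}_{p}" for c, p in zip(markers["chromosome"], markers["position_bp"])
    ]
    markers["allele1"] = "A"
    markers["allele2"] = "B"

    freqs = rng.uniform(*cfg.maf_range, size=cfg.n_snps)

    sample_ids = [f"{cfg.population}_{i:05d}" for i in range(cfg.n_samples)]

    # island carriers drawn before per-sample planning (fixed rng order)
    carriers: list[int] = []
    if cfg.island is not None and cfg.island.carrier_fraction > 0:
        n_car = int(round(cfg.island.carrier_fraction * cfg.n_samples))
        carriers = sorted(rng.choice(cfg.n_samples, size=n_car, replace=False).tolist())

    target = np.broadcast_to(
        np.asarray(cfg.target_f_roh, dtype=float), (cfg.n_samples,)
    )
    truth_rows: list[tuple] = []
    plan: list[list[tuple[int, int, int]]] = []
    for i in range(cfg.n_samples):
        occupied: dict[int, list[tuple[int, int]]] = {
            c: [] for c in range(1, cfg.n_chromosomes + 1)
        }
        segs: list[tuple[int, int, int]] = []
        if cfg.island is not None and i in carriers:
            isl = (cfg.island.chromosome, cfg.island.start_bp, cfg.island.end_bp)
            occupied[cfg.island.chromosome].append((cfg.island.start_bp, cfg.island.end_bp))
            segs.append(isl)
        target_bp = int(target[i] * cfg.genome_bp)
        remaining = target_bp - sum(e - s + 1 for _, s, e in segs)
        if remaining > 0 or cfg.segment_lengths_bp is not None:
            segs += _plan_sample_segments(rng, cfg, max(remaining, 0), occupied)
        plan.append(segs)
        for chrom, s, e in segs:
            ln = e - s + 1
            truth_rows.append(
                (sample_ids[i], str(chrom), s, e, ln, classify_length(ln) or "<2")
            )

    # genotypes, chromosome block by chromosome block
    genotypes = np.empty((cfg.n_samples, cfg.n_snps), dtype=np.int8)
    offsets = np.concatenate(([0], np.cumsum(per_chrom)))
    for c in range(cfg.n_chromosomes):
        a, b = offsets[c], offsets[c + 1]
        block = rng.binomial(2, freqs[a:b], size=(cfg.n_samples, b - a)).astype(np.int8)
        pos = chrom_pos[c]
        for i in range(cfg.n_samples):
            for chrom, s, e in plan[i]:
                if chrom != c + 1:
                    continue
                j0 = np.searchsorted(pos, s, side="left")
                j1 = np.searchsorted(pos, e, side="right")
                if j1 <= j0:
                    continue
                p_seg = freqs[a + j0 : a + j1]
                hom_minor = rng.random(j1 - j0) < p_seg
                block[i, j0:j1] = np.where(hom_minor, 2, 0).astype(np.int8)
                if cfg.het_error_rate > 0:
                    err = rng.random(j1 - j0) < cfg.het_error_rate
                    block[i, j0:j1][err] = 1
        if cfg.missing_rate > 0:
            miss = rng.random(block.shape) < cfg.missing_rate
            block[miss] = MISSING
        genotypes[:, a:b] = block

    samples = pd.DataFrame({"sample_id": sample_ids, "population": cfg.population})
    ds = GenotypeDataset(genotypes, markers, samples)
    # planting homozygotes can push the counted allele past 0.5 frequency;
    # keep the package-wide minor-allele dosage convention
    from .genotype_io import recode_to_minor

    ds = recode_to_minor(ds)
    ds.validate()

    truth_segments = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "chromosome", "start_bp", "end_bp", "length_bp", "class_label"],
    )
    planted = truth_segments.groupby("sample_id")["length_bp"].sum()
    true_fraction = (
        planted.reindex(sample_ids, fill_value=0) / cfg.genome_bp
    ).rename("true_fraction")
    truth = SimulationTruth(
        segments=truth_segments,
        true_fraction=true_fraction,
        island_carriers=[sample_ids[i] for i in carriers],
    )
    return ds, truth
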