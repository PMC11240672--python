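"""Shared fixtures and the brute-force ROH oracle used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohscape import GenotypeDataset, ROHCallingParams
from rohscape.datatypes import MISSING


def make_dataset(
    genotypes,
    positions=None,
    chromosomes=None,
    populations=None,
) -> GenotypeDataset:
    """Build a small GenotypeDataset from plain lists.

    ``positions`` defaults to 1-based 100 kb spacing on one chromosome.
    """
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if positions is None:
        positions = [100_000 * (j + 1) for j in range(m)]
    if chromosomes is None:
        chromosomes = ["1"] * m
    markers = pd.DataFrame(
        {
            "chromosome": [str(c) for c in chromosomes],
            "position_bp": np.asarray(positions, dtype=np.int64),
            "snp_id": [f"snp{j}" for j in range(m)],
            "allele1": "A",
            "allele2": "B",
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "population": populations if populations is not None else ["pop"] * n,
        }
    )
    return GenotypeDataset(g, markers, samples)


def brute_force_single_pass(
    g_row: np.ndarray, positions: np.ndarray, params: ROHCallingParams
) -> list[tuple[int, int]]:
    """Window-scan ROH caller written as explicit loops (the oracle).

    Returns (start_idx, end_idx) marker-index pairs for one sample on one
    chromosome, following the published sliding-window semantics step by
    step: enumerate every full window, compute every SNP's hit rate, take
    maximal in-state runs, split at large gaps, trim ends onto called
    homozygous SNPs, then apply the SNP-count, length, density and
    segment-content filters.
    """
    m = len(g_row)
    L = params.window_snps
    if m < L:
        return []
    het = [int(x == 1) for x in g_row]
    mis = [int(x == MISSING) for x in g_row]

    passing = []
    for w in range(m - L + 1):
        win = list(range(w, w + L))
        ok = (
            sum(het[k] for k in win) <= params.het_allowed
            and sum(mis[k] for k in win) <= params.missing_allowed
        )
        passing.append(ok)

    state = []
    for j in range(m):
        covering = [w for w in range(m - L + 1) if w <= j <= w + L - 1]
        hits = sum(passing[w] for w in covering)
        state.append(hits / len(covering) >= params.scan_threshold)

    runs = []
    j = 0
    while j < m:
        if state[j]:
            k = j
            while k + 1 < m and state[k + 1]:
                k += 1
            runs.append((j, k))
            j = k + 1
        else:
            j += 1

    pieces = []
    for a, b in runs:
        cut = a
        for k in range(a, b):
            if positions[k + 1] - positions[k] > params.max_gap_bp:
                pieces.append((cut, k))
                cut = k + 1
        pieces.append((cut, b))

    out = []
    for a, b in pieces:
        # trim until the candidate starts/ends on a called homozygous SNP and
        # holds at most the allowed het/missing calls (outermost offender on
        # the cheaper side removed first)
        while a <= b:
            while a <= b and (het[a] or mis[a]):
                a += 1
            while b >= a and (het[b] or mis[b]):
                b -= 1
            if a > b:
                break
            offenders = [k for k in range(a, b + 1) if het[k] or mis[k]]
            if (sum(het[a : b + 1]) <= params.het_allowed
                    and sum(mis[a : b + 1]) <= params.missing_allowed):
                break
            if offenders[0] - a <= b - offenders[-1]:
                a = offenders[0] + 1
            else:
                b = offenders[-1] - 1
        if a > b:
            continue
        n_snps = b - a + 1
        if n_snps < params.effective_min_snps:
            continue
        length = positions[b] - positions[a] + 1
        if length < params.min_length_bp:
            continue
        if length / n_snps > params.min_density_bp_per_snp:
            continue
        out.append((a, b))
    return out


@pytest.fixture(scope="session")
def inbred_population():
    """A mid-size simulated population with planted autozygosity + island.

    26 chromosomes of 40 Mb with ~25 kb SNP spacing, so even 2-Mb segments
    comfortably exceed the adaptive window size; shared across tests to keep
    the suite fast.
    """
    from rohscape import IslandSpec, SimulationConfig, simulate_population

    cfg = SimulationConfig(
        n_samples=120,
        n_chromosomes=26,
        chrom_length_bp=40_000_000,
        n_snps=26 * 1600,
        # per-sample targets spread like real inbreeding (mean ~0.05,
        # range 0-0.2) so F_HOM and F_ROH have variance to correlate over
        target_f_roh=tuple(0.2 * np.linspace(0.0, 1.0, 120) ** 2),
        island=IslandSpec(6, 34_253_440, 38_238_124, 0.4),
        missing_rate=0.002,
        seed=11,
    )
    return cfg, simulate_population(cfg)
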