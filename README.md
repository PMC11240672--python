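# rohscape

Runs-of-homozygosity (ROH) analysis for livestock SNP-array genotypes:
data-adaptive ROH calling, genomic inbreeding coefficients, ROH-island
detection with gene/QTL annotation, and population structure — plus a
synthetic genotype generator with planted autozygosity so every stage can be
validated against known truth.

## Who this is for

Conservation and breeding geneticists working with medium-density SNP chips
(e.g. the ovine 50K BeadChip) who need per-animal genomic inbreeding and
population-level selection signatures from PLINK-format genotypes, with
reproducible, parameter-explicit methodology. All heavy lifting is in plain
functions and sklearn-style estimator classes (`fit`, fitted `*_` attributes,
`get_params`), so the stages compose with each other and with scikit-learn
tooling.

## The methods

**Adaptive calling parameters.** The minimum number of SNPs in the scanning
window and in a final ROH segment is

&nbsp;&nbsp;&nbsp;&nbsp;L = ln(α / (nₛ·nᵢ)) / ln(1 − het)

with nₛ SNPs per individual, nᵢ individuals, het the mean per-SNP
heterozygosity and α the tolerated genome-wide type-I error. The per-SNP
threshold declaring a SNP "in ROH state" is t = floor((N_out + 1)/L, 3
decimals), which tolerates N_out SNPs on each outer flank of a true segment.

**Detection.** A window of L SNPs slides along each chromosome per sample; a
window passes when it holds at most the allowed heterozygous/missing calls.
Each SNP's hit rate is the fraction of windows covering it that pass; runs of
SNPs with hit rate ≥ t become candidates, which are split at inter-SNP gaps
> 1 Mb, trimmed to start/end on called homozygous SNPs within their
het/missing budget, and filtered on SNP count (≥ L), length (≥ 1 Mb) and
density (≥ 1 SNP / 150 kb). Four passes with 50K-chip allowances — 0/0, 1/0,
2/0, 4/1 missing/het for the 2–4, 4–8, 8–16 and >16 Mb classes — are combined,
each pass keeping only segments in its own length class.

**Inbreeding.** F_HOM = (O_HOM − E_HOM)/(L − E_HOM) from the excess of
observed over Hardy–Weinberg-expected homozygous genotypes;
F_ROH = ΣL_ROH / L_auto, the fraction of the SNP-covered autosome inside ROH
≥ 2 Mb, overall and per length class (long classes indicate recent
inbreeding).

**Islands.** Per-SNP ROH incidence = carriers / genotyped individuals; SNPs
in the top 0.1% of the incidence distribution (empirical quantile, or a
z-score variant) that are also covered in ≥ 30% of the population merge into
ROH islands — candidate selection signatures. Genes and QTLs within ±500 kb
are reported, with one-sided hypergeometric trait enrichment and
Benjamini–Hochberg adjustment.

**Structure.** Identity-by-state distances and classical multidimensional
scaling.

## Worked example

```python
import numpy as np
import rohscape as rs

cfg = rs.SimulationConfig(
    n_samples=80, n_chromosomes=26, chrom_length_bp=40_000_000,
    n_snps=26 * 1600,
    target_f_roh=tuple(0.15 * np.linspace(0, 1, 80) ** 2),
    island=rs.IslandSpec(6, 34_253_440, 38_238_124, 0.4), seed=42,
)
ds, truth = rs.simulate_population(cfg)
ds = rs.apply_qc(ds)                           # call rates 0.9 / 0.95, autosomes only

det = rs.ROHDetector(alpha=0.05, n_out=2).fit(ds)
print(f"L = {det.window_snps_}, t = {det.scan_threshold_}")
est = rs.InbreedingEstimator().fit(ds, segments=det.segments_)
print(f"mean F_ROH>2 = {est.records_.f_roh_overall.mean():.4f}")
print(f"Pearson r(F_HOM, F_ROH>2) = {est.correlation_:.3f}")
caller = rs.IslandCaller().fit(ds, segments=det.segments_)
print(caller.islands_.to_string(index=False))
```

prints

```
L = 43, t = 0.069
mean F_ROH>2 = 0.0515
Pearson r(F_HOM, F_ROH>2) = 0.983
chromosome  start_bp   end_bp  length_bp  n_snps  peak_incidence
         6  35053787 36626375    1572588      62             0.4
```

The window size L = 43 follows from this population's size and
heterozygosity; the mean F_ROH>2 of 0.0515 estimates the planted mean
autozygous fraction (0.0573 here — missing calls cost a little recovery in
the strict 0-missing short classes); the two inbreeding estimators agree
at r = 0.98; and the planted island on chromosome 6, carried by 40% of
samples, is recovered as the peak-incidence subregion of the planted
interval.

A `rohscape` CLI mirrors the library (`simulate`, `qc`, `detect`,
`inbreeding`, `islands`, `run --config config.yaml`); the pipeline runner
writes per-population TSV tables plus a manifest whose reruns are
byte-identical.

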