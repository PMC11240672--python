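# Methods

## Scope and model

The package analyses diploid autosomal SNP-array genotypes, coded as
minor-allele dosage {0, 1, 2} with a missing sentinel. An ROH (run of
homozygosity) is a contiguous stretch of homozygous genotypes interpreted as
autozygosity; inbreeding is summarised per animal by F_HOM (excess
homozygosity relative to Hardy–Weinberg) and F_ROH (genomic fraction inside
ROH); population-level homozygosity hotspots (ROH islands) are read as
candidate selection signatures. Default chromosome labels are the 26 Ovis
aries autosomes; nothing else is sheep-specific.

## Genotype coding and PLINK IO

Dosage counts `allele1` of each marker. The text (.ped/.map) reader infers
the counted allele as the minor-by-count allele (ties broken
lexicographically), since .ped carries no allele order; the binary
(.bed/.bim/.fam) reader honors the .bim A1 allele, so binary round trips are
exact for any coding. `recode_to_minor` makes the coding a deterministic
function of the data (flip when the counted-allele frequency exceeds 0.5, or
equals 0.5 with the lexicographically larger code) and is applied after batch
merging and by the simulator. Homozygote/heterozygote status — all ROH and
F_HOM logic — is invariant to this choice.

QC order is fixed: non-autosomal and all duplicate-position markers first,
then SNP call rate (default ≥ 0.95), then sample call rate (default ≥ 0.9)
over the surviving markers. "Duplicate position" drops *every* marker sharing
an exact (chromosome, bp), reading "unique positions" strictly. The order
matters (a sample can be rescued by removal of a low-call-rate marker) and is
asserted by a test.

## Adaptive calling parameters

* `L = round( ln(α/(nₛ·nᵢ)) / ln(1 − het) )` — the minimum SNPs in the
  scanning window *and* in a final segment. `het` is the mean per-SNP observed
  heterozygote frequency, estimated from the analysed population unless
  supplied. α defaults to 0.05.
* `t = floor((N_out + 1)/L, 3 decimals)` with N_out = 2 by default. The floor
  is computed in integer arithmetic (`(1000·(N_out+1)) // L / 1000`); naive
  floating-point flooring gives 0.059 instead of 0.06 at L = 50.

At 50K-chip scale (33,965 SNPs; 1,047 or 2,323 animals; het ≈ 0.335/0.357)
these yield L = 50/48 and t = 0.06/0.062.

## Detection semantics

Windows of exactly L SNPs (no truncated edge windows) pass when they contain
at most the allowed heterozygous and missing calls. A SNP's hit rate divides
its passing covering windows by the windows that actually contain it, so SNPs
near chromosome ends are judged over fewer windows. SNPs with hit rate ≥ t
are in ROH state; maximal in-state runs are candidates.

Candidates are then (1) split at single inter-SNP gaps > 1 Mb; (2) trimmed
from the outside until they start and end on a called homozygous SNP *and*
contain at most the pass's het/missing budget — the offending call nearest an
end is removed from whichever side costs fewer SNPs; (3) kept if they have
≥ L SNPs, span ≥ 1 Mb, and average at most 150 kb per SNP. Trimming rather
than discarding over-budget candidates matters: the hit-rate state bleeds one
to three SNPs onto flanking heterozygous/missing calls, and discarding would
throw away clean multi-megabase runs because of their flanks.

Two consequences are deliberate and documented rather than "fixed":

* Relaxing the allowances grows the in-ROH-state SNP set monotonically (a
  theorem, property-tested), but *final* coverage is not monotone — a
  permissive pass can merge two clean runs across a heterozygote into one
  candidate whose trimmed form differs from either.
* Because each class's pass keeps only segments whose *detected* length falls
  in its half-open interval ([2,4), [4,8), [8,16), [16,∞) Mb), one physical
  region can be called in two classes (e.g. a clean 3 Mb sub-run inside a
  16 Mb run that needs the 1-het allowance). Per-class F_ROH therefore sums
  to more than the overall coefficient on occasion — the same discrepancy
  visible in published per-class tables.

Segments of 1–2 Mb pass detection (the 1 Mb floor) but belong to no class and
are excluded from F_ROH>2.

## Inbreeding coefficients

F_HOM per sample uses O_HOM (non-missing homozygous genotypes), L (non-missing
markers) and E_HOM = Σ (1 − 2pq·2n/(2n−1)) over those markers, with p the
population minor-allele frequency and n the marker's non-missing sample count.
The 2n/(2n−1) small-sample correction matches the dominant implementation of
this estimator and can be disabled for the plain 1 − 2pq form. Frequencies are
computed within the analysed population after QC, never pooled across breeds.
Monomorphic markers contribute an expectation of 1 and are retained; a sample
with L = E_HOM exactly is reported as NaN.

L_auto is the summed per-chromosome span max(pos) − min(pos) + 1.
F_ROH overall divides the per-sample interval *union* of segments ≥ 2 Mb by
L_auto (union, because cross-class physical overlap would otherwise be
double-counted and the coefficient could exceed 1); per-class coefficients are
plain within-class sums, reported in percent in the TSV output.

## Islands

Incidence per SNP counts samples with any ≥ 2 Mb segment covering its
position (overlapping segments of one sample count once). The island
threshold is the genome-wide empirical 0.999 quantile of the incidence
distribution by default; a z-score variant (mean + Φ⁻¹(0.999)·sd) assumes
normality and is exposed as an option, as is an optional 1 Mb max-pooling
smoother applied before thresholding (off by default; its role in the
published protocol is ambiguous). Qualifying SNPs must also reach 30%
incidence; runs of qualifying SNPs with gaps ≤ 1 Mb merge, and single-SNP
islands are dropped. Island length is end − start; gene lengths are inclusive
(end − start + 1) — both conventions appear in published coordinate tables
and each is applied where that table applies it.

Note that when an island's SNPs are themselves the top of the incidence
distribution (the usual case), the 0.999 quantile falls *within* the island's
incidence values, so the called interval is the peak subregion of the true
island, not its full extent.

## Annotation and enrichment

Gene-level records are parsed from GTF or GFF3 (feature type `gene` only);
QTLs from the Animal-QTLdb GFF dialect (`QTL_ID`, `Name`, `trait_type`
attributes) or a minimal TSV. A feature is associated with an island when its
interval intersects the island ± 500 kb. Trait enrichment is one-sided
hypergeometric — P[X ≥ k] for k trait QTLs among the n island-associated
QTLs drawn from a database of N containing K of the trait — with
Benjamini–Hochberg adjustment across traits; the hypergeometric is chosen
over chi-square for validity at the small counts typical of island hits.
Richness factor = k/K.

## Structure

IBS similarity is the mean over jointly non-missing markers of shared
alleles/2 (shared = 2 − |g₁ − g₂|), computed with indicator-matrix products.
Classical (Torgerson) MDS eigendecomposes the double-centered squared
distances; component shares are relative to the sum of positive eigenvalues,
a run aborts if negative eigenvalue mass exceeds positive, and component
signs are fixed so the first sample's coordinates are nonnegative (the math
leaves signs free; fixing them stabilises outputs and tests).

## Synthetic populations

The generator emulates the shape of a 50K-chip sheep dataset. Defaults:
1,047 samples × 33,965 SNPs on 26 × 101 Mb autosomes (≈ 2.63 Gb), MAF ~
U(0.05, 0.5) (mean heterozygosity ≈ 0.36), target autozygous fraction 0.05
per sample, planted-segment class mix (0.15, 0.43, 0.26, 0.16) over the
2–4/4–8/8–16/>16 Mb classes (>16 capped at 32 Mb or the chromosome length),
and missing rate 0.005 (consistent with ≥ 0.95 call-rate data). Baseline
genotypes are Hardy–Weinberg draws independent across markers — there is no
background LD, which is sufficient for every statistic implemented here and
is exactly why LD-based methods (effective population size from LD decay)
are out of scope. Planted segments overwrite genotypes with a homozygote for
one frequency-weighted draw per marker (runs are homozygous but not
monomorphic across carriers); heterozygote errors (default 0) and missingness
are then injected. Segments of one sample are placed without overlap and with
≥ 1 Mb separation, so distinct true runs remain distinguishable to a
window-based caller. An optional island plants an identical segment at a
fixed region in a carrier fraction of samples. Everything derives from one
seed; identical configs are bit-identical.

What passing tests on these data do *not* show: robustness to LD structure,
to array ascertainment bias, to genotyping-batch effects, or to non-uniform
recombination/marker density — real-data behaviour on those axes is
untested by construction.

## Problem sizes and tolerances

Tests and the acceptance script run scaled-down populations — typically 120
samples on 26 × 40 Mb chromosomes with ~25 kb marker spacing (41,600 SNPs),
chosen so that even 2 Mb segments comfortably exceed the adaptive window of
~44 SNPs. Planted-bp recovery ≥ 95% is asserted on clean data (no missing
calls): the 0-missing allowances of the 2–8 Mb classes make segments
containing a missing call unrecoverable in those classes by definition
(measured: ≈ 99% clean, ≈ 97.6% at missing rate 0.002). Endpoint accuracy is
asserted at 250 kb (~5% of a 5 Mb segment): N_out = 2 flank SNPs are excluded
by design and marker gaps are exponential. F_ROH recovery is asserted at
± 0.01 of the planted fraction; the F_HOM/F_ROH Pearson r > 0.9 threshold is
evaluated on populations whose planted inbreeding varies over 0–0.2, since a
correlation needs between-animal variance. Window-scanner correctness is
established against a loop-by-loop brute-force oracle on ≤ 200-SNP instances,
and enrichment p-values against explicit hypergeometric tail sums.

## Known limitations

* No LD-aware methods (consecutive-runs callers, LD pruning effects, N_e).
* The hit-rate scanner is O(samples × SNPs) per pass and four passes are
  run; at full 50K scale a population takes tens of seconds, which is fine
  for analysis but not tuned for biobank scale.
* Heterozygosity-rich regions, F_PED/F_GRM estimators and GO/KEGG enrichment
  are out of scope.
* The island caller reports peak subregions (see above); downstream flanking
  windows (±500 kb) absorb most of the difference for annotation purposes.
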