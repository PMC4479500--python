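# Methods

This note documents the models, defaults and design choices behind
gctmethyl, and what the synthetic-cohort tests do and do not demonstrate
about real array data.

## Data model and preprocessing

Input is a normalized β matrix (probes × samples, β ∈ [0, 1]) with a
1-based, (chromosome, position)-sorted probe manifest.  M-values are
computed as M = log2(b / (1 − b)) with b clamped to [ε, 1 − ε],
ε = 1e-6 by default (configurable), purely to keep M finite at β ∈ {0, 1};
within the clamp region the transform round-trips to < 1e-12.  All test
statistics use M; β is reported for interpretation.

Probe exclusion removes (a) probes *not* detected (detection p < 0.01) in
at least 95% of samples, (b) cross-hybridizing probes from a supplied
list, (c) probes with a SNP record at distance ≤ 10 bp and allele
frequency ≥ 0.05 (both boundaries inclusive).  Exclusion reasons may
overlap; the filter report reconciles `n_valid + |union excluded| =
n_input`.  When no detection matrix is supplied the detection filter is
skipped with a logged notice.  The detection rule is implemented as
"retain iff detected in ≥ 95% of samples", the standard reading of the
detection-rate convention.

The low-variability filter drops features whose sample standard deviation
(ddof = 1; the conventional unbiased estimator) of M across *all* samples
is below the threshold — 0.8 for probes, 0.6 for segments.  Exclusion is
strict (<), so a feature exactly at the threshold is retained.

## Probe annotation

Functional categories are derived from manifest columns (TSS distance
class, gene-region classes, island, repeat, miR/snRNA association) plus
imprinting resources.  TSSAssociated is the union of TSS200 and TSS1500.
"Close to the TSS of an imprinted gene" means within 200/1500 bp upstream
on the annotated strand, with distance 0 (at the TSS) inside both
windows; per the not-mutually-exclusive convention, probes inside an ICR
of the matching allele are also members of the IMPR_* classes, so
IMPR_*200 ⊆ IMPR_*1500 always holds.  ICR intervals are merged within
(chromosome, allele), book-ended intervals included; overlapping
intervals with conflicting alleles are kept separate with a logged
warning.  Repeat/miR/snRNA assignment is taken from manifest columns as
precomputed annotation — rebuilding it from RepeatMasker/miRBase is a
data-preparation concern outside this package.

The exact composition of the functional category list is configurable
(`classify_probes(..., categories=...)`); the default is the 17 named
functional classes plus X_CHROM, with X_CHROM excluded from the
functional count used for the Bonferroni threshold.

## HMM segmentation

Observations are per-probe vectors of M values across the tumour samples
(cell lines excluded); each chromosome is an independent sequence sharing
one parameter set.  Emissions are diagonal-covariance Gaussians — chosen
for identifiability with tens of samples and desk-scale cost — with a
hard per-dimension variance floor (default 1e-3) applied in the M-step.
Inter-probe genomic distance is not modelled (homogeneous transitions).

Initialization per restart: emission means from a seeded k-means on the
probe vectors (one initialization per restart, different seeds), cluster
variances floored, uniform initial distribution, 0.9 self-loop /
uniform off-diagonal transitions.  Baum–Welch runs in log space until the
relative log-likelihood change is < 1e-6 or 500 iterations; the best of 3
restarts by final likelihood is kept.  Everything is deterministic given
the seed.

State-count selection fits an ascending grid and picks the last k before
the per-step likelihood gain falls below 1% (configurable) of the total
gain accumulated over the grid — a scale-free saturation rule; absolute
log-likelihoods grow with cohort size, so a fraction of |log L| would
not transfer across problem sizes.  The pipeline default is k = 20 at
study scale; the synthetic default cohort uses k = 6, which covers its
pattern vocabulary (shared low/high domains, the hemi-methylated female
X, ICR patterns, planted blocks).

Viterbi decoding is per chromosome; maximal runs of one state form
segments, which therefore partition the probes.  Degenerate states with
no assigned probes are excluded from state medians with a warning.

## Differential testing

Mann–Whitney U is two-sided: exact (dynamic-programming null
distribution, p = min(1, 2·min(P(U ≤ u), P(U ≥ u)))) when both groups
have ≤ 12 samples and the feature has no ties, otherwise the
tie-corrected normal approximation with continuity correction.
Benjamini–Hochberg adjustment runs across all tested features of a route.

Bootstrap validation draws 100 stratified resamples (with replacement
within each group, preserving group sizes).  Within each replicate the
candidate features are re-tested and re-adjusted by BH before the
p < 0.05 call (a raw-p mode is available); support is the fraction of
supporting replicates, and ≥ 0.95 is required.  Replicates contain
duplicated values, so the tie-aware approximation applies there by
construction.

The effect-size gate |Δ median M| > 0.9 is strict and uses group medians
of M.  The 0.9 default is the midpoint of the recommended 0.4–1.4 cutoff
range for M-value differences and is configurable.

LASSO state selection standardizes the state-median matrix, walks a
100-value λ path log-spaced from λ_max (the smallest λ with all
coefficients zero, computed from the score at the null model) down by a
factor 1e-4, scores each λ by stratified 10-fold cross-validated binomial
deviance, and picks the largest λ within one standard error of the CV
minimum.  States with any nonzero coefficient at λ_1se are selected; a
strictly-positive-coefficient mode is available but not the default,
since direction is assigned afterwards by the per-probe ΔM sign and a
positive-only rule would make hyper-B states unreachable from this
route.  Folds are reduced with a warning when a group is smaller than the
fold count.

The final DMP set intersects the three routes per direction; the state
route applies the ΔM gate per probe (not per state median), matching the
per-probe nature of the final intersection.  Swapping the group labels
exactly swaps the hyper-A and hyper-B sets.

## DMRs

Within one (comparison, direction, chromosome), DMPs sorted by position
chain while consecutive DMPs are ≤ 1,000 bp apart (boundary included);
maximal chains of ≥ 5 become DMRs.  Intervening non-DMP array probes do
not break a chain — only inter-DMP distance is constrained.  Mixed
directions never merge.  Gene annotation uses flanks of
round(0.2 × region length) on each side, clipped at position 1; a gene is
recurrent when it occurs in more than one DMR, within or between
comparison lists.

## Enrichment and summaries

Enrichment builds, per category, the 2×2 table (DMP vs non-DMP) × (in vs
out of category) over the valid-probe universe and applies the two-sided
Fisher's exact test (sum of tables with point probability ≤ observed).
The significance threshold is α / (n functional categories + n
chromosome sets + n HMM states); with the study-scale defaults
(18 + 24 + 20) this is 0.05/62 = 0.00080645161.  On synthetic cohorts the
chromosome count is the number of chromosomes present.  The reported
effect is log2(%DMPs in category / %non-DMPs in category); with zero
DMPs in a category the ratio is undefined and reported as missing while
the significance flag is retained.

Imprinting summaries give per group × {ICR_P, ICR_M, X_CHROM} the median
β, quantiles and a kernel density (Gaussian KDE, Silverman bandwidth by
default, renormalized to integrate to 1 on [0, 1]).  The qualitative
bands — erased < 0.25, somatic 0.25–0.75, uniparental > 0.75 — are an
artifact-defined reading aid for tests and tables, not a published
convention, and can mislabel strongly bimodal sets (a bimodal male X has
a low *median* and reads as "erased").

PCA summaries mean-center M values and report PC1–2 scores; separation is
quantified as the silhouette of group labels in PC1–2 space, recomputed
over stratified bootstrap resamples of samples.  Silhouette-in-PC-space
is this package's choice of validation metric; with a single group it is
undefined and reported as missing.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not raw array physics (no IDAT intensities, probe-type bias or batch
effects):

* **Coordinates.** Per-chromosome inter-probe gaps are log-normal
  (median 3 kb, σ_log = 0.8), matching the dispersed-with-clusters
  spacing of array designs; probes sort within chromosomes by position.
* **Domains.** A Markov chain assigns each probe a low, high or mid
  *archetype* in contiguous runs (45% high, 12% mid, mean run ≈ 10
  probes), shared across groups — methylation comes in domains, which
  gives the HMM structure to find.  Mid domains are partially methylated
  (mode 0.45) in every group, emulating partially methylated domains.
* **Group profiles.** β is drawn per probe × sample from a Beta
  distribution parameterized by (mode, concentration = 60): bimodal
  groups use modes 0.1/0.9 by archetype; intermediate groups 0.1/0.55;
  hypomethylated groups sit at mode 0.1 except for residual methylation
  — a shared 15% of high domains stay at 0.9 — plus a thin
  per-observation upper tail (2% of draws from a wide mode-0.5 Beta).
  Beta noise keeps values natively in [0, 1].
* **Imprinting and X.** ICR probes are overridden per group state
  (somatic 0.5, erased 0.05, uniparental 0.95); X probes in female
  groups sit at mode 0.5.
* **Planted truth.** Each planted DMR block occupies 8 consecutive
  high-archetype probes at 400 bp spacing, flanked by forced low-archetype
  probes; the affected group's M values are shifted up by ΔM = 3 through
  the logit transform.  Placing blocks on the methylated compartment and
  flanking them with unmethylated probes makes them distinct segments
  and members of a group-separating state, so recovery exercises all
  three routes rather than the probe route alone.
* **Default cohort.** Four groups × 12 samples (EC-like bimodal, SE-like
  intermediate, TE-like bimodal and female, SS-like hypomethylated with
  erased ICR_P / uniparental ICR_M), 20,000 probes on chromosomes 1–3
  and X, three planted blocks in the EC-like vs SE-like comparison, a
  0.4% probe-level detection-failure rate, and 60-probe cross-hybridizing
  and SNP exclusion lists (plus decoy SNP records below the thresholds).
  These sizes keep a full five-seed pipeline run in the minutes range on
  one CPU while preserving the study's structure — tens of samples per
  group and a genome-scale probe count are reproducible by configuration
  only.  The cohort's six major pattern classes (shared low, high,
  partially methylated, residual-methylation, and the two female-X
  classes) match the default k = 6, so the HMM spends every state on
  genuine structure; with spare states, EM can dedicate a state to a
  handful of anomalous probes, and the LASSO would then drop that tiny
  state as redundant with the large discriminating ones — a correlated-
  predictor effect worth keeping in mind when choosing k on real data.
* An optional `group_specific_frac` plants subtype-private methylated
  domains (used by the PCA separation test); the default cohort leaves it
  at 0 so that the compared pair differs only by global profile and the
  planted blocks.

The null generator gives every group the same distribution (male,
bimodal, somatic ICRs, nothing planted), so any downstream DMP is a false
positive.

**What passing tests show — and do not.**  Planted-truth recovery shows
the pipeline wiring is correct under the generator's assumptions:
domain-structured, Beta-noised, exchangeable samples within groups.  Real
cohorts add probe-type bias, batch effects, tumour purity variation and
correlated noise that the generator does not emulate; recovery rates here
do not predict sensitivity on real data, and the null-cohort false-positive
rate does not bound the real-data false-positive rate.

## Numerical choices and degenerate inputs

* EM convergence: relative log-likelihood change < 1e-6, cap 500
  iterations; the monitor records the full likelihood curve, which is
  non-decreasing to 1e-8 (the variance floor can in principle break
  monotonicity, but only when it binds).
* k-means per restart uses a single initialization so that restarts
  explore genuinely different starts; best-of-restarts is decided by the
  EM likelihood, not k-means inertia.
* λ_max degenerates to 1e-3 when the score vector is exactly zero;
  liblinear with tol 1e-7 keeps the path deterministic.
* Features with zero variance in the LASSO design are left unscaled
  (σ := 1) rather than dropped, so state indices remain stable.
* An empty candidate set (e.g. everything filtered on a null cohort)
  flows through: no DMPs, no DMRs, enrichment skipped with a notice.
* MWU with all-tied pooled values returns p = 1; the exact-MWU dynamic
  programming table is cached per (n_A, n_B).

## Known limitations

* The HMM does not model inter-probe distance; a 1 Mb gap and a 100 bp
  gap carry the same transition prior.  Segments can therefore span
  assay deserts.
* Diagonal emission covariance ignores sample–sample correlation within
  a state (e.g. shared purity effects).
* The bootstrap re-tests candidates only (those BH-significant on the
  full data) — the protocol's stage order — which makes support
  fractions conditional on the first-pass selection.
* Enrichment treats probes as independent; adjacent correlated probes
  inflate category counts jointly.
* CLI stage commands rerun upstream stages for simplicity; `run-all` (or
  the library, passing a shared fitted model) is the efficient path.
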