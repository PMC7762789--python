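# Methods

`exorelease` analyses time-resolved untargeted LC-MS feature tables from
bacterial monocultures held in stationary phase, together with the matching
RNA-seq count matrices, to decide which mass-spectral features behave like
*released exometabolites* — compounds a strain exports into spent medium
while growth is arrested — and to characterise how the resulting
exometabolite profiles differ by strain and move through time.

## The release classifier

The unit of analysis is an aligned LC-MS feature (an m/z × retention-time
signal quantified by peak area per sample) observed in samples of one
polarity/ionization mode. For each strain separately, a feature is called
**released** when all six criteria hold:

1. **Control maximum** — the global maximum peak area over the strain's
   samples and the medium-only external controls must lie in a strain
   sample. A tie between a strain sample and a control at the global
   maximum fails (conservative).
2. **Noise floor** — the *minimum* peak area across replicates at the last
   time point (45 h) must be positive and at least 3× the *maximum* peak
   area over all external-control replicates.
3. **Replicate reproducibility** — at every time point with ≥2 replicates,
   the percent CV (100·sd/mean, sample sd with the n−1 denominator) must be
   < 20%. sd = 0 maps to CV = 0, including the all-zero case: a feature
   that is reproducibly absent is reproducible. Single-replicate time
   points carry no spread information and are skipped.
4. **Minimum first** — the time-point mean must attain its minimum at the
   first, exponential-phase time point (12.5 h). The comparison is
   non-strict: a later time point tying the first still passes.
5. **Fold change** — log₂(mean₄₅ₕ/mean₁₂.₅ₕ) must exceed 1 (strictly).
   A feature absent at 12.5 h but present at 45 h has LFC = +∞ and passes;
   absent at both time points fails.
6. **Temporal correlation** — Pearson r of abundance against time must be
   ≥ 0.7. By default r is computed over replicate-level (time, abundance)
   pairs, which uses all data; a variant over time-point means is exposed
   via `pearson_on="means"`. Zero abundance variance leaves r undefined
   and fails.

All six criteria are evaluated for every feature (no short-circuiting), so
the per-criterion verdicts serve as diagnostics. The control pool for
criteria 1–2 is every external-control sample of the table, across the
whole time course: the criteria reference "the external control sample"
without a time anchor, and pooling is the conservative reading. Thresholds
(3×, 20%, 1, 0.7) are `ReleaseThresholds` fields and can be overridden,
but the defaults are the analysis's definition of "released".

A logical coupling worth knowing: criterion 1 failing implies criterion 2
failing, because a control-held global maximum bounds min(45 h) from above
by the control maximum, which is strictly less than 3× itself (unless
everything is zero, which also fails). The synthetic decoy class D1
therefore fails criteria 1 *and* 2 while passing 3–6; no feature can fail
criterion 1 alone.

Replicate-level QC (`replicate_qc`) computes, per sample, the Pearson
correlation between its feature vector and the mean vector of its
co-replicates in the same (class, time, mode) group, flagging samples with
r ≤ 0.14. The pairing ("each sample vs. the mean of the others") is this
package's definition — the threshold is standard, the pairing is not
specified by convention elsewhere. Singleton groups are skipped with a
warning. Note that profile-free samples (e.g. medium-only controls, whose
features vary only by noise) naturally sit near r = 0 under this
statistic; apply it to the sample classes whose reproducibility is in
question.

## Normalization

Every sample is spiked with internal standards (ITSDs). The reference is
the ITSD with the lowest percent CV across all retained samples (ties
break lexicographically by feature id; candidates with a zero in any
sample are excluded). Each feature's peak area is divided by the
reference's area in the same sample — removing per-sample multiplicative
scale such as injection-volume differences — and cube-root transformed.
Z-scoring rows (n−1 sd; constant rows map to zeros, keeping planted
constant features finite) is a separate step used for Euclidean-distance
heat-map input; Ward clustering and rendering are left to dedicated
heat-map tools.

## Longitudinal composition statistics

Dissimilarity between normalized profiles is Bray-Curtis,
BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), with the 0/0 case (two all-zero profiles)
defined as 0. PCoA is classical metric scaling: Gower double-centering of
−D²/2 followed by an eigendecomposition; coordinates are eigenvectors
scaled by √eigenvalue on the positive axes, and negative eigenvalues are
reported unchanged (no Lingoes/Cailliez correction) so metric distortion
stays visible. When D is of Euclidean origin the coordinates reproduce it
to numerical tolerance.

PERMANOVA follows the McArdle–Anderson trace identity: for the
double-centered Gower matrix G and the hat matrix H of a design matrix X,
the sum of squares captured by X is tr(HG). Terms are added sequentially
(Type I) in the order strain, time, strain × time; the order is fixed and
documented because sequential SS depends on it (it matters only for
unbalanced designs). Projectors are computed by SVD so rank-deficient
interaction blocks get their correct degrees of freedom. Permutation
p-values use the add-one estimator (#{F* ≥ F} + 1)/(n_perm + 1) over
whole-sample relabelings, seeded; n_perm defaults to 999, and the
permutation set can be supplied explicitly for exact enumeration on small
instances. Pairwise tests run the one-way statistic per group pair with
Benjamini–Hochberg adjustment over the family of pairs. The
repeated-measures variant restricts permutations to shuffling time labels
within each independently replicated time series; each series must contain
every time point exactly once. This within-series shuffle is one
defensible restricted-permutation scheme for longitudinal profiles, chosen
here; other schemes (e.g. cyclic shifts) exist.

Protest measures concordance of two ordinations (the first two PCoA axes
of matched time points) by the Procrustes residual m₁₂² after optimal
translation, rotation and scaling of the standardized configurations;
correlation = √(1 − m₁₂²); the permutation null shuffles the rows of one
configuration.

Centroid dissimilarities are computed in normalized-profile space: the
centroid is the arithmetic mean profile per group (time point), and
Bray-Curtis is taken between centroids — either each stationary time point
against the 12.5 h baseline, or consecutive time points stepwise.
Computing centroids in PCoA space instead is a documented alternative the
package does not default to, since the profile-space version needs no
ordination choices. Per-feature strain effects use one-way ANOVA at the
final time point with BH adjustment across features.

## Transcript-side screening

Gene counts are filtered in two ordered steps: genes with zero counts in
all samples are removed, then genes with counts ≤10 in strictly more than
90% of samples. The low-expression minimum (LEM) is the 25th percentile
(linear-interpolation quantile) of per-gene mean counts; a gene is
expressed iff its mean count is strictly above the LEM. The underlying
cumulative-abundance-curve construction admits several readings (quantile
over genes, over reads, or over the curve); this package fixes the
per-gene-mean reading precisely and tests it, rather than claiming to
reproduce any particular dataset's threshold. Transporter genes (ids from
an external annotation, e.g. TransportDB) are then counted in nested
classes: above the LEM; additionally differentially expressed (Q < 0.01 in
an externally produced DE table — the negative-binomial DE model is an
input, not recomputed); additionally carrying log₂ fold change > 1 at some
stationary-phase time point. The nesting invariants
(total ≥ above ≥ DE ≥ DE∧LFC; above + below = total) are asserted on
construction.

## The synthetic-data generator

`generate_feature_table` emulates the study design: 3 strains × 6 time
points (12.5, 25, 30, 35, 40, 45 h) × 4 replicates in one mode, plus
medium-only controls at every time point and extraction blanks, with
internal standards spiked into every sample. Defaults: 50 planted released
features and 10 decoys per class per strain, 5% replicate CV, control
(spent-medium background) level 1000, ITSD CV 2%. Noise is multiplicative
lognormal parameterized by its CV — peak areas are nonnegative and
heteroscedastic, and a CV-parameterized multiplicative model preserves the
CV target across magnitudes. Released features follow
μ(t) = a·2^(k·(t−t₀)/(t_last−t₀)) with a log-uniform over [5·10⁴, 5·10⁵]
and k uniform over [1.5, 3]: the minimum sits at t₀, LFC = k > 1, and the
time correlation of the trajectory exceeds 0.9 on the default grid.

Decoy constructions (zero-noise exact; robust at the default 5% CV):

- **D1** plants 1.5× the feature's strain maximum into one control
  replicate (fails criterion 1, and — entailed — criterion 2).
- **D2** gives the feature its own control baseline c₀ and scales the
  trajectory so the 45 h mean is 2·c₀: above the control (passes 1) but
  under the 3× floor (fails 2).
- **D3** replaces one interior time point's replicates with a fixed
  zero-mean spread pattern at exactly 40% CV (fails 3; the mean is
  preserved so 4–6 hold). Configurations with replicate_cv ≥ 0.2 are
  rejected as infeasible — background noise would blur into the planted
  spread.
- **D4** moves the trajectory minimum to the third time point (30 h on the
  default grid) with a dip to 0.5a inside an otherwise rising LFC-3
  trajectory (fails 4; the time correlation stays above 0.7).
- **D5** uses k = 0.5, i.e. LFC = 0.5 (fails 5 only).
- **D6** rises 10-fold by 25 h and decays to 2.5a at 45 h: minimum first,
  LFC ≈ 1.32, but time correlation near 0 (fails 6).

Optional whole-sample dropout emulates failed injections while always
keeping ≥2 replicates per (strain, time point). What the generator does
*not* emulate: chemically meaningful m/z values, retention-time drift,
chromatographic peak shapes, correlated (batch) noise, or missingness that
depends on abundance. Passing tests on these data therefore demonstrate
the correctness of the filter arithmetic and the statistics under the
stated noise model, not robustness to instrument artifacts.

`generate_count_table` plants per-gene means with a low-expression group
(log-uniform [0.5, 3]) sized to exactly the LEM quantile fraction (25% by
default) against a high group (log-uniform [50, 5000]), so the
interpolated quantile lands in the gap between the groups and zero-noise
recovery of planted classes is exact. Counts are negative-binomial with
dispersion tied to the replicate CV (exact rounded means at CV 0). Planted
DE transporters carry Q < 0.01 and a final-time-point LFC in [1.5, 3] in
the fabricated DE table; stable transporters get Q ≥ 0.02.

## Numerical and design choices

- CV and Z-score standard deviations use the n−1 denominator throughout.
- Criterion 5 and the DE LFC rule are strict inequalities; criterion 6 is
  ≥; "above the LEM" is strict.
- Percentages that mirror printed summaries are rounded half-up to one
  decimal. The "shared by ≥2 strains" percentage uses the sum of
  strain-unique counts as its denominator (the computation that reproduces
  the reference arithmetic); the per-strain unique percentages use the
  grand total of distinct features. Both computations are stated rather
  than inferred.
- Default problem sizes (3 strains × 6 × 4 design, ≤ a few hundred
  features, 1,000 genes, 999 permutations) keep every pipeline stage
  comfortably under a minute on one CPU; they are the package's chosen
  test scale for a design of this shape.
- Empty peak-area cells read as 0 (non-detection); there is no blank
  subtraction, drift correction, or imputation anywhere in the pipeline.

## Known limitations

- The release filter's verdicts on real data depend on upstream peak
  picking and alignment, which this package does not perform.
- The repeated-measures permutation scheme and the centroid space are
  documented choices among defensible alternatives (see above).
- The LEM definition here will not numerically reproduce thresholds
  derived from a different reading of the cumulative-abundance rule.
- Sequential SS makes multi-factor PERMANOVA results order-dependent on
  unbalanced designs; reorder terms or balance the design accordingly.
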