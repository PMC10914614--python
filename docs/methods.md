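# Methods

## Sedimentation profiles

A gradient run is summarized as a protein × 21 matrix: fractions F01–F20
collected top-to-bottom plus the resuspended pellet P. Profile
construction follows the standard Grad-seq convention:

* **Spike-in correction.** Every fraction receives the same molar amount
  of a foreign standard protein, so the standard's measured intensity
  tracks purely technical per-fraction scale (injection, digestion,
  column performance). Column *j* of the matrix is multiplied by
  `s_ref / s_j` where `s_j` is the spike-in intensity in column *j* and
  `s_ref` is the median of the 21 spike-in values. Using the median
  rather than 1 keeps corrected intensities on the original scale. The
  correction is idempotent and removes any column-wise distortion shared
  with the spike-in, up to one global constant. A zero spike-in value is
  a hard error, not something to interpolate over.
* **Per-protein normalization.** Fractions 1–20 are divided by their own
  maximum, so the profile encodes *shape* (peak = 1) regardless of
  abundance. The pellet is not part of that shape: it is reported as
  `P / (ΣF + P)`, the protein's share of total signal that pelleted. The
  alternative convention `P / ΣF` is available as
  `pellet_denominator="gradient_only"`; the two are monotonically
  related, and the share-of-total form is the default because it is
  bounded in [0, 1]. Peak ties break to the lowest fraction index.
* **Missing values.** Empty or `NA` intensity cells are read as 0: in
  iBAQ-style output, absence means "not detected", and a non-detection
  genuinely carries no gradient signal. The imputation count is logged so
  a file full of holes is visible.
* **Abundance filter.** Proteins are kept when log₁₀ of their summed
  spike-corrected intensity across all 21 compartments strictly exceeds
  8.0. "Summed" (rather than max) is the default reading of a relative
  iBAQ threshold; the threshold and the statistic are both parameters.

## Clustering and machinery assignment

Profile similarity is Pearson correlation over the 20 fraction values.
The pellet is excluded from correlation because it lives on a different
scale (share-of-total vs max-normalized); mixing the two would distort r.
Correlation distance `1 − r` ∈ [0, 2] feeds average- or complete-linkage
agglomeration (scipy); for small inputs the merge sequence is verified in
the tests against an exhaustive agglomerator that recomputes every
cluster-pair linkage at each step, with ties broken to the lexicographic
lowest pair.

Machinery membership is *not* read off the dendrogram or the t-SNE
embedding. Each reference machinery (30S, 50S, RNAP, "other" for
70S/polysomes) gets a centroid — the arithmetic mean of the normalized
profiles of its annotated members, at least 3 of which must pass the
abundance filter — and a protein is assigned to the centroid with the
highest correlation provided it reaches `r_min`, else it is unassigned.
`r_min = 0.8` is a declared default, swept in the tests; there is no
canonical published value. The t-SNE embedding (seeded, perplexity a
parameter, default 30, requiring n ≥ 3·perplexity) is diagnostic only.

## Candidate calling

A phage protein is called a ribosome-association candidate iff:

* its profile peaks at fraction ≥ 4 (`hmw_min_fraction`); fractions 1–3
  hold monomers and sub-100 kDa species,
* it is assigned to a 30S or 50S centroid (this adapts to gradient
  geometry, unlike a fixed fraction window), and
* its pellet share is ≤ 0.2 (`pellet_max`); "absent from the pellet" has
  no published numeric threshold, so 0.2 is a declared parameter with a
  monotonicity guarantee: shrinking `pellet_max` or raising `r_min` can
  only shrink the candidate set.

The 30S-vs-50S class is the higher centroid correlation; a tie within
1e-9 raises an error for manual review rather than silently picking one.

## Infection time course

The phage share of coding reads at each time point is raw phage counts
over raw total counts — invariant to library size per time point.
Phage transcripts are ranked by raw counts summed over the 0–10 min
window (no length normalization by default; the statistic is a config
choice) and the "top set" is the minimal prefix whose cumulative share
*strictly exceeds* the cutoff (default 0.85). Candidates are then ordered
by (top-set membership, transcript rank, co-sedimentation score);
candidates with no mapped transcript sort last, flagged.

## Absolute quantitation

`ribosomes_per_cell` is Beer–Lambert: A260 / (ε·path) gives molarity
(ε = 3.84 × 10⁷ M⁻¹ cm⁻¹ for 70S, path 1 cm), times volume and Avogadro's
number (SI-exact 6.02214076 × 10²³), divided by cells lysed.
`cells_loaded` is CFU/mL × culture mL × lane fraction.
`copies_per_cell` divides a blot signal by the slope of a standard curve
fit by least squares *through the origin* — zero protein must give zero
signal; an intercept would model blot background, which belongs upstream.
Residuals are kept so a nonlinear dilution series can be rejected. All
three operations are homogeneous of degree 1 in their signal inputs.

## Synthetic data generator

The generator emulates exactly the structure the analysis exploits, with
ground truth attached to every row.

**Gradient.** Complex class *c* sediments as a Gaussian bump `g(j; μ_c,
σ_c)` evaluated at fraction indices j = 1..20 and renormalized to sum 1;
protein rows are `A_p · [w_free·g_free + w_c·g_c]` with abundance `A_p`
log-uniform in 10^[8.3, 10.5] (the detected regime above the abundance
filter) and a free-pool weight of 0.1 for complexed proteins. The pellet
is a separate compartment, `A_p · w_c · pellet_mass_c`, not fraction 21
of the bump. Measurement applies (i) lognormal noise with mean 1 and
CV 0.2, (ii) dropout of values below 0.1% of the median positive signal,
and (iii) per-fraction scale factors `d_j ~ lognormal(0, 0.3)` shared
with a constant spike-in row — precisely the distortion spike-in
correction removes. The dropout mask is computed *before* the `d_j` are
applied, i.e. detection is a property of the analyte amount, not of the
per-fraction technical scale; this keeps the spike-in identity exact
(dividing the distorted matrix by the spike-in row reproduces the
undistorted matrix to machine precision), which the tests exploit.
Class widths must exceed 0.3 fractions — narrower bumps are
unidentifiable at integer fraction resolution.

Default census (~440 proteins plus spike-in): host free (μ=2, n=310),
RNAP (μ=5, n=8), 30S (μ=11, n=21), 50S (μ=14, n=33), 70S/polysome
(μ=17, n=30, annotated "other"); phage free (n=21), polymerase-like
(μ=5, n=5), planted 30S binders (μ=11, n=3), planted 50S binders
(μ=14, n=5), virion-like (μ=18, pellet_mass 0.8, n=6). Host machinery
classes are exposed in the annotation table; the planted phage binders
are not — they are what the pipeline must discover.

**Time course.** Samples at 0, 2, …, 10 min. Phage transcript classes
turn on logistically, `logistic((t − τ)/s)` anchored to zero at t = 0
(the t0 sample precedes infection), with onsets τ_early = 3,
τ_early-other = 3.5, τ_mid = 6.5, τ_late = 9 min (validated strictly
increasing) and scale 1.5 min. Host transcripts are flat until 4 min and
then decay at 5%/min. Per-transcript rates are lognormal (σ = 0.6). The
global phage amplitude is solved, per realization, so the *expected*
phage share of reads at 10 min equals the configured 40% target; counts
are then Poisson at an expected library of 2 × 10⁵ reads per time point —
deliberately below real sequencing depth to keep the suite fast, while
leaving share noise far smaller than the ±5-point calibration band used
in the tests. The 8 early-ribosome transcripts reuse the planted-binder
protein ids, so the joint simulation links protein and transcript by
identity.

All randomness derives from one seed via per-row substreams
(`default_rng([seed, stream, i])`), making output independent of row
order and byte-reproducible.

**What passing tests do not show.** Real Grad-seq profiles are often
multi-modal (free plus complexed pools beyond the single free bump
modelled here), fraction noise is correlated across neighbouring
fractions, iBAQ dropout is abundance-*and*-peptide dependent, and real
annotations contain errors. Recovery rates on the generator therefore
demonstrate correctness of the inference chain under its own model, not
expected performance on deposited datasets.

## Numerical choices

* Pearson r is clipped to [−1, 1] after computation; zero-variance
  vectors raise rather than returning NaN.
* Agglomeration and candidate ordering are fully deterministic (ties by
  lexicographic id); t-SNE is deterministic given its seed.
* Profile tables are written with `repr` floats so read∘write is the
  identity to 1e-12.
* The pipeline report omits wall-clock timing (logged instead), so a
  rerun with the same config and seed is identical apart from its
  timestamp field.

## Known limitations

* Reference centroids require ≥ 3 annotated members per machinery; very
  sparse annotation sets cannot be used.
* The candidate rule presumes the gradient resolves 30S from 50S; on
  gradients where the subunits co-sediment, the subunit class degenerates
  (and ties are refused, by design).
* Transcript ranking uses raw counts; comparing transcripts of very
  different lengths benefits from the length-normalized option.
* No significance testing of co-sedimentation is attempted — assignment
  scores are correlations, not p-values.
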