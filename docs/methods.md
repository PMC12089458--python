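# Methods

## Cone-section motility classification

A displacement vector **s** is compared with the per-recording anterograde
axis **u** (unit vector pointing away from the neurosphere/soma) through its
cosine c = (**s**·**u**)/|**s**|. With the default cos(half-angle) of 1/3 the
classification is anterograde for c ≥ 1/3, retrograde for c ≤ −1/3 and
orthogonal otherwise; the boundary is inclusive to the motile classes (a
documented tie-break — in continuous data exact equality has measure zero).
The cone's internal angle is 2·acos(1/3) ≈ 141°, and in 3D the two polar
caps and the equatorial band each cover exactly one third of the sphere
((1 − 1/3)/2 per cap). The same rule is applied unchanged in 2D, where the
sectors are *not* equal-measure (the anterograde/retrograde wedges span
2·acos(1/3) ≈ 141° of the circle each); this mirrors how planar
epifluorescence data are analysed and is deliberate, not an approximation
error.

A branch — one maximal linear run of a track graph, see below — is
classified stationary when its maximal per-step speed (step length divided
by the true inter-spot time difference, no smoothing) stays below
0.05 µm/s, or when its summed step length stays below 2 µm over the
time-lapse. Otherwise the *net* start→end displacement is classified with
the cone rule; a per-step majority-vote alternative is available behind
`MotilityParams(per_step_vote=True)` for sensitivity analysis, because the
aggregation level of the original description ("overall" movement) admits
both readings and net displacement is the simplest consistent one. A
non-stationary branch with exactly zero net displacement is a degenerate
case labelled stationary. Branches moving orthogonally overall are excluded
from motility proportions; proportions are therefore over
stationary + anterograde + retrograde and are embedded in the 2-simplex as
(x, y) = (p_a + p_r/2, p_r·√3/2) for ternary plots.

The anterograde axis cannot be derived from the data alone: a helper
(`estimate_axis`) returns the first principal axis of first-frame positions,
but its sign (which end is the soma) must be supplied by the user from the
recording geometry.

Line × class association is Pearson's χ² without continuity correction,
expected counts from the margins, p from the upper χ² tail with
(r−1)(c−1) degrees of freedom. Pearson residuals (O−E)/√E carry the
attraction/repulsion sign; their squares divided by χ² are per-cell
contributions and sum to one.

## Branch splitting

Track graphs are split into maximal linear segments terminated at merge or
split spots. Membership is disjoint: a split spot (out-degree > 1) belongs
to the parent branch only, a merge spot (in-degree > 1) to the downstream
branch only. Branches shorter than `min_spots` (default 5 — the analysis
needs at least a few steps to estimate a maximal speed; configurable and
reported) are discarded and counted. Gap-closed links are kept as single
long steps with their true time difference, preserving speed semantics.
Cyclic graphs are rejected. Coordinates are physical µm throughout; a
TrackMate file declaring pixel units requires its calibration
(`Settings/ImageData@pixelwidth`) and a missing unit declaration is an
error rather than a silent pixel assumption.

## Axial spacing

In the first frame of each recording, every mitochondrion's candidate
neighbours on the anterograde (resp. retrograde) side are those whose
relative position vector falls in the same cone; the nearest candidate by
Euclidean distance is taken, with ties broken by smallest id. The
across-distance (sum of both sides) and |antero − retro| are computed only
when both neighbours exist. By default only branches already present in
frame 0 contribute (their frame-0 spot); `first_frame_only=False` uses each
branch's first appearance instead. Group tests run on recording-level
means — the recording, not the mitochondrion, is the experimental unit — as
one-way ANOVA followed by pairwise two-sided Wilcoxon rank-sum tests of
each line against the reference, exact (no normal approximation) at the
small recording counts typical here, unadjusted p with stars at
0.05/0.01/0.001.

## Cell typing

QC excludes cells with < 100,000 uniquely mapped reads **or** < 5,000
detected genes (RPKM > 1 counts as detected); boundary equality passes,
since the published rules are strict "<". The decision tree (order:
neuron → motor neuron → V2a interneuron → other interneuron) uses strict
comparisons exactly as printed, so boundary equality fails a condition.
Non-neuronal cells are not subdivided into progenitor/proliferating
sub-types: no thresholds are defined for those markers (SOX2, MKI67, CDK1),
which are simulated and reported descriptively only. Gene ids are HGNC
symbols; a small alias map (VACHT→SLC18A3, CHT→SLC5A7, CHX10→VSX2,
HB9→MNX1) can be applied before lookup. A neuron with NaN in a needed
marker raises rather than silently non-calling.

## Set comparison

Per-line sets contain ids with adjusted p < 0.05, directed by the sign of
the fold change or enrichment score. The Venn partition enumerates all
2^k − 1 disjoint regions for 2–4 sets and can be split by direction. The
GOF/LOF partition takes shared = mut₁ ∩ mut₂ ∩ mut₃, LOF = shared ∩ KO and
GOF = shared \ KO. Pairwise overlap tests build the 2×2 membership table
over a universe — by default the union of all dysregulated items in the
run, configurable to the full tested universe — and report the odds ratio
(Haldane–Anscombe +0.5 on all cells only when a zero cell occurs; the
uncorrected value is also kept), its log₂, the two-sided Fisher exact
p-value, BH-adjusted p across all pairs of one invocation, and a flag for
odds ratios above five-fold. Up-vs-up and down-vs-down comparisons are
intended to be run as separate invocations.

## Case-report aggregation

Disease duration runs from onset to the endpoint — respiratory failure,
tracheostomy, or else death. Summaries are per-mutation n, mean and sample
sd (n−1); missing values are dropped per variable, censored
(alive-without-endpoint) cases are excluded from the duration summary and
counted separately, and sd is undefined at n = 1. Candidate duplicate rows
(same mutation/onset/sex/country) are flagged, never auto-merged: merging
needs the source publications.

## Synthetic data

The generators emulate upstream tool *output* (detected spots, RPKM
matrices, significance-filtered sets, curated case rows), not raw data, so
ground truth is exact by construction.

* **Tracks** are sampled at 0.5 Hz (2 s interval) over 180 frames (~6 min;
  the two recording lengths in circulation, 5 and 6 min, are both
  configurable and neither is hard-coded as correct). The default mixture
  is 60/20/20 stationary/anterograde/retrograde over 2000 branches. Motile
  branches drift along ±axis at a per-branch speed drawn from
  N(0.4, 0.1²) µm/s — the fast-transport range for axonal mitochondria;
  these are plausibility placeholders, not a reproduction of measured speed
  distributions — plus isotropic Gaussian positional noise (sd 0.02 µm).
  Stationary branches jitter i.i.d. around a fixed point with sd 0.01 µm:
  the frame-to-frame step is then Rayleigh with σ ≈ 0.014 µm, so the
  probability of any of 179 steps exceeding the 0.1 µm (= 0.05 µm/s × 2 s)
  speed cut is ~2·10⁻⁹ and the simulated labels are unambiguous ground
  truth. (At a jitter sd of 0.02 µm roughly a quarter of stationary
  branches would cross the speed cut at least once, which is why the
  smaller default was chosen.) Tracks are linear chains — no fusion/fission
  — unless a split probability is set, and direction reversals are off by
  default so that ground truth stays unambiguous; both exist for stress
  tests. Positions are 2D by default, matching epifluorescence imaging.
  What this does **not** emulate: curved axons, detection dropouts/gap
  closing, speed-state switching, fusion/fission dynamics — so passing
  recovery tests show the classifier implements its rules correctly, not
  that real recordings are this clean.
* **Expression** draws lognormal marker RPKM per class (five classes:
  motor neuron, V2a interneuron, other interneuron, progenitor,
  proliferating — the last two both map to the non-neuronal label), with
  class means placed at least tenfold beyond each threshold the class must
  clear or stay under, log-sd 0.3, optional per-(class, marker) dropout
  (default 0), 200 background genes, and QC fields drawn uniformly from
  per-class ranges. Real data have correlated depth/complexity, doublets
  and ambient contamination; none are simulated.
* **Gene sets** realize exact Venn-region cardinalities by consuming a
  seeded permutation of the universe, with directions drawn per (member,
  set).
* **Cases** draw Gaussian onset (years) and duration (months) per mutation,
  clipped at zero (the clipping bias is ≪ 0.1 at the configured
  parameters), with optional missingness. The default configuration is a
  synthetic stand-in for the aggregated ALS-FUS case-report table: group
  parameters are the published statistics (P525L 21 ± 8 y onset, 17 ± 10 mo
  duration; R495X 31 ± 11 y, 20 ± 18 mo; other mutations 41 ± 18 y, with
  60 ± 40 mo chosen as a realistic slower progression) and group sizes
  (120/60/322) sum to the 502 aggregated cases; the split across mutations
  is itself a modelling choice, as only the total is published.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeds carried in
the config objects. The Monte-Carlo trisection check uses 10⁵ isotropic
vectors (SE ≈ 0.15 percentage points); mixture recovery uses the default
2000 branches; χ²-vs-brute-force agreement is checked on 100 random tables
at 10⁻¹⁰; Fisher p-values are validated against exhaustive hypergeometric
enumeration for total counts ≤ 30, and the Wilcoxon test against full
rank-assignment enumeration for group sizes ≤ 6. These sizes keep the whole
suite in the tens of seconds while leaving the statistical tolerances far
tighter than the effects they guard.

## Known limitations

* The 2D cone sectors are not equal-measure; isotropy-based expectations
  (each class ⅓) hold only in 3D.
* `estimate_axis` fails on branching or strongly curved axon fields; the
  axis should then come from recording metadata.
* Fisher's two-sided p uses the standard minimum-likelihood summation; other
  two-sided conventions (doubling) differ for asymmetric margins.
* Case summaries are descriptive; no survival modelling is attempted, and
  censored durations are simply excluded.
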