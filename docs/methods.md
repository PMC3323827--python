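# Methods

## Problem and scope

Comprehensive two-dimensional gas chromatography time-of-flight mass
spectrometry (GC×GC/TOF-MS) reports each analyte as a peak with two
retention times — RT1 on the first column (minutes) and RT2 on the
modulated second column (seconds) — plus a mass spectrum and an area.
Retention times drift within a batch and shift systematically between
acquisition configurations (e.g., different temperature gradients), and a
single metabolite can be reported as several peak entries within one run.
`gcalign` starts from detected peak tables (ChromaTOF-style exports), not
raw signal, and performs: within-run merging, cross-run peak matching with
an empirical Bayes posterior confidence, landmark selection, and
lattice-wise retention-time adjustment.

## Peak merging

Entries sharing a compound identification (CAS preferred, else lowercased
name) are collapsed to the maximum-area entry. Area ties break by earlier
RT1, then earlier RT2, then input order, so output is deterministic. Peaks
without an identification pass through unmerged: without an identity there
is no grouping rule, and merging them by RT/spectrum proximity is a
different method that we deliberately do not implement.

## Mixture dissimilarity score

For peaks A (reference run) and B (target run),

    S(A, B) = w · D/(1 + D) + (1 − w) · C′ ,

where D is the Euclidean distance between the peaks' within-run
(rank-by-RT1, rank-by-RT2) vectors (average ranks on ties) and C is the
angle in degrees between the two spectra, vectorized on the union of
integer-rounded m/z channels with zero fill. Smaller S means more similar.
Ranks make the score invariant to any monotone RT warp, which is what lets
one score serve homogeneous and heterogeneous data without an RT
transformation step.

Two scales for the spectral term are provided. The `normalized` scale uses
C′ = C/90, bounding S in [0, 1). The default `angle` scale uses C′ = C
(degrees): it is the scale on which the stock candidate threshold h = 40
and typical observed scores (≈ 9.7) are self-consistent. Thresholds are
always interpreted on the active scale. An optional square-root intensity
transform and rank normalization for unequal run sizes are available but
off by default.

The weight default w = 0.1 keeps the spectral term dominant; rank distance
acts as a tie-breaker among spectrally similar candidates. A peak's
candidate set is every target peak with S below h.

## Empirical Bayes matching model

For each reference peak j, four layers compose the probability of what is
observed (whether j claims any candidate, Z_j, and the candidate scores
S_j):

1. **Presence.** The metabolite is present in the target with probability
   ρ (Y_j = 1).
2. **Claiming.** P[Z=1|Y=0] = η0 when the competition score b_j = 0, else
   the quadratic-logistic γ(β; b_j) = 1 − 1/(1+exp(β0+β1 b+β2 b²));
   P[Z=1|Y=1] = η1 when b*_j = 1, else λ(α; b*_j) of the same form. The
   competition scores are computed within the reference run: a_k counts
   peaks within h of peak k (self included), b_j sums 1/a_k over j's
   neighbors, and b*_j = b_j + 1/a_j adds j itself. The η strata are
   handled discretely, exactly as defined — no continuity between the
   constant and the logistic branch is assumed. Peaks with b* < 1 (possible
   when a peak's neighbors are better connected than itself) follow the
   logistic branch; only b* = 1 is the η1 stratum.
3. **Correctness.** A claimed match of a present metabolite is correct
   with probability τ.
4. **Scores.** Candidate scores come from a correct-match density f_T or
   an incorrect-match density f_F, both normal (f_F optionally a
   two-component normal mixture with weights π1, π2 behind a flag), with
   μ_T < μ_F enforced by relabeling — correct matches have smaller
   dissimilarity.

Only the minimal-score candidate of a reference peak can be the correct
one; all other candidates are incorrect by construction. This mirrors how
the matcher ultimately selects the smaller-score pair, and reduces the
per-peak latent space to three feasible states given Z=1:
(Y=0), (Y=1, W=0), (Y=1, W=1).

### EM estimation

The observed-data likelihood per reference peak is

    z=1:  L_j = (1−ρ)·P[Z=1|Y=0]·∏_l f_F(S_jl)
              + ρ·P[Z=1|Y=1]·[τ f_T(S_jl*) + (1−τ) f_F(S_jl*)]·∏_{l≠l*} f_F(S_jl)
    z=0:  L_j = (1−ρ)(1−P[Z=1|Y=0]) + ρ(1−P[Z=1|Y=1])

with l* the minimal-score candidate. The E-step enumerates the three
feasible joint states exactly (log-space). The M-step updates ρ, τ, η0, η1
as responsibility-weighted proportions within their strata; α and β by
weighted logistic regression of the claim indicator on (1, b*, b*²) over
the b* ≠ 1 stratum and on (1, b, b²) over b > 0, with weights equal to the
Y-responsibilities (resp. their complements); and the density parameters by
responsibility-weighted normal moments with a variance floor of 1e−6 on the
score scale.

Numerical choices:

* The weighted logistic solver is a damped Newton iteration warm-started at
  the previous coefficients; an update is kept only if it does not decrease
  the weighted Bernoulli objective, so the procedure is a generalized EM
  and the observed-data log-likelihood is non-decreasing by construction
  (the test suite asserts this to 1e−10 slack on every dataset it touches).
* Initialization is deterministic: a two-cluster split of best-candidate
  scores seeds (μ_T, μ_F) — augmented by pooling non-best candidate scores
  (incorrect by construction) into the f_F moments — plus method-of-moments
  starts ρ₀ = claim rate and τ₀ = lower-cluster share. The split is
  rejected when cluster separation does not exceed the cluster widths
  (numerically tied scores would otherwise seed μ_T ≈ μ_F).
* When fewer than 5 non-best candidate scores exist in the whole dataset
  there is no direct evidence about incorrect-match scores, and maximum
  likelihood would overfit by splitting the unimodal correct-score
  distribution. φ_F is then initialized beyond the observed scores and held
  fixed; τ and the posteriors then behave as they should in data with no
  evidence of error (posteriors → ρ̂λ̂ ≈ 1 for clean self-matches).
* Convergence: relative log-likelihood change below 1e−8 (default), at most
  500 iterations; both are exposed because the likelihood surface has flat
  ridges (next paragraph) on which tighter settings are useful.

### Identifiability of ρ and τ

The model is only *set-identified* in (ρ, τ): per competition stratum the
data provide two observables (the claim rate and the f_T share of claims)
while the free logistic layers can be solved per stratum to match both for
any (ρ, τ) with ρ·λ·τ equal to the observed correct-match mass. In
simulations from the model itself, μ_T and μ_F recover to within a couple
of percent, but the maximum-likelihood point for (ρ, τ) can sit anywhere on
a nearly flat ridge, occasionally at the τ = 1 boundary; deviations of
±0.1 from the generating values are common at n = 2000. The matching
posteriors are much less affected: they depend on the combined quantities
that *are* identified (the wide-band calibration check in the test suite
passes). Users should treat ρ̂ and τ̂ as descriptive, not as precise
estimates. The parameter-recovery study in `scripts/acceptance.py` uses a
generating design chosen for realism — a present metabolite almost always
claims a candidate (η1 = 0.95, α = (2.0, 0.5, 0.1)), an absent one rarely
does (η0 = 0.1, β = (−2.5, 0.6, 0.05)) — with a sparse reference
neighborhood graph (mean degree 2) and 1 + Poisson(1) candidates per
claiming peak, run at tol 1e−10 and at most 2000 iterations.

### Posterior

The matching confidence P_jl = P[W_jl = 1 | Z_j = 1, S_j; θ̂] is computed
by the same three-state enumeration under the fitted parameters and is
nonzero only for the best candidate. The test suite verifies it against an
independent brute-force enumeration oracle to 1e−8.

## Alignment

Matching runs between consecutive run pairs in the user-given order
(`--pairing all` computes every pair and requires chains to be mutually
consistent cliques). Retained pairs have posterior above the cutoff
(default 0.9) and are made one-to-one by keeping the higher-posterior pair
on target conflicts (ties: smaller score, then smaller reference id).

Peaks whose pairs link through every run form landmark chains; the mean RT
of a chain's members per dimension is its representative landmark. Per run
and per dimension, the landmarks' (run RT → representative RT) pairs form
the knots of a monotone piecewise-linear map applied to all peaks of the
run simultaneously; between knots (t_L, t_H) → (r_L, r_H) a peak at t moves
to r_L + Δ(r_H − r_L) with Δ = (t − t_L)/(t_H − t_L). Outside the knot span
the map extrapolates linearly from the two outermost knots, which keeps it
strictly increasing on the whole line (a nearest-offset shift would not).
At a knot the map returns the representative RT exactly, so landmark
members land exactly on the representative grid. Dimensions are adjusted
sequentially and independently; no 2-D coupled warp is attempted.

Landmarks whose RTs tie only up to measurement precision can produce tiny
monotonicity violations in the representative sequence (two metabolites
0.001 s apart can swap order between a single run and the cross-run mean).
Monotonicity is therefore restored by pool-adjacent-violators: adjacent
knots whose representative RTs invert merge into their weighted average in
both coordinates, iterated to a fixed point — the natural generalization of
the exact-duplicate collapse to finite precision. The repair is bounded: if
a merge would move a representative RT by more than 2% of the
representative span, the inversion is too large to be a measurement tie —
it signals bad matching — and a hard `CrossingLandmarksError` is raised
rather than silently repairing; `knot_resolution=0` makes every violation a
hard error.

## Evaluation

The gold standard pairs peaks of two merged runs sharing an identical
compound key; keyless peaks are excluded. Matching itself never reads
compound keys, and the evaluation pipeline additionally strips them before
matching, so there is no leakage. PPV = TP/predicted, sensitivity = TP/GS,
F1 is their harmonic mean (zero when either is empty). The sweep evaluates
F1 on a grid of w ∈ {0.1, 0.2, 0.3, 0.5} × cutoff ∈ {0.6, 0.7, 0.8, 0.9,
0.95} (20 cells; a single EM fit per w is re-thresholded across cutoffs,
which is exactly equivalent because the fit does not depend on the cutoff),
reports the best cell, and a separate aggregator averages best-F1 over run
pairs. KDE diagnostics use a Gaussian kernel (Silverman bandwidth by
default) on 512 grid points spanning the data ± 3 bandwidths.

## Synthetic data generator

The generator emulates what the method must survive in real exports, with
known ground truth. A master list draws `n_metabolites` with RT1 uniform on
10–60 min, RT2 uniform on 1–5 s, unique synthetic CAS-like keys, and sparse
spectra (18 of 120 unit-mass channels, log-normal intensities), re-drawn
until every pairwise angle exceeds 25° so that no two master metabolites
are spectrally confusable. Per run:

* **Warps.** rt′ = a·rt + c + N(0, jitter²) per dimension. The homogeneous
  preset uses a = 1, c = 0 with jitter 0.02 min / 0.01 s; the heterogeneous
  preset spreads a over 0.85–1.15 and c over ±2 min (RT1), a over
  0.92–1.08 and c over ±0.15 s (RT2) across runs, emulating distinct
  temperature gradients. Affine warps are chosen because the piecewise
  linear landmark map should invert them near-exactly; arbitrary smooth
  monotone warps can be emulated by raising jitter.
* **Spectral noise.** Multiplicative log-normal (σ = 0.1) per channel,
  renormalized to constant total intensity so angles stay well defined and
  scale invariance remains meaningful.
* **Splitting** (rate 0.1): a duplicate entry with the same (re-noised)
  spectrum, slightly shifted RT2 and strictly smaller area, so the merge
  rule's correctness is mechanically checkable.
* **Dropout** (rate 0.05) and **label errors** (rate 0.2, matching typical
  ~80% software identification accuracy). Label errors replace the key with
  another master key and never touch RTs or spectra, so gold-standard
  discordance in tests is attributable to label noise alone.

All randomness flows through `numpy.random.default_rng` (PCG64); a fixed
seed reproduces byte-identical tables. What the generator does *not*
emulate: co-eluting analytes with genuinely shared spectra, intensity-
dependent RT shifts, detector saturation, or retention-order inversions
between configurations. Passing tests on this generator therefore show the
pipeline's correctness and its robustness to warp/noise/dropout/label
error, not performance on arbitrarily pathological real data.

## Problem sizes used in checks

The end-to-end study uses 3 heterogeneous runs of 100 metabolites with 10%
dropout and no label errors — comparable to a standards-mixture experiment
— and the parameter-recovery study uses 2000 reference peaks; both complete
in seconds. Known limitations: ρ̂/τ̂ ridge (above); chains require a
posterior above the cutoff in *every* consecutive pair, so a single weak
link removes a landmark; RT extrapolation far outside the landmark span is
linear and unverified by construction.
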