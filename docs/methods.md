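# Methods

This note documents the models, estimators and numerical choices behind
`smlmbayes`, and what the synthetic test conditions do and do not show.

## Camera and optics model

Raw frames in ADU are converted to photoelectrons by the affine camera
model `n = (I − offset)/gain`; negative values (noise below the bias) are
preserved so background estimates stay unbiased. For an EMCCD the gain is
the single *effective* gain in ADU per photoelectron; excess-noise-factor
modelling is deliberately out of scope.

Two pixel-domain scales derive from the optics (`λ` emission wavelength,
`NA`, magnification `M`, physical pixel `μ`):

* Airy-disk radius `R_airy = 0.61 λ M / (NA μ)` px — the classic
  first-minimum radius. The constant 0.61 is the conventional choice; the
  detection neighborhood and the fit half-window `h_f = ceil(R_airy)` both
  scale with it.
* Gaussian PSF width `s0 = 0.21 λ M / (NA μ)` px — the standard
  least-squares-optimal Gaussian approximation of an in-focus Airy PSF.

At the default configuration (λ = 670 nm, NA = 1.49, 70 nm effective
pixels) this gives `R_airy ≈ 3.92` px, `h_f = 4` (9×9 windows) and
`s0 ≈ 1.35` px. Configurations with `R_airy < 1` px are rejected as
undersampled.

**Coordinate convention.** Pixel `i` covers `[i·p_eff, (i+1)·p_eff)` nm
with `p_eff = μ/M`; exported nm coordinates are therefore
`(pos_px + 0.5)·p_eff`, origin at the outer corner of pixel (0, 0), x along
columns.

## Candidate detection and background

A candidate is any pixel that is maximal within a *circular* Euclidean
neighborhood of radius `R_airy`. No pre-selection whatsoever follows — the
separation of signal from noise is deferred entirely to the histogram
stage, which is the point of the method. Plateau ties keep the
lexicographically first pixel of each 8-connected component so output is
deterministic; candidates within `h_f` of a border are dropped because
their fit window would leave the frame.

Background is the minimum of the Gaussian-smoothed frame (kernel width
`s0`, truncated to the `(2h_f+1)` square and renormalized to unit sum so
constants are preserved) over a `(6h_f+1)` square around each pixel,
clipped at the borders (implemented via edge replication, which is
equivalent for a minimum filter and avoids artificial dark rims).

## PSF fitting

Each candidate window is fitted with the fixed-width Gaussian
`n_psf/(2πs0²)·exp(−r²/2s0²) + n_b`, free parameters `(x0, y0, n_psf,
n_b)`. Starting values: the integer peak position, the background estimate
under the peak, and `n_psf = 2π s0² (peak − n_b)` (the amplitude-to-integral
conversion of the model), floored at 1.

The least-squares fit runs in two passes: an unweighted pass, then a refit
with weights `1/max(model, 1)` — each pixel's inverse Poisson variance
under the first-pass model, floored at one photoelectron. The weighted
refit is the standard route to maximum-likelihood efficiency for
shot-noise-limited data: for a 1000-photoelectron spot on a background of
10 e⁻/px the mean per-axis position error drops from ≈0.051 px (unweighted,
matching the analytic unweighted-LS covariance) to ≈0.047 px, against a
CRLB of ≈0.046 px. On noiseless model data both passes recover parameters
to machine precision.

Two solver paths share the objective: a per-spot SciPy
Levenberg–Marquardt (`fit_psf`, the reference) and a vectorized LM over all
windows of a frame (`fit_spots`, used by the pipeline; a movie produces
tens of thousands of candidates and the batched solver is ~50× faster).
They agree to solver tolerance (asserted in tests). Convergence uses
relative step/cost tolerances of 1e-8 and at most 200 iterations; fits with
non-positive `n_psf`, a center outside the window, or diverged damping are
flagged failed and excluded from the histogram (the original behavior for
failed fits is unspecified; exclusion is the conservative choice).

Spots closer than `s0` (between fitted sub-pixel centers) are reduced to
the one with the largest `n_psf`, greedily in descending-count order —
deterministic, idempotent, and equal to the O(n²) largest-first suppression
oracle.

## Minimum-error thresholding

The pooled `n_psf` values of all frames are quantized into `N` gray levels,
`N = min(ceil(max), count)` by default (near unit-width bins for
photoelectron counts). Gray-axis coordinates are bin centers `L + 0.5`,
which also keeps logarithms finite at level 0. For every candidate level
`T` the histogram sides `{0..T}` and `{T+1..N−1}` are fitted separately and
the criterion

    J(T) = − Σ_i Σ_{x∈R_iT} h(x)·[log P_iT + log f_i(x|θ_iT)]

is evaluated; the global minimizer wins, and the threshold is reported as
`T* + 0.5` in raw units so "≥ threshold" selection is unambiguous. Any
monotone transform of the classification-error criterion preserves the
argmin; the log-likelihood form is used. Zero-count levels contribute
nothing (`0·log ≡ 0`).

Per-side estimators (the families are prescribed; the estimators are the
standard closed or quasi-closed forms):

* Gaussian: weighted mean and (population) standard deviation.
* Lognormal: mean/std of log bin centers.
* Weibull: profile-likelihood Newton iteration on the shape `k` (scale
  from the profile equation), started from the coefficient-of-variation
  moment approximation, computed on `x/max(x)` for overflow-free powers;
  method-of-moments fallback after 50 non-converged iterations; `k`
  clipped to [0.05, 50].

A candidate `T` is valid only if both sides carry ≥ 5 populated levels with
positive variance; if no candidate is valid the histogram is declared
not-bimodal and an error is raised — the method only applies when false and
true emitters form distinguishable groups.

**Plateau tie-break.** When the two modes are separated by an empty gap,
`J(T)` is *exactly* flat across the gap (every cut classifies the observed
data identically). The contiguous argmin plateau is then resolved at the
Bayes crossing of the fitted component densities (`P₀f₀ = P₁f₁`, found by
bracketed root solving), with the plateau midpoint as fallback. Dense
histograms have single-level plateaus and are unaffected. This makes the
threshold on well-separated mixtures converge to the Bayes-optimal
boundary instead of the arbitrary gap edge.

The stage is characteristic-agnostic: any scalar per-emitter quantity with
bimodal false/true structure can be thresholded (`smlmbayes threshold`
accepts a plain one-column CSV).

## Reliability

With fitted priors and densities, the expected false/true counts at
characteristic value x are `NF = total·P₀·f₀(x)` and `NT = total·P₁·f₁(x)`,
and the reliability is `R = NT/(NF+NT)`, evaluated as a logistic of the
log-density difference for numerical stability. Where both densities
underflow, R is set by the side of the fitted-mode midpoint (the density-
ratio limit). The reliability map holds the per-render-pixel *mean* R over
all potential emitters (accepted and rejected), max-normalized; "mean" is
the literal reading of the definition, and max-normalization is the chosen
interpretation of "normalized".

## Rendering

Super-resolution images are 2D count histograms of the accepted
localizations on a half-open `[lo, hi)` grid, default 10 nm render pixels;
an optional Gaussian blur (σ = 0.5 render px) gives conventional blob
rendering. Rendering conserves total intensity and is translation-
consistent.

## Evaluation

Reconstructed and reference tables are matched one-to-one within a
tolerance radius — by default the PSF FWHM, `2√(2 ln 2)·s0·p_eff ≈ 222 nm`
at the default optics — per frame. The pairing is an optimal assignment on
the within-tolerance pair graph (maximum cardinality, then minimum total
distance; solved with the Hungarian algorithm using a large constant on
infeasible edges), which is deterministic and order-independent, unlike
greedy matching. Jaccard = TP/(TP+FP+FN), precision, recall, and RMSD over
matched pairs follow; 0/0 ratios are defined as 0.

## Synthetic study conditions

The canonical scene (`standard_scene`) is a 128×128 px field at 70 nm
effective pixels (8.96 μm wide) holding three crossing polyline filaments,
imaged for 200 frames:

* 8 emitters/μm of filament, positions jittered laterally by σ = 10 nm to
  mimic label placement;
* per-frame activation probability 0.05 (≈12 active emitters per frame —
  sparse, as the single-emitter fitting model assumes);
* lognormal photoelectron counts per activation, median 800
  (`μ_log = ln 800`, `σ_log = 0.35`), the right-skewed single-fluorophore
  regime the Weibull–Lognormal model targets;
* smooth structured background, mean 10 e⁻/px; pixelwise Poisson noise;
  gain 2 ADU/e⁻ over offset 100 ADU.

These sizes keep a full analysis of one scene (≈50 000 candidate fits) to
about a minute on one CPU while reproducing the regime that matters: the
candidate count exceeds the true activation count ~20-fold, and the pooled
histogram is clearly bimodal. What passing tests on this generator show is
that the pipeline finds a near-Jaccard-optimal cut *when its distributional
assumptions hold approximately*; real data adds effects the generator
deliberately omits — fluorophore re-blinking kinetics, overlapping
emitters, EMCCD excess noise, PSF aberrations and 3D defocus, drift — so
performance there depends on how far those effects distort the two modes.

## Known limitations

* Single-emitter model: overlapping PSFs are fitted as one spot (and often
  pruned or misfit); multi-emitter fitting is future work.
* Fixed-width 2D fitting only; no astigmatic/3D or free-width mode.
* The threshold is undefined (by design, with a clear error) when the
  characteristic histogram is not separably bimodal.
* The fitted densities are a means to a good threshold, not a faithful
  description of the true-emitter distribution, which is typically a
  mixture of sub-populations; reliability values inherit this
  approximation.
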