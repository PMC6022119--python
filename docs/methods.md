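# Methods

## Data model

The unit of analysis is an averaged reflectance spectrum on a fixed
wavelength grid. The expected acquisition design is hierarchical: specimens
(individual fruit) × 4 sampling positions × 3 scans, recorded in one or more
sessions with differing ambient light. `average_scans` collapses scans to
one row per (specimen, session, position) *before* preprocessing; averaging
raw scans first reduces noise ahead of the nonlinear min-subtraction step.
Whether averaging precedes preprocessing is a genuine design choice (both
orders are defensible); the raw-first order is the package default and the
only one exercised.

Wavelengths must be strictly increasing and within 300–800 nm — a sanity
bound wide enough for any visible-range instrument but tight enough to catch
column indices passed as wavelengths.

## Preprocessing

Three per-row stages, applied in the fixed order zero → normalize → smooth:

| stage | operation | default | removes |
|---|---|---|---|
| zero correction | x − min(x) | on | constant ambient floor |
| two-norm normalization | x/‖x‖₂ | on | distance/illumination scale |
| Savitzky–Golay | order-3 LSQ polynomial, 31-point window | on | uncorrelated point noise |

The window is specified in **points**, exactly as configured; on grids with
different spacing the physical bandwidth (nm) changes and is never silently
rescaled. Edge handling fits the window-sized polynomial at each edge and
evaluates it over the first/last half-window (scipy's `mode="interp"`),
avoiding boundary discontinuities; the polynomial-preservation property is
asserted only at interior points. Because every stage is per-row, the chain
can be applied once up front without train/test leakage; the one
data-dependent statistic in the pipeline — column centering — lives inside
the model fit and is always computed on the training fold only.

The composite invariance that motivates the chain: output is unchanged under
x → a·x + b·1 for a > 0 (up to smoothing edge effects), i.e. affine
intensity drift between scans carries no signal downstream.

## SIMPLS and PLS-DA

Both X and the dummy-coded Y are column-centred. Each component takes its
x-weight **w** from the dominant left singular vector of the current
cross-product matrix S = XᶜᵀYᶜ (a p×c matrix, c ≤ number of classes, so the
decomposition cost is independent of n·p²); scores are t = Xᶜw; x- and
y-loadings are p = Xᶜᵀt/tᵀt and q = Yᶜᵀt/tᵀt; S is then deflated against
the orthonormalised basis of x-loadings, which enforces score
orthogonality. Weights are kept unit-length and scores unnormalised, with
tᵀt retained per component (`score_norms`) so the explained-variance
bookkeeping for VIP — SSYₐ = ‖qₐ‖²·tₐᵀtₐ — is explicit. Coefficients are
B = WQᵀ and prediction is (x − x̄)·B + ȳ. Extraction stops with an error if
S deflates to (relative) zero before the requested component count: the
data's rank is exhausted.

Class assignment is argmax over the continuous responses, ties broken
toward the earlier class in encoding order; a 0.5-threshold rule is exposed
as an option for binary models. Y is centred along with X (the indicator
means are the class priors, so ȳ acts as a prior-correcting intercept).
Truncating a fitted model to its first a components (`coefficients_at`)
is numerically identical to refitting at a, which is how
accuracy-versus-components curves are computed from one fit per fold.

VIP uses Y-variance summed over all dummy columns (the standard multi-class
choice; a per-response variant would weight components differently when
class sizes are unbalanced). The normalization identity Σⱼ VIPⱼ² = p holds
for every fitted model and is asserted at 1e-9.

## Evaluation protocols

**Repeated cross-validation.** Stratified k-fold (default k = 10), redrawn
per repeat (default 10 repeats) from seed + repeat-index, giving 100
per-fold accuracies per component count; curves report their mean and SD
(±2 SD is the conventional error bar). Stratification is used even though
plain random folds would also work at these sizes — with ~50 rows per fold
it visibly stabilises per-fold accuracy. Folds can be drawn at the sample
level (default, the most literal protocol) or at the specimen level, which
keeps all rows of one fruit on one side of each split. Sample-level folds
leak specimen identity when spectra carry per-specimen structure; the
generator includes such structure precisely so the difference is testable,
and the inter-session protocol is the external guard against the resulting
optimism.

**Inter-session evaluation.** One model per component count trained on the
full first session, tested on the full second session; the two sets must
have disjoint session ids. This probes robustness to ambient-light change:
a model that memorised session-specific background fails here while still
acing within-session CV.

**Baselines and selection.** ZeroR (majority-class accuracy) is the floor
for every task; component selection takes the accuracy peak, ties toward
fewer components.

## RGB comparison

Channel values are raw sensitivity-weighted sums over the profile's grid
(spectra are linearly interpolated onto it; out-of-range points contribute
zero and are warned about). No gamma, white balance, channel-area
normalization or illuminant term: the measured spectrum already contains
the illuminant, and each extra term would be a free parameter the
comparison doesn't need. Conversion is applied to preprocessed spectra —
the conversion sits downstream of the modelling pipeline, and after L2
normalization proportional raw spectra give identical RGB rows. Three
synthetic bell-curve camera profiles ship with the package (filenames
prefixed `synthetic_`); measured profiles in the same
`wavelength_nm,R,G,B` CSV format are drop-in replacements. With only three
features and centering, at most 2 PLS components are meaningful; the CLI
clamps the RGB component range accordingly.

The metameric construction projects a band-shaped class-difference vector
onto the orthogonal complement of the camera's three sensitivity rows, so
the two classes have identical noise-free RGB responses while remaining
separable in the full spectrum — the mechanism by which a camera loses
authentication-relevant information, isolated exactly.

## Synthetic data generator

A scan is gain·[baseline(λ) − Σ bands] + offset(λ) + N(0, noise_sd²).
Reflectance is modelled as a smooth two-lobe baseline minus Gaussian
absorption bands rather than raw detector physics: it reproduces the broad
shape of real fruit spectra qualitatively and makes class information local
in wavelength, which VIP testing requires. Defaults emulate the study
design the pipeline targets: 3 varieties × 44 specimens (half organic),
4 positions × 3 scans, a 1024-point 380–700 nm grid, and two sessions, the
second with a low-order-polynomial ambient offset and a gain change.

Default signatures place a chlorophyll-like band at 662 nm in every variety
with variety-specific depth (0.12–0.28) plus one variety-specific band;
organic status adds +0.03 to the 662 nm depth — deliberately small relative
to noise so the organic task is the harder one, matching the qualitative
difficulty ordering of the two determinations. Scan noise defaults to
sd 0.02 (baseline amplitude ≈ 1). A per-specimen amplitude jitter
(sd 0.05, shared across all 12 scans of a fruit and across sessions, since
the same fruit is re-scanned) makes specimens the independent units; real
data has such structure, and without it sample-level and specimen-level CV
would be indistinguishable. All randomness flows from one seed through
named substreams (specimen effects / per-session scan noise), so a config
regenerates bit-identically.

The ambient-offset magnitude between real sessions is unknown; it is a free
simulation parameter. The high-offset configuration used to demonstrate the
overfitting decline (offset coefficients (0.15, 0.3, −0.2), gain 1.2, band
amplitude 0.06 against noise 0.03) was chosen as a regime where the shift
is comparable to the class signal: small-component models stay accurate
across sessions while 15-component models degrade. For that check the
component count is selected on the inter-session curve (as the model
analysis does throughout), and the assertion additionally requires the peak
to fall strictly before 15 components so the comparison is not vacuous.

**What passing tests do not show.** The generator's classes are Gaussian
bands in i.i.d. Gaussian noise: no scattering baselines, no wavelength-
correlated detector noise, no within-specimen position gradients, no
temperature drift. Accuracy numbers on synthetic data therefore say the
pipeline is correct and well-behaved, not how accurate it would be on real
produce; with the default (deliberately clean) signatures the variety task
saturates near 100%.

## Problem sizes and numerics

The test suite runs on reduced grids (32–512 points) and small designs
(2–10 specimens per class) chosen so the whole suite completes in seconds;
`scripts/acceptance.py` runs the full 528-row × 1024-point design with
10×10-fold CV. Tolerances: SIMPLS vs oracles 1e-8, VIP identity 1e-9,
Savitzky–Golay polynomial preservation 1e-9 (interior points), score
orthogonality 1e-8 relative. Statistical assertions use 3-SD bands around
their expected values. Degenerate inputs fail loudly: all-zero spectra at
normalization, zero cross-product at fitting, rank exhaustion during
extraction, single-class one-vs-all targets.

## Known limitations

- No real instrument data ships with the package; conclusions about real
  apples require real spectra in the documented CSV format.
- Preprocessing order and the averaging-before-preprocessing choice are
  fixed defaults, not empirically optimised.
- VIP with summed explained variance is one of two common multi-class
  conventions; per-response weighting is not implemented.
- The RGB model ignores camera noise, quantisation and colour processing,
  so it bounds the information available to a camera from above.
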