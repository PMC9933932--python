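# Methods

## Correlation connectomes and quality control

Per-session ROI time series (T×N, TR in seconds) become Pearson
connectomes after confound regression. The confound design expands 9
base signals (6 rigid-body motion parameters plus global, white-matter
and CSF means) to 36 regressors: the 9 signals, their
backward-difference temporal derivatives (leading element 0), and the
elementwise squares of those 18. The derivative convention is the common
backward difference; the regression is single-shot OLS on
[intercept, 36 confounds, one delta regressor per spike volume], with
collinear columns dropped under a logged warning. Whether confound
regression and bandpass filtering should be one combined regression is
left open by the source procedure; this package performs a single
regression and treats bandpass as out of scope (synthetic data are
generated band-limited by construction).

Motion QC: a volume is a spike when framewise displacement exceeds
0.25 mm (configurable); a session is discarded when its non-spike
volumes amount to less than 4 minutes. With 150 volumes at TR = 2 s this
is the 120-clean-volume rule; the decision is monotone in the spike set.

Distances are d = 1 − r. Negative correlations give d > 1 and are
retained; no threshold is applied anywhere. A sentinel network label
`ALL` denotes the whole-brain matrix so whole-brain and per-network
analyses share one code path; per-network analysis takes the principal
submatrix of the 13-network parcellation (at least 3 ROIs required).

## Rips persistence

The Vietoris–Rips filtration is capped at `maxscale` (default 2.0, the
theoretical maximum of 1 − r; the cap is configurable). Simplices are
ordered by (filtration value, dimension, lexicographic vertex tuple).

*Degree 0.* Kruskal union-find over the sorted edges: each merge kills a
component at the edge weight, so the finite H₀ deaths are exactly the
minimum-spanning-forest edge weights; one essential class per component
at `maxscale` is reported with death +∞. Zero-persistence pairs are
dropped (they contribute nothing to any statistic).

*Degree 1.* Columns of the triangle boundary matrix are reduced over
GF(2) with a clearing restriction: rows are limited to the
cycle-creating (non-forest) edges, which is exact because the largest
edge of any 1-cycle necessarily creates a cycle when it enters the
filtration, so forest-edge rows can never hold pivots. Columns are
Python integers (bit = positive-edge rank), reduction is XOR with pivot
lookup. A reduced pivot pairs the triangle's value (its longest edge)
with the positive edge's weight; unpaired positive edges are essential
within the cap. Complexity is cubic in N through triangle enumeration:
comfortable to ~100 ROIs, slow at the full 264-ROI scale (the
whole-brain analyses in the validation studies therefore run at 60
ROIs).

Betti curves use the right-continuous convention
count(ε) = #{birth ≤ ε < death}; the AUC is computed exactly from the
diagram as total persistence Σ (min(death, maxscale) − birth), never
from a grid. Curve landmarks: `eps_single` is the largest finite H₀
death (where the component count first reaches its terminal value),
`b1_onset`/`b1_offset` the first hole birth and last finite hole death,
`b1_max`/`b1_argmax` the peak hole count and the smallest ε attaining
it; B₁ landmarks are reported as missing when the diagram has no holes.
Grids (default step 0.005) serve plotting and the null-ensemble band
only.

Correctness is established against two independent oracles: a
brute-force GF(2) boundary-rank computation of B₀/B₁ at every distinct
filtration value (B₀ = N − rank ∂₁, B₁ = nullity ∂₁ − rank ∂₂), and
scipy's minimum spanning tree for the H₀ deaths.

## Rewired-edge null models

"Randomly rewired" is implemented as a uniform permutation of the
upper-triangle correlation values over node pairs, mirrored to the lower
triangle: the weight multiset is conserved exactly while all topology is
destroyed. Degree- or strength-preserving rewiring is deliberately not
implemented. Each bootstrap draws one connectome from the sample with
replacement, then rewires it (resample-then-rewire; whether the original
procedure rewired each session once instead is not determinable from its
description). The ensemble reports the pointwise mean and 2.5/97.5
percentile band (no normal approximation). One master seed spawns one
substream per bootstrap, so enlarging `n_boot` never reshuffles earlier
draws; connectomes are internally ordered by a content hash so the
ensemble is invariant to input order.

## Developmental trajectory battery

All eight models share: subject random intercepts, mean framewise
displacement and head coil (8ch reference; the coil column is dropped
with a note when only one level is present) as covariates, sex coded
with F as reference, and maximum-likelihood estimation. The solver
profiles the fixed effects and the residual variance out of the marginal
Gaussian likelihood and optimizes the variance ratios (coarse log-grid
start, Nelder-Mead polish); it was verified to reproduce statsmodels
MixedLM log-likelihoods to ~1e-9 and mgcv penalized-spline fits to
shape correlation > 0.999.

Smooths are cubic P-splines: B-spline bases with equally spaced interior
knots, penalized by second divided differences over the Greville
abscissae, so the penalty null space is exactly {1, x}. In the
mixed-model representation the centered covariate is the unpenalized
fixed column and the whitened wiggle space is a variance component.
Basis dimension is min(10, number of distinct covariate values) — for
ordinal PDS effectively 4 — shrunk with a logged warning when needed.
The age×PDS interaction is a tensor-product smooth decomposed
t2-style into three variance components (age-wiggle × {1, PDS},
{1, age} × PDS-wiggle, wiggle × wiggle) over the bilinear fixed columns
{age, PDS, age·PDS}; by-sex smooths are one smooth per sex level plus a
sex main effect, with per-sex smoothing parameters for 1-D smooths and
shared per-component parameters for the by-sex tensor (keeping the
optimizer low-dimensional).

AIC uses the marginal ML log-likelihood with
k = p_fixed + 2 + (number of smoothing parameters) + (smooth EDF), the
smooth EDF measured by the edf1 variant 2tr(F) − tr(FF) of the penalized
hat trace, which charges for smoothing-parameter adaptivity; for the
linear mixed models this reduces to the usual fixed effects + 2 variance
parameters. Without the edf1 charge the nested tensor model wins on pure
noise far too often for model ranking to be meaningful.

Smooth terms are tested with a Wood-type F statistic: the term's fitted
contribution f̂ against the rank-r pseudoinverse of its Bayesian
covariance, with fractional rank handled by down-weighting the
(⌊r⌋+1)-th eigendirection; the rank is the term's edf1, the
coefficient-covariance scale is RSS/(n − total EDF) and the reference
distribution F(r, n − total EDF). On matched null datasets the resulting
p-values reproduce mgcv's summary to a median |Δlog₁₀ p| of ~0.002, and
the smooth-term type-I error at α = 0.05 is 0.061 over 1000 null cohorts
at the default study scale. Shapiro–Wilk normality checks (scipy's
Royston implementation) run on conditional residuals and on the
estimated random intercepts of every fit. Non-converged fits are
reported and excluded from the AIC argmin, never silently replaced.

Missing PDS: sessions under age 10 are set to level 1; remaining gaps
are predicted (clipped to [1, 4]) from a per-sex penalized smooth of the
observed PDS on age with subject random intercepts, adding the subject's
estimated intercept where that subject contributed observed values.

Whole-brain analysis selects among all 8 models; the winning model is
then refit per network, and the 13 network p-values per response are
corrected by Benjamini–Hochberg FDR at q = 0.05 (statsmodels'
implementation, verified against the step-up definition on random
vectors). Per-network refitting is the plain reading of applying the
winning model to the networks; a joint model across networks is not
attempted.

## Synthetic cohorts

`simulate_cohort` draws 98 subjects by default (fraction female 0.54,
baseline ages uniform on 6.7–18.1 years). About 42% return ~5 years
later and 16% again ~2 years after that; returners are drawn among
subjects young enough that all sessions stay inside the stated age
range. PDS is the ordinal rounding of a clipped logistic in age
(midpoint 11.5 y for females, 12.5 y for males, scale 1.1 y, latent
noise SD 0.2), forced to 1 under age 10; 5% of entries are masked
missing (the study itself had 8 of 155 missing). Mean FD is lognormal
with a negative age trend; 13% of sessions use a 32-channel coil; ~12%
fail QC with failure probability increasing in FD.

The developmental effect is g(PDS): linear rise from 0 at level 1 to a
peak of 1 at level 2, then a linear decline to 0.5 at level 4. Its
default amplitude (2.0) together with the default noise scales (subject
intercept SD 0.5, residual SD 0.5) gives a standardized effect around
d ≈ 0.85 — a clearly detectable effect, which is what the recovery
studies are meant to probe.

Two generation routes share one ground truth. The *time-series route*
samples T = 150 multivariate-normal volumes (TR = 2 s) from a
block-modular correlation matrix — 4 covariance modules by default, the
fronto-parietal network its own module with within-block correlation
0.30 + 0.15·(amplitude·g(PDS) + 0.3·subject intercept), other modules at
0.35 within and 0.08 between — eigenvalue-floored to positive
semidefinite, plus white observation noise. The *feature route* writes
per-session, per-network response values directly:
y = 10 + amplitude·g(PDS)·[network carries the effect] + subject
intercept − FD + 0.2·[32ch] + noise, with the effect carried by the
fronto-parietal network and the whole brain. The feature route is what
the thousand-replicate recovery, calibration and localization studies
use; the time-series route exercises the full pipeline (QC →
connectome → persistence → nulls → models) at the small profile
(30 subjects / 60 ROIs by default, under a minute to generate).

What the synthetic data do *not* emulate: hemodynamics, scanner
artifacts, spatial structure within ROIs, distance-dependent motion
artifacts, or any real spatial layout of the parcellation. Passing
recovery tests therefore demonstrates that the pipeline measures what it
claims on data satisfying its model assumptions — not that those
assumptions hold for any given fMRI dataset.

## Validation studies and problem sizes

The acceptance script and the heavy end of the test suite run: the
homology oracle on 1000 random matrices (N ≤ 10, exact agreement
required), the spanning-forest identity on 1000 instances, AUC vs
1e-3-grid integration on 200 instances (tolerance 1e-2, the grid
left-rule error bound), the worked FDR example over the 13 published
network p-values (exactly the fronto-parietal network survives), the
null-ordering study on 100 modular connectomes (60 ROIs, 4 modules,
within/between correlation 0.6/0.1), selection recovery and linear-age
recovery at 100 replicates each, type-I calibration at 1000 null
replicates, and localization at 100 replicates — the simulation studies
at the default 98-subject scale through the feature route, the
topology-heavy studies at 60 ROIs. These sizes keep the full suite
under ~10 minutes on one CPU.

## Known limitations

- Homology stops at dimension 1; no landmark/witness complexes, no
  persistence images or landscapes.
- The pure-Python reduction is not built for 264-ROI whole-brain
  matrices in bulk; a compiled backend would be the natural extension.
- AIC for additive models is one convention among several; model
  *ranking* under the stated k is the contract, and AIC values are not
  comparable across packages.
- The smooth F test is approximate (as all tests of penalized smooths
  are); its calibration was verified by simulation at the default study
  scale only.
- REML estimation and random slopes are out of scope; estimation is ML
  throughout.
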