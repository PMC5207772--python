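# Methods

## Binding model and its assumptions

Every fit in this package reduces to a two-state 1:1 association
U + L ⇌ UL at equilibrium, solved without the excess-ligand approximation:
with the observed species at total concentration [U]₀ and the titrant at
[L]₀, the bound fraction is the physical root of
(U₀−c)(L₀−c) = Kd·c, i.e.

    f_b = ((Kd + L₀ + U₀) − sqrt((Kd + L₀ + U₀)² − 4·U₀·L₀)) / (2·U₀).

Numerically the equivalent form 2·L₀ / (b + sqrt(b² − 4·U₀·L₀)),
b = Kd + U₀ + L₀, is used to avoid cancellation at small bound fractions,
with the discriminant clipped at zero against roundoff.

Assumptions: a single binding site, no cooperativity or 2:1 stoichiometry,
and observables that are linear in the bound fraction. For slow-exchange
NMR data the intensity model attributes peak fading entirely to population
loss of the free state; exchange-broadening contributions beyond population
transfer are not modeled. Intermediate-exchange lineshapes are out of scope.

For membrane-confined species, concentrations are in mol% — (moles protein ×
100)/(moles long-chain lipid), with short-chain detergent (D6PC) excluded —
because association within a bicelle scales with the lipidic volume, not the
aqueous volume. Soluble ligands use µM. Every concentration-bearing object
carries a unit tag and mixing tags raises an error rather than a warning:
a Kd silently interpreted in the wrong unit is the costliest failure mode of
this kind of analysis.

The hybrid amide shift default is Δ(HN) = sqrt((W_H²ΔH² + W_N²ΔN²)/2) with
W_H = 1 and W_N = 0.154. The common alternative sqrt(ΔH² + (W_N·ΔN)²) is
available via `hybrid_shift(..., form="quadrature")`; because the two differ
per peak only by a fixed rescaling under the default weights, fitted Kd
values are insensitive to the choice — only Δmax values rescale.

## Global titration fitting

A titration of n peaks over m points is fit jointly with n+1 parameters: one
global Kd (bounded ≥ 0) and one free amplitude per peak (I₀ for intensity
decays, Δmax for shift perturbations). Amplitudes are never shared across
peaks: real peaks respond with visibly different amplitudes.

*Optimizer.* Bounded trust-region least squares (via lmfit), with a
multistart on Kd at {0.1, 1, 10} × max(L₀). The isotherm's objective is
nearly flat in Kd when a titration stops far from saturation, and a single
start from the wrong side of the flat region stalls; the best of the three
starts by chi-square is kept.

*Weighting.* Residuals are weighted as constant coefficient-of-variation:
σ_ip = max(|y_ip|, 0.1 · max_p|y_ip|). NMR peak intensities and shift
perturbations carry errors roughly proportional to the measured value (the
same convention as the "5% of value" floor used for intensity ratios), and
an unweighted fit under such noise produces standard errors too small by
roughly a third. The floor at 10% of each peak's full response keeps
near-zero points (the fast-exchange reference point, fully faded peaks) from
dominating. Weighting by the *model* instead of the data is deliberately
avoided: with free amplitudes it is degenerate, since inflating an amplitude
inflates σ and shrinks the weighted residuals.

*Uncertainties.* Standard errors come from the Jacobian-based covariance at
the optimum, scaled by reduced chi-square; no bootstrap by default. Under
the generator's 5% noise the ±1 SE interval covers the truth in ~62–78% of
runs, consistent with a Wald interval.

*Saturation and lower bounds.* After every fit, the bound fraction at the
top titrant point is computed from the fitted Kd. If it is strictly below
0.5 (ties stay quantified), or if the Wald upper edge Kd + 1.96·SE exceeds
3 × max(L₀), the result is flagged `lower_bound` with
`lower_bound_value = max(L₀)` by default. All three constants and the
lower-bound convention are configurable (`SaturationOptions`); published
lower bounds derived from other conventions will not in general equal
max(L₀), so the callable hook exists to reproduce them. The flag never
suppresses the point estimate: a flagged fit still reports Kd and SE, since
near the threshold the estimate can be perfectly serviceable (a titration
reaching 49% bound determines Kd to a few percent).

## Topology from paramagnetic probes

Per-residue accessibility is I_para/I_dia between matched spectra. Errors
are max(noise-propagated error, 5% of the ratio); residues detectable only
in the diamagnetic spectrum enter as ratio 0 with error noise/I_dia —
"broadened beyond detection" is information, not missing data.

The TM caller smooths both profiles with a moving median (window 3, robust
to single-residue dropouts without moving monotone edges), then takes the
longest run of consecutive residues where the hydrophilic-probe ratio is
≥ 0.7 and the lipophilic-probe ratio is ≤ 0.5, requiring at least 12
residues (a shorter helix cannot span a bilayer). No published numeric
thresholds exist for the plateau/trough reading — it is done by eye in
practice — so 0.7/0.5 are this package's calibration, chosen jointly with
the synthetic-profile shapes (below) and exposed in `TopologyParams`.
If no run qualifies the call is empty with an explicit
"no membrane-embedded span" flag. Boundaries are reported 1-based inclusive;
intervals are half-open internally.

Profile comparison combines per-residue errors in quadrature and counts
residues with |Δ| > 2σ; the verdict is "unchanged" while the count stays
within ceil(0.05·n), the chance allowance at that threshold. Swapping the
two profiles negates deltas and preserves the verdict.

## Secondary structure and dynamics

The CSI caller indexes each of CA/CB/CO by its deviation from a random-coil
reference (thresholds 0.7/0.7/0.5 ppm; helix = CA or CO downfield, CB
upfield), takes a majority consensus over the atoms present, and reports
helix segments as runs of ≥ 4 consecutive helix-consensus residues;
candidate segments with under 70% CA coverage are dropped as too sparse to
call. A packaged random-coil CA/CB/CO table (standard published coil shifts)
ships with the package and `coil_reference_for_sequence` builds per-residue
references from a one-letter sequence. This is an approximation of a full
CSI-plus-dihedral-prediction workflow: it locates helix boundaries from
carbon shifts but does not predict dihedral angles.

CLEANEX ratios are reported raw (low I/I0 = exchange-resistant); no
threshold is imposed because protection is a continuum along a fraying
helix. R2 rates come from per-residue fits of I(t) = I₀·exp(−R2·t)
(delays in ms, rates in s⁻¹), initialized from a log-linear regression on
the positive intensities and bounded R2 ≥ 0; residues that fail to converge
are excluded with a warning rather than poisoning the table. The delay list
is data — nothing assumes a particular number of delays.

## What the synthetic generators emulate

All generators are deterministic functions of (truth, design, seed), with
one seeded generator per call, and their zero-noise output is exactly
on-model.

*Titrations* use the six-point schedules of the targeted experiments
(mole ratios 0, 0.5, 1, 2, 3, 4 for slow exchange at U₀ = 0.17 mol%;
0, 1.25, 2.5, 3.75, 5, 7.5 for fast exchange at U₀ = 0.23 mol%; the talin
design fixes the labeled integrin at 100 µM), draw per-peak amplitudes
log-uniformly (I₀ ∈ [0.5, 2] a.u.; Δmax ∈ [0.02, 0.12] ppm, the span of
well-shifting amide peaks), and apply 5% multiplicative Gaussian noise.

*Accessibility profiles* rise logistically (steepness 1.5 residues) into the
annotated TM span for the hydrophilic probe (0.20 exposed → 0.95 protected)
and dip as a Gaussian bell for the lipophilic probe (0.95 → 0.10 at the TM
center). The threshold crossings are placed half a residue outside the
annotated boundary residues, which calibrates the default 0.7/0.5 thresholds
to read back the fixture truth exactly at zero noise. The quoted per-residue
error propagates noise from both the probe-containing and the probe-free
spectrum (√2 × the per-spectrum relative noise) while the simulated scatter
applies the net perturbation as a single draw — quoted errors are therefore
mildly conservative, as empirical intensity-ratio error bars tend to be.
An optional chelate-artifact mode depresses hydrophilic ratios in a ~2.5
residue Gaussian around a designated carboxylate site, emulating transient
association of chelate probes with Glu/Asp side chains; its signature — a
"changed" verdict for the hydrophilic probe with an "unchanged" lipophilic
verdict — is how the artifact is diagnosed.

*Anisotropy titrations* fix the labeled species at 0.2 µM in 2% w/v q = 0.3
D6PC/POPC/POPS bicelles (≈ 8.8 mM long-chain lipid, so U₀ ≈ 0.0023 mol%),
titrate over a zero point plus 11 log-spaced points up to 3.2 mol% (the
published schedules are unprinted; this design spans the relevant Kd range),
and average five replicate readings with 0.005 additive noise each, reporting
the replicate SD per point.

*Packaged fixtures* encode the residue annotations of the two proteins the
package was built around: β1 TM/CT (residues 719–798, TM 732–757, helix
732–765) and β3 TM/CT (685–762, TM 693–721, helix 693–737). Fixtures store
numbering and annotations only; sequences are optional.

What the generators do **not** emulate: spectral processing, peak overlap
and misassignment, exchange broadening beyond population transfer,
temperature/pH effects, bicelle-size polydispersity, and fluorophore
photophysics. Passing tests therefore demonstrate that the estimators are
correct and well-calibrated for the stated noise model, not that they are
robust to every pathology of real spectra — outlier peaks (the
`refit_excluding` workflow) and the chelate artifact are the two real-data
pathologies explicitly modeled.

## Problem sizes and numerical choices

Stochastic checks use 50-seed ensembles for parameter recovery (median
recovered Kd within 15% for NMR fits, 20% for anisotropy) and 100-seed
ensembles for topology boundary recovery (±2 residues in ≥ 90% of runs) —
ensemble sizes at which medians of these estimators are stable to a few
percent. Round-trip identities are asserted at 1e−6 (optimizer tolerance)
and the closed-form bound fraction agrees with a brentq mass-action solution
to 1e−9 over kd ∈ [1e−4, 10], u0 ∈ [0.01, 1], l0 ∈ [0, 10] mol%.

Degenerate inputs are errors, not NaNs: all-zero intensities, no shared
residues between paired tables, excluding every peak, decreasing-only
anisotropy (inverted labeling), non-positive lipid in mol% conversions, and
unit mixing all raise with messages naming the offending data.

## Known limitations

* Lower-bound values default to max(L₀); published lower limits computed by
  other conventions are not reproduced without a custom
  `lower_bound_value` callable.
* The slow-exchange intensity model ignores exchange-broadening; if fading
  peaks also broaden, the fitted Kd absorbs that systematic.
* CSI here is a boundary locator, not a dihedral predictor; helix termini in
  fraying regions are soft by nature and the ≥ 4-residue run rule makes
  single-residue helix interruptions invisible.
* The topology thresholds were calibrated on the synthetic profile shapes;
  real profiles with strong artifacts or sparse coverage may need
  per-dataset threshold adjustment via `TopologyParams`.
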