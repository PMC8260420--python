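# Methods

## Forward model

Each metabolite is a set of resonances; a resonance is a J-multiplet of
Lorentzian absorption-mode lines with a shared FWHM. On a ppm grid *x* the
render of a resonance with centre δ, components (Δν_j, w_j) and n protons is

    s(x) = n · Σ_j w_j · (γ/π) / ((x − δ − Δν_j/ν₀)² + γ²),

with γ the half width in ppm (FWHM/2, converted from Hz by the Larmor
frequency ν₀) and Σ w_j = 1. The analytic area on the ppm axis is exactly
*n* per unit amplitude, so **unit amplitude ≡ 1 mmol/L-equivalent** and the
area of a fitted signal is `amplitude × n_protons`. Basis columns are these
renders; the default basis holds the ethanol CH₃ triplet (1.18 ppm,
J = 7.1 Hz, 1:2:1, 3H), NAA (2.01 ppm, 3H), Cr (3.03 ppm, 3H) and Cho
(3.20 ppm, 9H), with the ethanol CH₂ quartet (3.65 ppm, 2H) available but off
by default. These shifts and couplings are standard in vivo values, kept in a
constants table so they can be revised. Defaults: 3 T (ν₀ = 123.25 MHz),
TE 74 ms, FWHM 4 Hz, uniform grid 0–5 ppm with 2048 points.

Deliberate simplifications: no density-matrix simulation, no TE-dependent
J-modulation of the ethanol triplet (the basis is treated as TE-matched), no
macromolecule baseline, no phase/frequency/lineshape nuisance parameters.

## Estimator and precision

Amplitudes minimize ‖y − B·a‖² subject to a ≥ 0 (active-set NNLS,
`scipy.optimize.nnls`). Amplitudes within 1e-10 of the boundary relative to
the largest amplitude are set exactly to zero and excluded from the active
set. The noise SD is the residual SD, after removing a linear trend, in a
signal-free window (default 4.2–5.0 ppm of the water-suppressed spectrum).
The relative Cramér-Rao bound is computed on the active columns:

    CRLB_i(%) = sqrt([(BᵀB)⁻¹]_ii) · σ / a_i · 100.

Metabolites fitted at zero get NaN — the relative bound is undefined there.
Under the iid-Gaussian noise model the unconstrained estimator attains this
bound, so Monte-Carlo scatter should sit at ~1.0× the reported CRLB whenever
the truth is interior; the test suite checks [0.8, 1.25]× over replicate
fits. Spectra on a different grid are linearly resampled onto the basis grid;
extrapolation is refused.

## Absolute quantification

With A_met the metabolite signal area (= amplitude × n_protons) and A_w the
area of the unsuppressed water line:

    c_met [mmol/L voxel] = (A_met/A_w) · (n_w/n_met) · C_water · 1000,

where C_water = f_gm·42.9 + f_wm·35.8 + f_csf·53.4 mol/L is the
fraction-weighted voxel water molarity. The water area is estimated by a
single-column model fit rather than numerical integration: on a 0–5 ppm grid
the truncated Lorentzian tails carry ~3 % of the analytic area, which the
model-based estimate recovers exactly on noiseless data.

Two water-content variants are kept explicit: the mol/L molarity above
(reference scaling) and the volume-fraction percentage
wc = f_gm·78 + f_wm·65 + f_csf·97 (the normalization denominator). Ethanol is
assumed to distribute only in the aqueous compartments, so

    c_norm [g/L water] = c_raw [g/L voxel] / (wc/100),

with the inverse (`denormalize`) multiplying back. Molar mass 46.068 g/mol
converts mmol/L to g/L, exposed as a constant. No relaxation correction is
applied (`relaxation_factor` hooks default to 1); CSF-dissolved ethanol with
its longer T₂ receives no differential treatment — a known limitation.

Table-mirroring outputs round half away from zero (1 decimal for wc, 2 for
g/L). The wc of a voxel printed as integer tissue percentages is computed in
decimal arithmetic, because binary floats misround exact midpoints (85 % GM /
15 % WM gives exactly 76.05 → 76.1, while float arithmetic yields
76.049999…). Printed integer percentages need not sum to exactly 100; voxel
compositions therefore tolerate |f_gm+f_wm+f_csf − 1| ≤ 0.015 and are *not*
renormalized, which is the only convention that reproduces the printed water
contents.

## Synthetic data

The generator emulates the study conditions: a suppressed voxel spectrum is
B·a plus iid Gaussian noise per grid point; the water reference is a single
line at 4.70 ppm whose area is the physically consistent
n_w · C_water · 1000 for the voxel composition; region-typical GM/WM/CSF
fractions are drawn uniformly from ranges calibrated to the segmented study
voxels (e.g. cerebellum GM 0.77–0.89, CSF ≤ 0.04; frontal cortex CSF
0.08–0.23) and renormalized to sum exactly to 1. Default true concentrations
are 13 mmol/L ethanol (≈ 0.6 g/L, the centre of the study's design target)
and typical NAA/Cr/Cho (12/8/2 mmol/L).

The default noise SD (75 signal units per point) was derived analytically
from the design matrix: σ = CRLB·a/√[(BᵀB)⁻¹]_EE with a mid-single-digit
CRLB target, placing the ethanol CRLB at ~4–7 % for default truths —
inside the 3–12 % band typical of dedicated long-TE ethanol acquisitions.
The actual acquisition SNR behind that band is not identifiable from summary
data, so the claim is checked as *attainable*, not reproduced exactly.

Serum curves are piecewise linear: zero at t = 0, linear rise to the peak at
the end of the absorption window (default 60 min), then zero-order decline
at β (default 0.15 g/L/h, the classical elimination range), clamped at zero.
The sparse five-draw sampling of the study cannot identify a richer
absorption model, so absorption duration is a free parameter rather than a
fitted one. Not modelled: absorption compartments, Michaelis–Menten
elimination, time-domain FID effects (phase/frequency drift).

What passing synthetic tests do **not** show about real data: baseline and
lineshape model error, water-suppression residuals, relaxation losses, and
motion/drift — the CRLB is a precision bound, not an accuracy bound, and
systematic errors from an imperfect fitting model are outside it. A
mis-specified linewidth between simulation and basis is the only model-error
probe available here.

## Study-design arithmetic

Widmark dose: grams = BAC_target · mass · r / (1 − resorption deficit);
beverage volume = grams / (density · ABV). Serum (g/L) converts to blood
(g/kg) by the divisor 1.2375 = 0.99/0.8, the value implied by the design
correspondence (the conventional forensic 1.236 may be passed instead). The
study's actual beverage volumes are not reproducible without the authors' r
and deficit choices and are treated as data, not targets.

The brain-vs-serum comparison is descriptive (n = 3 forbids inference):
per-subject extrema, range, and coefficient of variation per matrix, a
flatness ratio CV_brain/CV_serum (defined as 1 when both curves are
constant), and brain/serum ratios at nearest-time pairings within ±20 min
(the scan/draw interleaving scale). Brain scan clock times in the packaged
table (20/30/50/60, 110/120/140/150 min) are reconstructed from the
protocol order and ~7-min scan length around the stated draw offsets
(+40/+70/+130/+160 min); they are approximate metadata.

## Determinism and problem sizes

Every stochastic routine takes an explicit integer seed; the pipeline derives
per-voxel seeds from one base seed, so identical configurations give
byte-identical output files. Monte-Carlo checks use 500 replicates of
2048-point spectra (300 in the unit suite), which estimates the relative SD
to ~3 % — comfortably inside the [0.8, 1.25]× CRLB acceptance band.
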