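# Methods

This note documents the models behind each pipeline stage, the synthetic
data they are exercised on, and the numerical choices that were genuinely
open. It states no result the tests or `scripts/acceptance.py` do not
themselves compute.

## The incision-assay model

The fluorescence assay follows a hairpin substrate whose cleavage separates
a fluorophore from a quencher: one incised substrate molecule adds `gain`
RFU. With first-order substrate turnover,

    F(t) = F0 + gain · S0 · (1 − exp(−k t)) + ε,   ε ~ N(0, σ²),

where `S0` is the substrate concentration (nM), and `k` depends on the
well: the basal rate `k0` (DMSO control), the APE1-coupled full-turnover
rate `k_ape1` (100% control), zero (no-enzyme control), or the
compound-dependent observed rate.

**Bell-shaped rate law.** An active-site activator increases turnover as it
occupies its site but competes with substrate binding at high
concentration. The simplest occupancy-times-competition model with both
limbs first order is

    k_obs(c) = (k0 + k_acc · c/(c + K_A)) · K_I/(K_I + c),

which satisfies k_obs(0) = k0, k_obs(∞) → 0 and is unimodal for
k_acc > 0. This functional form is a modeling choice of this package, not
a measured rate law; whether the competitive term acts before or after the
covalent (Schiff-base) intermediate is deliberately not resolved — a single
multiplicative term stands for the net effect.

**Default parameters** (the study conditions every recovery figure is
measured under):

| parameter | value | why |
|---|---|---|
| k0 | 3.125 × 10⁻⁶ s⁻¹ | basal AP-lyase turnover is very slow; 1/20 of the coupled rate |
| k_ape1 | 6.25 × 10⁻⁵ s⁻¹ | full-turnover control; k·T = 0.1 over the read (see below) |
| k_acc | 6.003125 × 10⁻⁵ s⁻¹ | solved analytically so the ground-truth AC50 is exactly 0.50 µM |
| K_A / K_I | 0.5 / 50 µM | two-decade separation gives a clear rise-then-fall shape |
| S0, gain, F0 | 10 nM, 100 RFU/nM, 50 RFU | 1000-RFU full-scale amplitude |
| reads | every 10 s for 1600 s (161 reads) | plate-reader kinetic mode |
| σ ("2% noise") | 20 RFU = 2% of the full-turnover amplitude | constant instrument read noise |
| concentrations | 0.01–30 µM, 8 half-log steps, triplicates | standard dose-response layout |

The read length was set by a bias/variance analysis of the initial-slope
estimator: an OLS slope of a saturating exponential underestimates
`gain·S0·k` by ≈ 0.45·kT (relative), so the % -activation ratio between a
compound well and the faster APE1 well inflates with k·T; read noise on the
slope instead scales as σ·√(12·Δt/T³). With k_ape1·T = 0.1 and 161 reads
the systematic error contributes ≈ 0.02 decades to the recovered log-AC50
and the stochastic part ≈ 0.03–0.04 — comfortably inside the 0.07-decade
recovery requirement the acceptance suite checks over 100 plates.

Per-well random streams are spawned from the master seed
(`numpy.random.SeedSequence(seed).spawn`), so plates are bit-reproducible
and wells independent.

## Rate extraction and normalization

`detect_linear_window` returns the longest *prefix* of a trace (initial
rates are anchored at t = 0) whose OLS fit has r² ≥ `r2_min`, at least
`max(3, ⌈min_frac·n⌉)` points; if none qualifies the minimal window is
returned flagged low-quality. r² is defined as 1 for a zero-variance trace
(a constant is a perfect flat-line fit). The rule is validated against an
exhaustive prefix-enumeration oracle.

The **default pipeline** uses the full read as the window
(`min_frac=1.0, r2_min=0.0`): the generator confines reads to the initial
phase (k·T ≤ 0.1) where the whole trace *is* the linear part, and under
read noise comparable to a slow well's total signal no single r² threshold
can both accept slow control wells and trim fast ones. Strict window
detection remains available for longer or cleaner traces.

% activation is `(v_c − v_dmso) / (v_ape1 − v_dmso) × 100` — 0% at the
basal (DMSO) rate, 100% at APE1-coupled full turnover. The controls fix
both the baseline and the scale; the value may legitimately be negative
(inhibition below basal) or above 100. Replicates are averaged at the rate
level (mean slope, SE = SD/√n), not at the fluorescence level.

## Dose-response fitting

The bell model `A(c) = a_max · c/(c+k_a) · k_i/(k_i+c)` (both Hill slopes
fixed at 1 — the data do not constrain more parameters) is fitted by
Levenberg–Marquardt least squares, multi-started over a fixed log-spaced
grid of (k_a, k_i) initial values so the result is deterministic; k_a and
k_i are parametrized on the log scale (clamped to e^±40) to stay positive.
A negative fitted amplitude is clamped to a_max = 0 ("no activation").

The fit is **unweighted by default**. Inverse-variance weighting with SEs
estimated from triplicates (2 degrees of freedom) lets a randomly small SE
dominate the fit; measured on the study conditions it raised the median
AC50 recovery error from 0.040 to 0.059 decades. `weighted=True` restores
1/se² weighting when well-estimated SEs are available.

**AC50** is read from the fitted curve's *rising limb*: the smallest
concentration where A(c) crosses 50 from below, found by bisection on
[c_min, argmax] to 10⁻⁴ relative tolerance (the bell's argmax is
√(k_a·k_i)). Curves that never reach 50% inside the tested range are
censored "AC50 > c_max"; curves already above 50% at c_min are censored
below. The primary-hit flag requires an uncensored AC50 below 100 µM.

Classification: *activator* when an uncensored AC50 exists; *inhibitor*
when the response drops below −10% activation at some tested concentration
(with a fast full-turnover control, complete loss of the basal rate only
reaches ≈ −5…−15%, so the conventional −50 would never fire); the IC50 is
then the midpoint of a hyperbolic fit 1/(1 + c/IC50) to the relative rates
v/v_dmso. *Inactive* otherwise.

## Compound metrics

pAC50 uses molar units and log base 10 (the universal pIC50 convention).
Heavy atoms are counted on the free base; the formula tokenizer rejects
salt/solvate dot-components outright, and `strip_adduct_proton` converts
[M+H]⁺ HRMS formulas. AcLE = (1.37/#HA)·pAC50 and AcLLE = pAC50 − clogP
are kept at full precision internally and rounded (3 dp / 2 dp) only at
the reporting layer. Triage keeps LE ≥ 0.40 (boundary inclusive) with
PAINS/REOS supplied as input flags — substructure catalogs are out of
scope. Fold-selectivity divides the lowest off-target panel IC50 by the
AC50 and propagates ">" lower bounds when every panel entry is censored.

## In-vitro PK

Microsomal stability: OLS of ln(remaining signal) vs time ("remaining"
being the chromatographic parent-peak area, not exposure); kel = −slope,
t½ = ln2/kel (the identity t½·kel = ln 2 holds exactly for every
uncensored fit), Clint = kel · 1000/0.42 µL/min/mg from the documented
0.42 mg protein/mL incubation. A non-positive slope is reported as
censored/stable rather than a negative clearance.

Caco-2: P_app = V_A/(Area·Time) · amount_acc/amount_donor,initial, with
the acceptor volume in cm³ and the result reported in nm/s; defaults are
the 0.7 cm² insert, 90 min, 300/1000 µL compartments. Efflux ratio =
P_app(B→A)/P_app(A→B); a ratio above 2 flags active efflux, and a
verapamil-induced decrease of at least 10% (relative; configurable, to
avoid noise-driven calls) flags a P-gp substrate. The transport simulator
inverts the same equation, so the noiseless round trip is exact to
floating-point.

Kinetic solubility interpolates a sample absorbance on an OLS calibration
line (×2 dilution factor) and flags values outside the ≈ 2–350 µM
effective range or calibrations with R² < 0.99.

## Trajectory analyses

Superposition uses the Kabsch algorithm (SVD of the cross-covariance with
the determinant correction, so reflections are never used), in double
precision; the test suite checks it against an independent quaternion
(Horn) implementation to 10⁻⁹ Å. RMSF superposes all frames onto the mean
structure, iterated twice so mean and alignment are self-consistent. Note
that rigid-body fitting absorbs 6 of the 3N fluctuation degrees of
freedom: for an isotropic Gaussian of SD σ the per-atom RMSF is σ√3 only
up to a factor √(1 − 6/(3N)).

The RDF normalizes pair counts by n_A · n_frames · ρ_B · 4πr²dr with
ρ_B = n_B/volume. The enclosing volume is user-supplied and there is **no
minimum-image convention** — the synthetic trajectories are non-periodic,
which is a documented difference from periodic production MD. For water
radii drawn from a Gaussian shell p(r), the g(r) mode sits slightly below
the shell center because of the r² geometric factor. Hydration counts use
the minimum distance from a water oxygen to *any* ligand atom ("within
5 Å of the ligand"), not the centroid.

Frame clustering builds the full pairwise superposition-RMSD matrix and
merges clusters by average linkage until k remain (default 10,
configurable); ties are broken by the lowest member frame index, making
the merge sequence fully deterministic — it is validated against the
reference average-linkage implementation in scipy on exhaustively small
cases. Each cluster's representative is the frame with the smallest mean
RMSD to the other members.

## What the synthetic data do and do not show

The generators reproduce the *statistical and mechanistic structure* the
analyses assume — saturating first-order kinetics with additive read
noise, first-order microsomal decay with multiplicative (LC-MS-like)
noise, transport consistent with the permeability equation, trajectories
with Gaussian atomic fluctuation, random rigid frame motions (uniform
quaternion rotations plus translations) and known radial water densities.
They do not emulate photobleaching or drift, plate edge effects,
stochastic single-molecule kinetics, explicit DNA or force-field
energetics, or periodic solvent. Passing the recovery tests therefore
demonstrates correctness of the estimators under their stated assumptions,
not robustness to instrument artifacts absent from the generator.

## Problem sizes

The acceptance script uses 100 simulated plates for AC50 recovery, 100
random 10-atom point sets for the superposition cross-check, 600 frames ×
2000 waters for the ideal-gas RDF calibration, 2000 frames for the RMSF
closed form, and 50 random ≤8-frame trajectories for the clustering
oracle — sizes at which every Monte-Carlo figure is stable to well within
the tolerances it is compared at, while the whole script runs in seconds.
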