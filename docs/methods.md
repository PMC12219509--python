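# Methods

This note documents the models, parameter choices, numerical
decisions, and known limitations of the package, in the order of the
analysis stages.

## Thermodynamic conventions

All free energies are in kcal/mol with R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹.
Three default temperatures recur and are exposed as contexts:

| context | T | RT (kcal/mol) | used for |
|---|---|---|---|
| room | 297.65 K (24.5 °C) | 0.5914 | steric trapping, cooperativity cutoffs |
| simulation | 310 K | 0.6160 | amphiphile solvation free energies |
| denaturation | 310.15 K (37 °C) | 0.6163 | three-state GdnHCl titrations |

Both the room and simulation RT round to the 0.6 kcal/mol "thermal
energy" commonly quoted for the cooperativity cutoffs; classification
accepts either the exact context RT or the rounded 0.6 via the `rt`
override.

ΔG°_N−D is the denatured→native free-energy change and is negative for
a stable protein; "stability" is −ΔG°_N−D.

## Steric-trapping isotherms

**First binding** uses the exact single-site mass-balance root
(quadratic tight-binding form), valid when the ligand is not in vast
excess over the protein. A brute-force equilibrium solver
(`single_site_bound_fraction` solved from mass balance) is the oracle
in the tests; the closed form matches it to ≤1e−10 relative.

**Second binding** is hyperbolic in total [mSA] with midpoint
K_d,biotin·(1+1/K_D). Total mSA is used as free mSA (no depletion
correction): the assay runs µM protein against tens of µM mSA, so
depletion is at the percent level and far below fitting noise. The
[mSA] = 0 point evaluates to the F₀ plateau analytically rather than
dividing by zero.

**Competition** is implemented exactly as published, including a
discriminant (`+4·P_T·[mSA]·K_u/K_l`) that does not follow from the
exact coupled two-ligand equilibrium. An exact numerical solver
(`competition_equilibrium_fraction`, bracketed root on free protein)
ships as a diagnostic; `compare_competition_to_equilibrium` reports
the deviation of the published form (tens of percent of the dynamic
range in unfavourable regimes) and nothing is silently corrected.
Ratio estimates from the published form should therefore be read as
operational parameters of that form, not exact equilibrium constants.

**Fitting.** All isotherm fits are unweighted least squares via
lmfit's Levenberg–Marquardt. Positivity-constrained scale parameters
(K_d,biotin, K_D, the affinity ratio) are fitted as natural
logarithms, which both enforces positivity structurally and makes the
ΔG standard error exact: se(ΔG) = RT·se(ln K_D) with no delta-method
approximation error. Initial guesses come from the data extremes
(plateaus) and the half-transition point. The fit residual evaluates
the midpoint shift directly from ln K_D so that exploratory steps
toward K_D → 0 cannot underflow. Asymptotic standard errors are the
usual curvature estimates; a refit started from a solution reproduces
it (fixed-point property, tested).

## Cooperativity profiling

ΔΔΔG = ΔΔG^N − ΔΔG^C with quadrature-combined standard errors. The
five-way classification uses the printed interval scheme: the
cooperative class is the closed interval [−RT, +RT]; moderate classes
are half-open outward, (RT, 2RT] and [−2RT, −RT); localized classes
are the open tails. Every finite value maps to exactly one label
(property-tested), and labels are stable under ±1e−12 perturbation
except exactly at the cutoffs. The narrow scheme halves both cutoffs.
Classification is reported as a hard label with the SE alongside; no
probabilistic softening near the cutoffs is attempted because none is
defined for the assay.

Burial: f_ASA = 0 → buried, 0 < f_ASA ≤ 0.1 → partially buried,
f_ASA > 0.1 → exposed. Rows with missing f_ASA are excluded from
burial-stratified analyses with a logged count.

Chow's test compares two regressions with k = 2 coefficients each:
F = [(S_C − (S₁+S₂))/k] / [(S₁+S₂)/(N₁+N₂−2k)], with the upper-tail
F(k, N₁+N₂−2k) p-value and no multiple-testing correction. Perfectly
collinear groups (S₁+S₂ = 0) are reported as a degenerate flag with
NaN statistics, not an arbitrary number. Monte-Carlo calibration (2000
null replicates) puts the empirical type-I error at α = 0.05 within
±0.02.

## Bicelle properties

q_eff divides total lipid by the detergent remaining in the bicellar
phase, using fixed aqueous-phase CBCs of 6.5 mM (DHPC) and 2.5 mM
(CHAPS); both are overridable. The ideal-mixing alternative computes
the CBC from the harmonic mole-fraction average of the monomer CMCs
(defaults: DMPC 6 nM, DHPC 15 mM, CHAPS 6 mM) and always lies between
the two CMCs.

Laurdan GP reads I₄₄₀ and I₄₉₀ by nearest sample within ±1 nm, falling
back to linear interpolation for coarser spectra.

The melting fit is r(T) = r₁(T)·logistic((T−T_m)/B) + r₂(T) with
linear baselines r_i = m_i·T + r_i,0; the steepness B is parameterized
directly in °C with a positivity bound, and the fit is unweighted
(per-point weights are not available for this assay). T_m is the
fitted inflection; a fit whose T_m lands outside the measured range is
treated as non-converged. At anisotropy noise σ = 0.005 over 100
seeds the T_m bias is well below 0.1 °C.

SAXS thickness uses L = 2π/Q on the second scattering maximum — the
standard Bragg-like relation for a repeat distance. (The alternative
"photon momentum" formulation sometimes quoted for this conversion is
dimensionally inconsistent with Q in Å⁻¹ and is not used.)

## Amphiphile solvation dynamics

The module consumes per-molecule contact-count tables (heavy atoms
within the protein's 5 Å contact shell is the expected upstream
convention) and coordinate tracks; it does not read trajectories.

**Events.** A contact event is a maximal run of q > 0 frames, merging
non-contact gaps no longer than a threshold. The threshold defaults to
0 and should be set to the bulk amphiphile conformational relaxation
time measured with `rmsd_lag` (time-lagged heavy-atom RMSD after
optimal superposition, averaged over bulk molecules and origins).

**Autocorrelation.** c(τ) averages q(t)·q(t+τ)/q(t)² over origins t
inside events with q(t) > 0 and t+τ inside the trace. Two deliberate
choices:

1. *Event scoping.* q is read as zero once the event containing t has
   ended, even if the molecule later rebinds — a rebinding is a new
   event. This makes c(τ) a per-event contact survival whose decay
   reflects the dissociation rate alone; without it the apparent decay
   would mix in the rebinding rate.
2. *Origin pooling.* All valid origins are weighted equally across
   events (the default). The alternative — averaging within each
   event first, then weighting events equally — under-weights origins
   in long events; for exponential dwell times its 1/e crossing sits
   near 0.43/k_off instead of 1/k_off, a ~2.3× systematic bias. The
   pooled estimator satisfies c(τ) = Σ(L−τ)⁺/ΣL → exp(−k_off·τ) and
   recovers 1/k_off within 10% at ≥500 events (tested). The
   event-weighted variant is available via `weighting="event"` as a
   diagnostic. The normalization q(t)q(t+τ)/q(t)² is asymmetric in t
   and is used as such (no symmetrization).

**Residence time** is the lag where c(τ) reaches 1/e, solved by
bracketed root finding on a fitted normalized triple-exponential
(default) or by linear interpolation on the raw curve (diagnostic). A
curve that never reaches 1/e in range returns a censored result
carrying the largest examined lag as a lower bound. The
triple-exponential fit bounds the log time-constants in a finite
window, restarts deterministically from shifted timescale guesses, and
accepts a solution whose RMS residual is below 0.05 even when the
optimizer's strict convergence flag trips on a degenerate amplitude
direction (common when the data are effectively mono-exponential and
the components collapse — which is itself a valid fit).

**Solvation free energy.** ΔG°_Solv = −RT·ln(τ_R,protein/τ_R,bulk) at
310 K, negative when amphiphiles prefer the protein surface. The
Boltzmann-ensemble form over per-site free energies and the
mean-residence-time form are algebraically identical (the exponentials
cancel exactly); both are implemented and their agreement is asserted
to 1e−12 relative over randomized site sets, guarding against any
future drift between the two code paths.

**RMSF** superposes frames onto their mean structure (two-pass
alignment) before computing per-atom fluctuations.

## Three-state chemical denaturation

Equilibrium constants are *unfolding* constants
K = exp(−(|ΔG°| − m[D])/RT), so K = 1 at the midpoint C_m = |ΔG°|/m
and K ≪ 1 in water for a stable protein, while the reported transition
free energies keep the folding sign convention (negative). Taking the
printed exponent together with negative ΔG° literally would make the
unfolded state dominate at [D] = 0, contradicting the fitted curves
and landscape; the magnitude reading is the physically consistent one
and is what the package implements.

The observable is evaluated through a softmax over log-populations
(log-sum-exp), so exponents of hundreds of RT cannot overflow;
populations sum to 1 to 1e−12. Folding- and unfolding-direction points
are pooled (reversibility after equilibration is assumed). m-values
can be fixed (the DC12PC workflow: m = 2.0 and 7.2 kcal mol⁻¹ M⁻¹ from
prior global fitting) or floated (DC11PC workflow). Baselines are
linear by default with a flat option for synthetic tests.

When m is fixed at values slightly different from those that generated
the data, the fitted ΔG° absorbs the mismatch roughly as
δΔG ≈ C_m·δm per transition — a known and quantifiable trade-off of
the fixed-m workflow, not hidden by the package.

Two failure modes raise a diagnostic instead of silently switching
models: a titration lying entirely above both fitted midpoints
(transitions unsampled), and an intermediate that never exceeds 5%
population across the fitted range (merged transitions; a two-state
treatment is suggested).

The landscape is reported relative to U: level(I) = ΔG°_I−U,
level(N) = ΔG°_N−I + ΔG°_I−U; the total is the N level. With the
DC12PC parameter set (−5.4, −26.4) the total is −31.8 kcal/mol and the
midpoints are 2.70 and 3.67 M. (Note the N–U total is the sum of both
transitions; a "total" labelled with the I–U subscript is read as the
N–U sum.) The printed bicelle-vs-micelle subdomain comparison
(−7.1/−6.8 vs −5.8/−4.7 kcal/mol) gives stabilizations of −1.3 and
−2.1 kcal/mol and a bicelle subdomain gap of 0.3 kcal/mol in
magnitude; the difference −7.1 − (−6.8) is itself negative, so the
package reports the magnitude where the sign convention of the quoted
gap is ambiguous.

## Synthetic data

The raw measurements (plate-reader fluorescence, anisotropy scans, MD
contact tables) are not publicly deposited, so seeded generators are
the canonical test inputs; the printed experimental parameter values
serve as default ground truths. All generators draw from
`numpy.random.default_rng(seed)` and are bit-reproducible; the seed,
design and truth are embedded in the returned metadata and written to
YAML sidecars.

Noise is additive, independent, homoscedastic Gaussian with default
σ = 1% of the signal's dynamic range (a typical plate-reader
repeatability); a Poisson option exists for contact counts. The
generators do **not** emulate instrument artifacts (photobleaching,
inner-filter effects, drift), heteroscedastic noise, baseline
curvature, or correlated replicate structure — passing parameter
recovery on them demonstrates estimator correctness and calibration,
not robustness to every pathology of real data.

Generator-specific designs:

* **Binding**: 12 points log-spaced over 0.01–60 µM total mSA (the
  experimental titration window). The default second-binding truth
  pairs K_D = 1e−4 with K_d,biotin = 2 nM so the attenuated phase's
  half-point (~20 µM) falls mid-window — mirroring the assay practice
  of screening mSA variants until the second phase is optimally
  placed. A half-point far outside the window leaves ln K_D
  practically unidentifiable at realistic noise.
* **Denaturation**: linear 1–5 M GdnHCl, DC12PC-like truth, flags
  midpoints outside the range.
* **Melting**: 3.0–42.5 °C, truth T_m = 24 °C, B = 1.5 °C.
* **Contacts**: per-molecule alternating exponential dwells
  (k_on default 1/100 ns⁻¹ — a molecule that leaves the shell is
  usually replaced rather than returning; k_off sets the residence
  time under study), discretized to 0.5 ns frames. Closure runs use
  60–500 molecules × 2000–3000 ns, giving ~900 events for the τ_R
  closure and ~19000 events for the ΔG°_Solv ratio closure; these
  sizes put the Monte-Carlo error comfortably inside the 10% / 0.05
  kcal/mol tolerances.
* **Mutant panels**: ΔΔG^N uniform on 0–3 kcal/mol, ΔΔG^C from a
  prescribed slope plus noise, burial classes sampled from a stated
  mix (default 40/30/30).

## Known limitations

* The published competition closed form is kept as the fitting model;
  its deviation from exact equilibrium is documented, not corrected.
* Contact analysis assumes the upstream contact definition and frame
  interval are uniform across traces; it does not re-derive contacts
  from coordinates.
* `rmsd_lag` treats molecules independently (no cross-molecule
  exchange symmetry) and requires ≥3 atoms for a defined
  superposition.
* The three-state model assumes linear free-energy dependence on
  denaturant over the fitted range and linear baselines; no lipid
  partitioning correction is applied to the fitted ΔG° values.
* No global multi-curve fitting across variants; each titration is
  fitted independently.
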