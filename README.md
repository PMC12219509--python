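# memfold

Quantitative analysis machinery for membrane-protein folding
thermodynamics: steric-trapping binding isotherms, cooperativity
(ΔΔΔG) profiling, bicelle physical properties, amphiphile solvation
dynamics from MD contact data, and three-state chemical denaturation.

## Who this is for

Experimentalists and simulators studying how the lipid environment
shapes membrane-protein stability. The package turns the raw readouts
of that work — fluorescence binding titrations, double-mutant ΔΔG
panels, DPH anisotropy melting curves, Laurdan spectra, SAXS peak
positions, per-molecule contact-count time series, and GdnHCl folding
titrations — into folding free energies, residue-level cooperativity
calls, bilayer property estimates, residence times and solvation free
energies, and three-state free-energy landscapes.

## The models

**Steric trapping.** A doubly biotinylated protein binds a first
monovalent streptavidin (mSA) unhindered; a second mSA can bind only
when the native tertiary contacts between the tags transiently open.
The attenuated second binding phase follows

    F([mSA]) = (F∞ − F₀) / (1 + K_d,biotin·(1 + 1/K_D)/[mSA]) + F₀

whose midpoint shift encodes the denaturation constant K_D and hence
the folding free energy ΔG°_N−D = −RT·ln(1/K_D) (negative for a stable
protein). First-binding (quadratic tight-binding) and competition
isotherms determine K_d,biotin.

**Cooperativity.** For each mutation measured against both subdomain
biotin pairs, ΔΔΔG = ΔΔG^N − ΔΔG^C classifies the residue as
cooperative (|ΔΔΔG| ≤ RT), moderately localized (RT < |ΔΔΔG| ≤ 2RT) or
localized (|ΔΔΔG| > 2RT) in either subdomain. Slope differences
between burial classes are tested with Chow's F statistic.

**Bicelle properties.** q_eff = [lipid]/([detergent] − CBC), the
ideal-mixing CBC from the harmonic CMC average, Laurdan
GP = (I₄₄₀ − I₄₉₀)/(I₄₄₀ + I₄₉₀), the gel–fluid T_m from a sigmoid
anisotropy fit with sloped baselines, and bilayer thickness L = 2π/Q
from the second SAXS maximum.

**Solvation dynamics.** Contact events from per-molecule heavy-atom
contact counts; contact autocorrelation c(τ); residence time τ_R at
the 1/e decay (via a triple-exponential fit); and

    ΔG°_Solv = −RT·ln(τ_R,protein / τ_R,bulk)

comparing how long amphiphiles linger on the protein versus on each
other.

**Three-state folding.** Y_obs is the population-weighted average of
three linear baselines with unfolding constants
K = exp(−(|ΔG°| − m[D])/RT); the landscape is reported relative to the
unfolded state.

## Worked example

```python
import numpy as np
from memfold import ROOM_CONTEXT, steric_binding as sb, synthetic as syn

# simulate a second-binding isotherm for a protein with dG = -7.1 kcal/mol
kd = sb.kd_from_dg(-7.1, ROOM_CONTEXT)
spec = syn.SyntheticSpec(seed=1, noise_sigma=0.009,
                         truth={"k_denat": kd, "kd_biotin": 2e-3})
titration, meta = syn.gen_binding_titration(spec, model="second")

fit = sb.fit_binding_model("second", titration,
                           fixed={"kd_biotin": 2e-3}, context=ROOM_CONTEXT)
print(f"dG_N-D = {fit.dg_nd:.2f} +/- {fit.standard_errors['dg_nd']:.2f} kcal/mol")
```

prints

```
dG_N-D = -6.95 +/- 0.52 kcal/mol
```

the folding free energy recovered from the noisy isotherm: within one
standard error of the −7.1 kcal/mol used to generate it. The same
workflow runs from the shell:

```sh
memfold simulate --kind binding --model second --seed 1 --out sim.csv
memfold fit-binding --model second --data sim.csv --kd-biotin 0.002 --out fit.csv
memfold report fit.csv
```

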