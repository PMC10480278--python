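# phspec

Analysis toolkit for the reaction specificity of glycoside
transferases: polyprotic activity–pH models, hydrolysis vs.
transglycosylation kinetics, and conformational-ensemble analytics.

Retaining glycoside hydrolases and transglycosidases share a catalytic
machinery but partition the glycosyl-enzyme intermediate differently:
hydrolases transfer the glycosyl moiety to water (H), transglycosidases
to a sugar acceptor such as maltose (T). Engineering studies on a
thermophilic 4-α-glucanotransferase probe this balance by mutating the
domain-B lid loop and comparing variants through three quantitative
lenses, all implemented here:

1. **Activity–pH profiles.** The enzyme is modelled as a linear chain of
   `n` stepwise deprotonations with `n + 1` species, each carrying a
   relative activity weight `w_j`; observed activity at a given pH is
   the population-weighted mean

       %A(pH) = Σ_j w_j 10^(Σ_{i≤j}(pH − pKa_i)) / Σ_j 10^(Σ_{i≤j}(pH − pKa_i))

   The classic bell `1/(1 + 10^(pKa1−pH) + 10^(pH−pKa2))` and the
   four-pKa/three-active-species generalisation are special cases.
   `phspec.fitting` fits these by multi-start constrained least
   squares with runs-test residual diagnostics, AICc model comparison
   and bootstrap intervals.

2. **H/T specificity.** `phspec.kinetics` reduces iodine–starch (A620)
   and DNS (A540) assay readings to specific activities, fits
   Michaelis–Menten acceptor kinetics `v = Vmax·S/(Km+S)`, and computes
   `H/T = H / Vmax_T`, its fold-change versus a reference variant, and
   `ΔΔG‡ = RT ln(Vmax_ref/Vmax_var)` at the 70 °C assay temperature.

3. **Ensemble analytics.** `phspec.ensemble` provides Kabsch
   superposition, RMSD series, windowed per-residue RMSF, greedy
   neighbour-count (GROMOS) clustering at a 2 Å cutoff, distance-only
   hydrogen-bond (3.4 Å, N/O) and carbon-contact (6 Å) counters, and
   Gaussian-mixture/BIC decomposition of per-frame pKa series into
   populations — operating on multi-model PDB ensembles and CSV pKa
   tables.

`phspec.synth` generates seeded synthetic versions of every input
(profiles, kinetics, two-state coordinate ensembles, Markov-switching
pKa series) with known ground truth for recovery testing.

## Worked example

Fit acceptor kinetics for a loop-truncated variant, compare its
specificity with the wild type, and ask whether a noisy wild-type pH
profile needs two or four pKas:

```python
import numpy as np
from phspec import (ProtonationScheme, ProfileModel, fit_profile,
                    compare_models)
from phspec.kinetics import (SpecificityResult, compute_specificity,
                             ht_increment, ddg_transition_state)
from phspec.synth import gen_kinetics, gen_profile

kin = gen_kinetics(615.0, 4.7, [1.2, 2.5, 5.0, 10.0, 20.5])
res, fit = compute_specificity("truncated", kin, hydrolysis=3.09e-4)
wt = SpecificityResult("WT", 2.52e-4, 5723.0)
print(f"Vmax = {fit.vmax:.0f} U/(min mg), Km = {fit.km:.1f} mM")
print(f"H/T  = {res.ht:.2e}")
print(f"fold-change vs WT = {ht_increment(res, wt):.1f}")
print(f"ddG  = {ddg_transition_state(wt.t_vmax, res.t_vmax):.2f} kcal/mol")

wt4 = ProtonationScheme([4.4, 6.2, 7.6, 9.5], [0, 81.6, 106.8, 55.8, 0])
data = gen_profile(wt4, np.arange(3, 11.01, 0.25), noise_sd=3.0, seed=42)
fits = [fit_profile(data, ProfileModel.eq1()),
        fit_profile(data, ProfileModel.eq2())]
cmp = compare_models(fits)
print(cmp.table.round(3).to_string(index=False))
print("preferred:", cmp.preferred)
```

Output:

```
Vmax = 615 U/(min mg), Km = 4.7 mM
H/T  = 5.02e-07
fold-change vs WT = 11.4
ddG  = 1.52 kcal/mol
model  k     sse    r2  runs_p   aicc
  eq1  3 135.183 0.967   0.005 55.963
  eq2  7  18.410 0.995   0.187  2.741
preferred: eq2
```

The truncated variant's H/T ratio is eleven-fold the wild type's — the
loop suppresses hydrolysis — and the ~1.5 kcal/mol is the
transition-state stabilisation lost with the ten-fold Vmax drop. In the
profile comparison, the two-pKa bell leaves sign-clustered residuals
(runs p ≈ 0.005) while the four-pKa model passes the randomness filter
and wins on AICc, recovering the generating pKas.

A thin CLI mirrors the library:

```sh
phspec simulate-profile --pkas 4.4,6.2,7.6,9.5 \
    --weights 0,81.6,106.8,55.8,0 --out curve.csv
phspec fit-profile --model eq2 --data curve.csv --out fit.csv
phspec synth-ensemble --frames 500 --seed 1 --out ens.pdb
phspec ensemble-cluster --pdb ens.pdb --cutoff 2.0 --out clusters.csv
```

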