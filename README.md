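# blastabc

Compartment models of cell-lineage allocation in the pre-implantation mouse
embryo (E2.5 → E4.5) and of embryonic-stem-cell (ESC) chimera formation,
with likelihood-free Bayesian inference.  Built for developmental/systems
biologists who want to ask, from cell-count data alone: which population
feedbacks are sufficient to time the two blastocyst fate decisions, and how
do injected donor ESCs displace host cells from the epiblast?

## The model

Host compartments: blastomeres `B`, trophectoderm `T`, unspecified inner
cell mass `C`, primitive endoderm `P`, epiblast `E`; all grow at net rate
α.  Blastomeres differentiate at rate β with bias ρ toward the ICM;
FGF4-driven PrE specification has per-capita rate η(C+E)^m and PrE-feedback
EPI specification ζP^l, with exponents l, m ∈ {0,1,2}:

    dB/dt = αB − βB
    dT/dt = αT + (1−ρ)βB
    dC/dt = αC + ρβB − η(C+E)^m C − ζP^l C
    dP/dt = αP + η(C+E)^m C
    dE/dt = αE + ζP^l C

Chimera variants (F, GF, FC, GFC) add donor ESC compartments `D⁺`
(Fgf4+/+) or `D⁻` (Fgf4−/−) growing at rate α_D, FGF4 induction from D⁺
(η(C+E+D⁺)^m), and crowding displacement ρ_eff = ρ₀/(1 + a(D⁺+D⁻)^n).

Because the data are time-implicit snapshots, fitting happens in state
space through a three-term summary statistic
S = Σₙ minₜ Σᵢ (Xᵢ(t)−xᵢ⁽ⁿ⁾)² + Σᵢ (maxₜXᵢ − maxₙxᵢ⁽ⁿ⁾)² + B(48)² + C(48)²,
with ABC-MCMC for posteriors and rejection-ABC acceptance-rate ratios for
Bayes factors.  An exact Gillespie simulator of the same reaction networks
validates the mean-field fits against small-population noise.  See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from blastabc import BaseParams, solve, asymptotic_te_fraction

# four doublings: 8-cell morula, 12 h doubling time, nothing else active
growth = BaseParams(alpha=np.log(2)/12, beta=0, rho=0.35,
                    zeta=0, l=0, eta=0, m=0)
print(solve(growth, t_max=48.0).final_state.total)   # 127.99999...

# lineage split with specification off: TE fraction -> 1 - rho
split = BaseParams(alpha=0.06, beta=0.25, rho=0.35, zeta=0, l=0, eta=0, m=0)
print(100 * asymptotic_te_fraction(split))           # 65.0
```

The numbered drivers under `analysis/` run the full pipeline on synthetic
data and write tables to `results/`:

```
01_simulate_models.py        base + all four chimera variants, endpoint tables
02_generate_synthetic_data.py  cross-sectional (60 embryos) + chimera panel (5×10)
03_fit_base_model.py         ABC-MCMC over all seven base parameters
04_model_selection.py        rejection-ABC exponent selection and Bayes factor
05_fit_chimera_model.py      ABC-MCMC over (α_D, a, n); GFC vs FC comparison
06_chimera_analysis.py       composition, Hi/Lo k-means, model overlays
07_stochastic_validation.py  Gillespie ensembles vs ODE endpoints
```

Example output (`03` then `05`, seed 123): the base fit recovers
`alpha: 0.0564` against a generating 0.06/h, `rho: 0.294` against 0.35 and
puts both feedback exponents at the generating `l = m = 2`; the chimera fit
recovers `alpha_D: 0.0197` against 0.02/h, and the FC variant (donor growth
pinned to the host rate) produces no acceptances in 6,000 prior draws, i.e.
a GFC/FC Bayes factor above ~47 — crowding plus differential growth is
decisively preferred.  `04` puts the posterior mode of both feedback
exponents at 2 (`l: {0: 83, 1: 98, 2: 119}`, `m: {0: 72, 1: 91, 2: 137}`),
and `06` classifies the injected embryos into Hi/Lo chimerism groups at
k = 2 with mean silhouette 0.68.

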