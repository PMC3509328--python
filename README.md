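# cfcsim

Stochastic simulation of thin-filament regulation: a continuous flexible
tropomyosin–troponin chain gating myosin-S1 binding to actin.

## The problem

Striated-muscle contraction is switched on and off by calcium through the
tropomyosin–troponin (Tm–Tn) complex that winds along each strand of the
actin filament. Classical models treat each Tm as a rigid unit covering
seven actin monomers with two or three discrete azimuthal positions
(blocked / closed / open). But adjacent tropomyosins overlap end to end, so
the assembly behaves as one **continuous flexible chain (CFC)**: an elastic
beam confined in an azimuthal potential well on the actin surface, whose
thermal wiggling — not discrete unit flips — sets how often a myosin head
finds its binding site uncovered. Cooperativity then emerges naturally:
every strongly bound myosin kinks the chain open over roughly twice the
chain's confined persistence length, inviting neighbours to bind.

`cfcsim` is for biophysicists who want to simulate and fit stopped-flow
myosin-binding transients on regulated actin with this chain model:
solution-kinetics people fitting calcium dependences, and modellers probing
how chain stiffness shapes cooperativity.

## Model

Chain energy for the angular displacement field φ(s) along one strand:

    E{φ} = ∫ [ κ/2 φ''(s)² + α/2 φ(s)² ] ds

with bending stiffness κ and confinement strength α. Between pinning
constraints the minimiser obeys (d⁴/ds⁴ + 4ξ⁴)φ = 0, ξ = (α/4κ)^¼, so
perturbations decay over the confined persistence length 1/ξ ≈ 22 nm. The
free chain fluctuates with SD σₒ = (k_BT/8κξ³)^½ ≈ 29.7°. Bound TnI pins
the chain at φ₋ = −25° (blocked); strongly bound myosin-S1 pins it at
φ₊ = +10° (open).

Each actin site's kinetics are gated by the time fraction the fluctuating
chain spends past the relevant angle, a Gaussian tail weight such as
r_M1 = ½ erfc[(φₒ − φ̄ᵢ)/(√2 σᵢ)] for weak binding. Myosin attaches weakly
and then isomerises to the strong (R) state — the state that quenches
pyrene fluorescence — while TnI detaches at a rate k₋I set only by calcium
and rebinds at a chain-weighted rate. A fixed-timestep Monte Carlo evolves
ensembles of 700-monomer strands (TnI on every seventh monomer from the
third), with ensemble-wide myosin depletion [M] = [M_tot] − f[A_tot] and an
empirical crowding factor δ = 1 − 0.82 f on weak binding.

The single calcium-dependent parameter is fitted per calcium level as
K_B = k₋I / k_I° = 1/K_I; its sigmoidal dependence on pCa is summarised by
a Hill fit.

## Worked example

```python
import numpy as np
from cfcsim import SimConfig, RateConstants, run_transient, derived_defaults

p = derived_defaults()   # kappa -> sigma_o -> xi -> alpha derivation chain
print(f"1/xi = {p.inv_xi:.1f} nm, sigma_o = {p.sigma_o_deg:.1f} deg, "
      f"alpha = {p.alpha:.3f} pN")

cfg = SimConfig(A_tot=0.5e-6, M_tot=5.0e-6,   # excess myosin, [S1]/[A] = 10
                duration=0.2, n_strands=200, dt=1e-5, seed=1,
                burn_in=0.1, record_interval=1000)
for K_B in (0.12, 11.89):                     # low vs high calcium
    tr = run_transient(cfg, p, RateConstants().with_K_B(K_B))
    g = tr.frac_not_R
    t50 = np.interp(-(g[0] - 0.5 * (g[0] - g[-1])), -g, tr.t)
    print(f"K_B={K_B:6.2f}: not-R fraction {g[0]:.3f} -> {g[-1]:.3f} in 0.2 s, "
          f"t1/2 = {t50*1e3:.0f} ms, TnI bound at mix = {tr.frac_tni_bound[0]:.3f}")
```

prints

```
1/xi = 22.0 nm, sigma_o = 29.7 deg, alpha = 0.342 pN
K_B=  0.12: not-R fraction 1.000 -> 0.322 in 0.2 s, t1/2 = 84 ms, TnI bound at mix = 0.913
K_B= 11.89: not-R fraction 1.000 -> 0.082 in 0.2 s, t1/2 = 30 ms, TnI bound at mix = 0.078
```

The derived chain constants come out at the published values (persistence
length ≈ 22 nm, free-chain SD 29.7°, confinement ≈ 0.34 pN). `frac_not_R`
is the model's pyrene-fluorescence proxy — the fraction of actin sites not
strongly occupied. At low calcium (K_B = 0.12) most TnI is bound at mixing
time, the chain is pinned blocked, and binding is ~3× slower than at high
calcium (K_B = 11.89) where the filament saturates quickly.

Command-line equivalents:

```bash
cfcsim derive-params                       # Table of derived chain constants
cfcsim simulate --config run.cfg --out tr.tsv --snapshot
cfcsim fit --config run.cfg --data observed.txt --out fit.txt
```

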