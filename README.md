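# bonepkpd

Mechanistic pharmacokinetic–pharmacodynamic (PK-PD) simulation of
alendronate treatment of postmenopausal osteoporosis (PMO).

Alendronate, the most widely prescribed bisphosphonate, binds avidly to
bone mineral and inhibits osteoclasts. Clinical bone-density response is
site specific (the hip and lumbar spine gain density at different rates),
which systemic turnover-marker models cannot capture. `bonepkpd` couples a
compartmental PK model of alendronate disposition to a bone cell population
model (BCPM) of remodeling evaluated at a specific bone site, and predicts
serum concentration, urinary excretion, bone cell dynamics and the bone
density gain (BDG) over multi-year treatments. It is written for
researchers in computational bone biomechanics and pharmacometrics who want
a tested, scriptable simulator and calibration workbench.

## The model

**Pharmacokinetics.** Five linear compartmental topologies (`1c`, `2c`,
`3c-series`, `3c-parallel`, `4c`) describe oral/IV alendronate disposition
between gut, plasma (CC), non-calcified tissues (NCT), bone (BC) and an
inactive bone pool (IC), with renal elimination

    dAle_CC/dt = F·k_CC·Ale_Gut + k_el,BC·Ale_BC + k_el,NCT·Ale_NCT
                 − (k_BC + k_NCT + k_el,urine)·Ale_CC,
    [Ale_CC] = Ale_CC / V_c .

**Bone cell population model.** Pre-osteoblasts Ob_p, active osteoblasts
Ob_a, pre-osteoclasts Oc_p, active osteoclasts Oc_a and osteocytes evolve
under TGF-β, RANK–RANKL–OPG and sclerostin/Wnt gating (Hill
activator/repressor functions π = c/(c+K)), with mechanical feedback about
a strain-energy setpoint. Matrix balance is
`df_bm/dt = −k_res·Oc_a + k_form·Ob_a`; a tissue-age histogram tracks ash
fraction (primary + exponential secondary mineralization), giving the
apparent density ρ and `BDG% = (ρ(t) − ρ₀)/ρ₀ · 100` from treatment start.
PMO is induced as a sigmoidal rise in RANKL production.

**Coupling.** The bone-compartment drug splits algebraically into an
*active* surface fraction `g(f_bm) = (S_v/f_bm)·(f_bm0/S_v0)` (specific
surface S_v from a quintic porosity correlation) and a buried inactive
remainder; the active concentration can saturate. Resorption releases
drug at `k_el,BC = k_res·Oc_a`, the released drug lowers the resorbing
capacity, `k_res = k_res,nom/(1 + Π_rep·k_res,nom·Oc_a·[Ale_act])`, and
raises osteoclast apoptosis, `A = A_nom·(1 + Π_act·k_res·Oc_a·[Ale_act])`.
Six variants (`pkpd1`…`pkpd6`) toggle the two drug effects, the
active/inactive split and the saturation.

**Calibration.** Curve errors are mean-normalized RMSEs averaged over the
compared experiments (×100): three PK curves, or eight coupled-model terms
(four curve kinds × two bone sites). A seeded real-coded genetic algorithm
(tournament/SBX/polynomial mutation, optional simplex polish) fits bounded
constants, and a ±10% one-at-a-time sensitivity analysis tabulates the
per-curve impact of each fitted constant. Because the original clinical
curves are not deposited, a synthetic-data module generates clinical-style
curves from known constants for closed-loop testing.

## Worked example

```python
import numpy as np
from bonepkpd import (BCPMParams, PDParams, PKParams, simulate_treatment,
                      PKPD_VARIANT_FITS)

v = PKPD_VARIANT_FITS["pkpd1"]                  # published coupled fit
pk = PKParams(**v["pk"], k_el_BC=0.0)           # release is osteoclast-driven
pd = PDParams(pi_act=v["pi_act"], pi_rep=v["pi_rep"], f_sat=v["f_sat"])
bcpm = BCPMParams.default()

for fbm in (15.0, 25.0):                        # trabecular-rich vs denser site
    ts = simulate_treatment(fbm, "weekly70", "pkpd1", pk, bcpm, pd,
                            years_pre=19, years_treat=2)
    print(f"f_bm={fbm:.0f}%  final BDG = {ts.bdg_pct[-1]:.2f}%")
```

Output:

```
f_bm=15%  final BDG = 7.29%
f_bm=25%  final BDG = 4.15%
```

After 19 years of simulated PMO (≈18% density loss) and 2 years of 70 mg
weekly alendronate, the more porous site gains ≈7% apparent density and
the denser site ≈4%: more of the porous site's drug sits on the resorbable
surface, and its higher relative turnover leaves more mineralization
headroom. A 10 mg daily regimen reproduces the weekly trajectories to
within 0.04 percentage points.

The same simulations are available from the shell:

```bash
bonepkpd simulate-treatment --variant pkpd1 --fbm 15 --regimen weekly70 --out hip.csv
bonepkpd simulate-pk --topology 3c-parallel --regimen single70 --horizon 540 --out pk.csv
bonepkpd make-fixtures --seed 1 --out-dir fixtures/
bonepkpd fit --model 3c-parallel --data fixtures/ --bounds bounds.yaml --seed 42
```

## Layout

- `src/bonepkpd/pk.py` — compartmental PK models, dose schedules, solver
- `src/bonepkpd/bcpm.py` — bone cell population model, mineralization,
  mechanics, disease induction
- `src/bonepkpd/coupling.py` — active/inactive split, drug effects,
  variants, treatment simulation
- `src/bonepkpd/calibration.py` — error functionals, GA, OAT sensitivity
- `src/bonepkpd/synthetic.py`, `io.py`, `cli.py` — fixtures, files, CLI
- `docs/methods.md` — modeling assumptions, parameter provenance, limits
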