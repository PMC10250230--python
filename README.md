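# autoinhib

Kinetic modelling of **dynamic autoinhibition by D/E repeats during DNA
target search**.

Proteins such as HMGB1 carry long Asp/Glu repeats that fold back onto
their own DNA-binding surface, forming an autoinhibited state `X` in
equilibrium with the binding-competent state `P`
(`K_ai = [X]_eq/[P]_eq`). Autoinhibition weakens the apparent target
affinity by

    K_d,app = K_d,PT (1 + K_ai) / (1 + K_ai K_d,PT / K_d,XT)

yet in a nucleus crowded with decoy sites it can *accelerate* target
association: the autoinhibited protein resists sequestration by decoys
and converts to the tight complex only after engaging DNA
(induced fit, `X -> XT -> PT`). The package is for quantitative
biochemists and modellers who want to simulate this mechanism, fit the
corresponding stopped-flow/anisotropy observables, and generate
realistic synthetic data for pipeline validation.

It provides:

- an eight-species mass-action model (`P, X, T, D, PT, XT, PD, XD`)
  with every reverse rate derived from detailed balance
  (`kinetics`, `params`);
- equilibrium analysis, the closed-form `K_d,app`, the quasi-equilibrium
  acceleration estimate `k_app/k_app,o ≈ K_ai (k_on,XT/k_on,PT) φ
  (P_tot/Q + K_d,PT)/(P_tot/Q_o + K_d,PT)`, and parameter scans
  (`equilibrium`);
- fitting of mono-exponential relaxations, pseudo-first-order `k_a`
  slopes, and direct/competitive anisotropy titrations (`fitting`);
- a seeded synthetic-data generator for stopped-flow traces and
  titrations (`synth`), plus a CLI (`autoinhib simulate|scan|fit|synth`).

## Worked example

```python
import autoinhib as ai

p = ai.canonical_parameters(K_ai=50.0)     # 200 nM protein, 10 nM target,
                                           # 8 uM decoys, K_d,PT = 1 nM

print(ai.kd_apparent(50.0, 1.0, 1000.0))   # 48.57142857142857
rates = ai.kapp_ratio_numeric(p)
print(rates)
# {'k_app': 19.157294978199302, 'k_app_o': 1.312711186686022,
#  'ratio': 14.593685021287034}

fd = ai.pathway_fluxes(ai.integrate(p, t_end=10.0), p)
print(fd.share_if, fd.share_cs)
# 0.9775486509622525 0.02245134903774759
```

Read: autoinhibition at `K_ai = 50` weakens the apparent affinity
~49-fold, yet target association in the decoy-rich system is 14.6x
*faster* than the identical system without autoinhibition
(19.2 s⁻¹ vs 1.3 s⁻¹ apparent rates), and ~98% of the productive flux
into the protein–target complex flows through the induced-fit pathway —
the uninhibited protein barely reaches the target because decoys trap
it first.

From the shell, the same simulation:

```bash
autoinhib simulate --config params/canonical.yaml --out timecourse.csv
autoinhib synth --preset benchmark --seed 1 --out fixtures/
```

`timecourse.csv` holds both curves (`model` column: `autoinhibited` /
`reference`) plus a JSON sidecar with provenance; a full run config may
wrap the parameters under a `parameters:` key together with `solver`
and `scan` sections (see `tests/test_cli.py`).

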