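# Methods

## The model

Many nucleic-acid-binding proteins carry long runs of aspartate and
glutamate (D/E repeats). Because these acidic tails mimic the charge of
the DNA backbone, they can dock intramolecularly onto the protein's own
DNA-binding surface, producing a *dynamically autoinhibited* state. The
package models a protein that exchanges between an uninhibited
conformation `P` and an autoinhibited conformation `X`
(`K_ai = [X]_eq/[P]_eq`), in a solution containing a scarce
high-affinity target site `T` and a large pool of weak decoy sites `D`.
Both conformations can bind either ligand:

```
         P  <=>  X                    k_PX / k_XP
    P + T <=> PT        X + T <=> XT        XT <=> PT
    P + D <=> PD        X + D <=> XD        XD <=> PD
```

Eight species, seven reversible reactions, three conservation laws
(total protein, total target, total decoy). The autoinhibited state
binds weakly (`K_d,XT >> K_d,PT`, `K_d,XD >> K_d,PD`), which is exactly
what lets it pass over decoys; on the target it can convert in place to
the tight complex (`XT -> PT`, the induced-fit step).

Two target-binding pathways compete:

- **conformational selection** `X -> P -> PT`: convert first, then bind;
- **induced fit** `X -> XT -> PT`: bind weakly first, then convert.

`pathway_fluxes` integrates the two net edge fluxes into `PT`
(`J_CS = k_on,PT[P][T] − k_off,PT[PT]`,
`J_IF = k_XTPT[XT] − k_PTXT[PT]`) with the trapezoid rule on the solver
grid; their sum must equal the net `PT` formed (checked to 1e-4
relative). In the decoy-rich regime the induced-fit share is ~98%:
uninhibited protein is instantly captured by decoys, so almost all
productive target encounters happen in the autoinhibited form.

## Thermodynamic consistency

Users supply equilibrium constants plus the *forward* rates only
(`k_on` per complex, `k_XP`, `k_XTPT`, `k_XDPD`). Every reverse rate is
derived: `k_off,s = k_on,s · K_d,s`, `k_PX = k_XP · K_ai`,
`k_PTXT = k_XTPT · K_ai · K_d,PT/K_d,XT`, and the analogous decoy
relation. This guarantees detailed balance around both thermodynamic
cycles (`P–X–XT–PT` and `P–X–XD–PD`); `validate_cycle_closure` reports
the cycle products (1 within 1e-12 by construction) and marks cycles
degenerate when `K_ai = 0`. A direct consequence worth noting: holding
`k_XTPT` fixed while raising `K_ai` makes the back-conversion
`PT -> XT` faster, so strong autoinhibition destabilizes the final
complex — the model's affinity/speed trade-off is built into the rate
relations, not added by hand.

## Canonical parameter set

`params/canonical.yaml` (also `canonical_parameters()`): K_d,PT = 1 nM,
K_d,PD = 500 nM, K_d,XT = 1 uM, K_d,XD = 500 uM; all intrinsic
association rates 1e8 M^-1 s^-1; k_XP = k_XTPT = k_XDPD = 1e3 s^-1;
P_tot = 200 nM, T_tot = 10 nM, D_tot = 8000 nM; K_ai = 50 as the
working value (physiological estimates for this class of protein are
~10–100). Internally all concentrations are nM, times s, bimolecular
rates nM^-1 s^-1, so state magnitudes stay O(1)–O(1e4); unit conversion
happens only when reading configs. The four `k_on` are accepted
independently even though the canonical set makes them equal, so the
`k_on,XT/k_on,PT` factor of the acceleration formula can be exercised.
The decoy-branch conversion rate `k_XDPD` is likewise independent but
defaults equal to the others.

## Numerical choices

- **Integration**: `scipy.integrate.solve_ivp` with BDF and an analytic
  Jacobian; rtol 1e-8, atol 1e-12 nM. The network is stiff (rates span
  0.1 to 5e4 s^-1). Default output grid: 500 log-spaced points, which
  resolves the ms-scale transient and the slow tail at once; linear
  experiment-like grids are available as presets. Negative round-off
  concentrations are clipped at 10x atol, anything larger is an error;
  conservation is verified to 1e-6 relative at every output point.
- **Equilibrium**: damped fixed-point iteration on the exact free-species
  update maps, then a Newton polish in log space (positivity preserved);
  residuals of all conservation laws must reach 1e-9 relative, with
  long-time ODE integration as fallback. Zero totals are handled by
  excluding the species rather than by log-of-zero.
- **Mono-exponential fits**: `v(t) = v_inf + (v0−v_inf)e^(−k t)` via
  lmfit least squares. The rate is initialized by a 40-point log-grid
  search with the linear parameters profiled out exactly — a plain
  log-linearized guess is unstable once plateau noise dominates.
  An optional dead-time cut (default 2 ms; stopped-flow mixing
  artefact) discards leading points. Flat traces, non-convergence and
  rates whose 95% CI spans zero come back as flagged failures.
- **Titration fits**: direct titrations use the exact two-component
  quadratic (probe depletion respected; reduces to the hyperbola for
  trace probe); competitive titrations solve the exact three-component
  equilibrium per point by bracketed root finding on the free-protein
  conservation equation (monotone, so `brentq` on [0, P_tot] is
  guaranteed). The closed-form approximation sometimes used for this
  assay is deliberately not used. Because a competitor series rarely
  reaches the free-probe plateau, `fit_competitive` accepts a fixed
  `r_free`/`r_bound` (routinely measured separately); leaving them free
  is supported but can render K_d unidentifiable, which the fit flags.
- **Confidence intervals** are 95%, from the parameter covariance at the
  optimum; replicates are fitted individually and summarized as
  mean ± SEM.

## The acceleration estimate

In the regime `T_tot << P_tot << D_tot` with fast conformational
exchange, the ratio of apparent target-association rates with and
without autoinhibition is approximately

```
k_app/k_app,o ≈ K_ai · (k_on,XT/k_on,PT) · φ · (P_tot/Q + K_d,PT) / (P_tot/Q_o + K_d,PT)
```

with commitment factor `φ = k_XTPT/(k_XTPT + k_off,XT)` (probability
that an autoinhibited encounter converts rather than dissociates) and
binding polynomials `Q = 1 + K_ai + D_tot/K_d,PD + K_ai·D_tot/K_d,XD`,
`Q_o = 1 + D_tot/K_d,PD` — quasi-equilibrium partition functions over
the protein's free and decoy-bound states. Against the ODE ground truth
(`kapp_ratio_numeric`: integrate both systems, fit `[PT]/T_tot`
mono-exponentially) the formula agrees within ~18% for K_ai in 10–100
under the canonical constants; it *underestimates* at small K_ai, where
the direct `P + T` channel it neglects still matters, and the test
suite checks agreement only inside the validity regime.

One empirical note: over K_ai in [0.1, 1000] the measured
`k_app/k_app,o` rises monotonically (from 1 toward large values driven
by the shortening PT lifetime). The often-quoted "optimal K_ai ~10–100"
is a trade-off statement — beyond it the *equilibrium* target occupancy
collapses even though the rate ratio keeps growing — and the package
exposes both quantities (`scan` metrics `ratio_ode` and `pt_fraction`)
so the trade-off can be mapped directly.

## Synthetic data: what it emulates, what it does not

`synth` emulates the statistical structure of the motivating
experiments: 1:1 stopped-flow mixing (pre-mix totals halved), ~10–11 s
acquisitions at 20 ms ("slow") or 1 ms ("fast") intervals, 8–10
replicates, Gaussian anisotropy noise (sigma 0.005 by default, optional
sqrt(dt_ref/dt) inflation for short intervals), and direct/competitive
titrations from exact equilibria. Anisotropy is mapped linearly from
the bound-probe fraction between r_free = 0.05 and r_bound = 0.20
(typical fluorescein/TAMRA values; the sources plot but do not tabulate
plateaus). The bound fraction includes the transient `XT` complex — a
probe bound by either conformation tumbles slowly — with a toggle to
exclude it; intensity-weighted anisotropy addition, photobleaching,
inner-filter effects and instrument response are *not* modelled.
Passing recovery tests therefore demonstrates correctness of the
fitting machinery under the stated noise model, not robustness to every
instrumental artefact of real traces.

All randomness derives from one integer seed via
`numpy.random.SeedSequence.spawn`, giving independent, bit-reproducible
replicate streams.

## Problem sizes

Default runs integrate 8 ODEs on 500-point grids; a K_ai scan of the
rate ratio uses 9 log-spaced points (two integrations plus two fits
each); recovery studies use 8 stopped-flow replicates per system and
triplicate 12-point titrations. These sizes give stable medians while
keeping any analysis in seconds on one core.

## Known limitations

- Deterministic mass action only: no spatial diffusion, no stochastic
  (Gillespie) dynamics, no facilitated 1D sliding — decoy trapping is
  the only crowding effect represented.
- `K_ai` is an input; its salt dependence (counterion-condensation
  physics) is out of scope.
- The mono-exponential `k_app` is an *apparent* rate; the underlying
  relaxation is multi-exponential, and at parameter extremes (very fast
  conversion plus coarse sampling) the fitted value depends on the
  sampling window, exactly as it does in the instrument.
- Microscopic rate constants are not fitted to kinetic data; the
  package compares simulated and measured trends instead.
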