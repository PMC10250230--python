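"""Equilibrium solutions, apparent affinity, and the acceleration estimate.

Everything here works on the same eight-species scheme as
:mod:`autoinhib.kinetics` but at steady state: the complexes are in
equilibrium with the free species, so the whole state is determined by
the three free concentrations ([P], [T], [D]) and the conservation laws.

Two routes to the apparent association rate are provided:

* :func:`kapp_ratio_numeric` — integrate the rate equations with and
  without autoinhibition, fit each [PT]/T_tot time course with a single
  exponential, and take the ratio of the fitted rates.  This is the
  model's ground truth.
* :func:`acceleration_approx` — the closed-form quasi-equilibrium
  estimate

      k_app/k_app,o ≈ K_ai (k_on,XT/k_on,PT) φ (P_tot/Q + K_d,PT)
                                               / (P_tot/Q_o + K_d,PT)

  with commitment factor φ = k_XTPT/(k_XTPT + k_off,XT) and binding
  polynomials Q = 1 + K_ai + D_tot/K_d,PD + K_ai D_tot/K_d,XD and
  Q_o = 1 + D_tot/K_d,PD.  It is valid for T_tot << P_tot << D_tot with
  fast conformational exchange, and is exercised against the numeric
  route in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import fitting
from .kinetics import SPECIES, integrate
from .params import ModelParameters, make_uninhibited_reference, with_updates

__all__ = [
    "EquilibriumState",
    "AccelerationEstimate",
    "ScanResult",
    "EquilibriumError",
    "solve_equilibrium",
    "kd_apparent",
    "acceleration_approx",
    "kapp_ratio_numeric",
    "scan",
    "SCAN_AXES",
    "SCAN_METRICS",
]


class EquilibriumError(RuntimeError):
    """Equilibrium root-finding failed to reach the residual tolerance."""


@dataclass(frozen=True)
class EquilibriumState:
    """Long-time species concentrations and derived populations."""

    concentrations: dict[str, float]          # nM, all eight species
    bound_target_fraction: float              # ([PT]+[XT])/T_tot
    pt_fraction: float                        # [PT]/T_tot
    kd_app: float                             # nM, closed form
    residual: float                           # max relative conservation residual

    def __getitem__(self, species: str) -> float:
        return self.concentrations[species]


def kd_apparent(K_ai: float, K_d_PT: float, K_d_XT: float) -> float:
    """Apparent target dissociation constant of the two-state protein.

    K_d,app = K_d,PT (1 + K_ai) / (1 + K_ai K_d,PT/K_d,XT): autoinhibition
    dilutes the binding-competent population (numerator) but the weak
    residual affinity of the autoinhibited state caps the penalty at
    K_d,XT (K_ai -> inf limit).
    """
    if K_d_PT <= 0 or K_d_XT <= 0:
        raise ValueError("dissociation constants must be > 0")
    if K_ai < 0:
        raise ValueError("K_ai must be >= 0")
    return K_d_PT * (1.0 + K_ai) / (1.0 + K_ai * K_d_PT / K_d_XT)


def _free_to_state(P: float, T: float, D: float, p: ModelParameters) -> dict[str, float]:
    eq = p.equilibrium
    kai = eq.K_ai if p.autoinhibition_enabled else 0.0
    X = kai * P
    return {
        "P": P,
        "X": X,
        "T": T,
        "D": D,
        "PT": P * T / eq.K_d_PT,
        "XT": X * T / eq.K_d_XT,
        "PD": P * D / eq.K_d_PD,
        "XD": X * D / eq.K_d_XD,
    }


def _conservation_residual(state: dict[str, float], p: ModelParameters) -> float:
    tot = p.totals
    res = 0.0
    if tot.P_tot > 0:
        s = state["P"] + state["X"] + state["PT"] + state["XT"] + state["PD"] + state["XD"]
        res = max(res, abs(s - tot.P_tot) / tot.P_tot)
    if tot.T_tot > 0:
        s = state["T"] + state["PT"] + state["XT"]
        res = max(res, abs(s - tot.T_tot) / tot.T_tot)
    if tot.D_tot > 0:
        s = state["D"] + state["PD"] + state["XD"]
        res = max(res, abs(s - tot.D_tot) / tot.D_tot)
    return res


def _solve_free(p: ModelParameters) -> tuple[float, float, float]:
    """Free (P, T, D) at equilibrium.

    Damped fixed-point iteration on the exact update maps, then a Newton
    polish in log space over the components with non-zero totals.  The
    fixed point is a contraction for this scheme whenever the iteration
    is damped, and the log parameterization keeps the Newton step inside
    the physical orthant.
    """
    eq = p.equilibrium
    tot = p.totals
    kai = eq.K_ai if p.autoinhibition_enabled else 0.0

    def p_update(T: float, D: float) -> float:
        denom = (
            (1.0 + kai)
            + T / eq.K_d_PT + kai * T / eq.K_d_XT
            + D / eq.K_d_PD + kai * D / eq.K_d_XD
        )
        return tot.P_tot / denom

    def t_update(P: float) -> float:
        return tot.T_tot / (1.0 + P / eq.K_d_PT + kai * P / eq.K_d_XT)

    def d_update(P: float) -> float:
        return tot.D_tot / (1.0 + P / eq.K_d_PD + kai * P / eq.K_d_XD)

    T, D = tot.T_tot, tot.D_tot
    P = p_update(T, D)
    for _ in range(200):
        P_new = 0.5 * (P + p_update(T, D))
        T_new = 0.5 * (T + t_update(P_new))
        D_new = 0.5 * (D + d_update(P_new))
        shift = max(
            abs(P_new - P) / max(P_new, 1e-300),
            abs(T_new - T) / max(T_new, 1e-300) if tot.T_tot > 0 else 0.0,
            abs(D_new - D) / max(D_new, 1e-300) if tot.D_tot > 0 else 0.0,
        )
        P, T, D = P_new, T_new, D_new
        if shift < 1e-13:
            break

    # Newton polish on log concentrations of the active components
    active = [tot.P_tot > 0, tot.T_tot > 0, tot.D_tot > 0]
    if any(active):
        x0 = []
        if active[0]:
            x0.append(np.log(max(P, 1e-300)))
        if active[1]:
            x0.append(np.log(max(T, 1e-300)))
        if active[2]:
            x0.append(np.log(max(D, 1e-300)))

        def residuals(x: np.ndarray) -> np.ndarray:
            vals = list(np.clip(x, -700.0, 700.0))
            Pv = np.exp(vals.pop(0)) if active[0] else 0.0
            Tv = np.exp(vals.pop(0)) if active[1] else 0.0
            Dv = np.exp(vals.pop(0)) if active[2] else 0.0
            st = _free_to_state(Pv, Tv, Dv, p)
            out = []
            if active[0]:
                s = st["P"] + st["X"] + st["PT"] + st["XT"] + st["PD"] + st["XD"]
                out.append(s / tot.P_tot - 1.0)
            if active[1]:
                out.append((st["T"] + st["PT"] + st["XT"]) / tot.T_tot - 1.0)
            if active[2]:
                out.append((st["D"] + st["PD"] + st["XD"]) / tot.D_tot - 1.0)
            return np.array(out)

        sol = optimize.root(residuals, np.array(x0), method="hybr", tol=1e-14)
        if sol.success:
            vals = list(sol.x)
            if active[0]:
                P = float(np.exp(vals.pop(0)))
            if active[1]:
                T = float(np.exp(vals.pop(0)))
            if active[2]:
                D = float(np.exp(vals.pop(0)))

    if tot.P_tot == 0:
        P = 0.0
    if tot.T_tot == 0:
        T = 0.0
    if tot.D_tot == 0:
        D = 0.0
    return P, T, D


def solve_equilibrium(p: ModelParameters, *, residual_tol: float = 1e-9) -> EquilibriumState:
    """Solve the simultaneous equilibrium + mass-conservation equations.

    Falls back to long-time ODE integration if root finding does not
    reach ``residual_tol``; raises :class:`EquilibriumError` if neither
    route converges.
    """
    P, T, D = _solve_free(p)
    state = _free_to_state(P, T, D, p)
    residual = _conservation_residual(state, p)

    if residual > residual_tol:
        # fall back: relax the ODE system and polish once more
        tc = integrate(p, t_end=1e6, n_points=200)
        y = dict(zip(SPECIES, tc.y[-1]))
        P, T, D = y["P"], y["T"], y["D"]
        state = _free_to_state(P, T, D, p)
        residual = _conservation_residual(state, p)
        if residual > residual_tol:
            raise EquilibriumError(
                f"equilibrium residual {residual:.3e} above tolerance {residual_tol:.1e}"
            )

    t_tot = p.totals.T_tot
    bound = (state["PT"] + state["XT"]) / t_tot if t_tot > 0 else 0.0
    ptf = state["PT"] / t_tot if t_tot > 0 else 0.0
    kai = p.equilibrium.K_ai if p.autoinhibition_enabled else 0.0
    return EquilibriumState(
        concentrations=state,
        bound_target_fraction=bound,
        pt_fraction=ptf,
        kd_app=kd_apparent(kai, p.equilibrium.K_d_PT, p.equilibrium.K_d_XT),
        residual=residual,
    )


@dataclass(frozen=True)
class AccelerationEstimate:
    """Closed-form estimate of k_app/k_app,o with all of its factors."""

    ratio: float
    K_ai: float
    k_on_ratio: float        # k_on,XT / k_on,PT
    phi: float               # k_XTPT / (k_XTPT + k_off,XT), commitment factor
    Q: float                 # binding polynomial with autoinhibition
    Q_o: float               # binding polynomial without autoinhibition
    occupancy_term: float    # P_tot/Q + K_d,PT
    occupancy_term_o: float  # P_tot/Q_o + K_d,PT


def acceleration_approx(p: ModelParameters) -> AccelerationEstimate:
    """Evaluate the quasi-equilibrium acceleration formula for ``p``."""
    if not p.autoinhibition_enabled:
        raise ValueError("acceleration estimate requires autoinhibition enabled")
    eq, r, tot = p.equilibrium, p.rates, p.totals
    denom = r.k_XTPT + r.k_off_XT
    phi = r.k_XTPT / denom if denom > 0 else 0.0
    Q = 1.0 + eq.K_ai + tot.D_tot / eq.K_d_PD + eq.K_ai * tot.D_tot / eq.K_d_XD
    Q_o = 1.0 + tot.D_tot / eq.K_d_PD
    if tot.P_tot == 0 and eq.K_d_PT == 0:
        raise ZeroDivisionError("P_tot and K_d_PT cannot both be zero")
    occ = tot.P_tot / Q + eq.K_d_PT
    occ_o = tot.P_tot / Q_o + eq.K_d_PT
    k_on_ratio = r.k_on_XT / r.k_on_PT
    ratio = eq.K_ai * k_on_ratio * phi * occ / occ_o
    return AccelerationEstimate(
        ratio=ratio,
        K_ai=eq.K_ai,
        k_on_ratio=k_on_ratio,
        phi=phi,
        Q=Q,
        Q_o=Q_o,
        occupancy_term=occ,
        occupancy_term_o=occ_o,
    )


def kapp_ratio_numeric(
    p: ModelParameters,
    *,
    t_end: float = 10.0,
    n_points: int = 500,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> dict[str, float]:
    """Apparent rate constants with/without autoinhibition, from the ODE.

    Integrates ``p`` and its uninhibited reference, fits each
    [PT]/T_tot time course mono-exponentially (log-spaced sampling so
    both fast and slow relaxations are resolved) and returns
    ``{"k_app": ..., "k_app_o": ..., "ratio": ...}``.
    """
    results: dict[str, float] = {}
    for key, model in (("k_app", p), ("k_app_o", make_uninhibited_reference(p))):
        tc = integrate(model, t_end=t_end, n_points=n_points, rtol=rtol, atol=atol)
        fit = fitting.fit_monoexponential(tc.t, tc.pt_fraction, dead_time=0.0)
        if not fit.success:
            raise RuntimeError(f"mono-exponential fit failed for {key}: {fit.message}")
        results[key] = fit.k_app
    results["ratio"] = results["k_app"] / results["k_app_o"]
    return results


SCAN_AXES = ("K_ai", "D_tot", "K_d_PD", "k_XTPT", "P_tot")
SCAN_METRICS = (
    "kd_app",
    "pt_fraction",
    "bound_fraction",
    "k_app",
    "k_app_o",
    "ratio_ode",
    "ratio_approx",
)


@dataclass(frozen=True)
class ScanResult:
    """One scanned axis with per-grid-point metrics (tidy table)."""

    axis: str
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _apply_axis(p: ModelParameters, axis: str, value: float, co_scale_decoy_kd: bool) -> ModelParameters:
    if axis == "K_ai":
        return with_updates(p, equilibrium={"K_ai": value})
    if axis == "D_tot":
        return with_updates(p, totals={"D_tot": value})
    if axis == "P_tot":
        return with_updates(p, totals={"P_tot": value})
    if axis == "k_XTPT":
        return with_updates(p, forward={"k_XTPT": value})
    if axis == "K_d_PD":
        updates = {"K_d_PD": value}
        if co_scale_decoy_kd:
            ratio = p.equilibrium.K_d_XD / p.equilibrium.K_d_PD
            updates["K_d_XD"] = value * ratio
        return with_updates(p, equilibrium=updates)
    raise ValueError(f"unknown scan axis {axis!r}; valid axes: {SCAN_AXES}")


def scan(
    p: ModelParameters,
    axis: str,
    grid,
    metrics=SCAN_METRICS,
    *,
    co_scale_decoy_kd: bool = True,
    t_end: float = 10.0,
) -> ScanResult:
    """Evaluate metrics over a strictly monotone grid of one parameter.

    Scanning ``K_d_PD`` co-scales ``K_d_XD`` by default so the
    autoinhibition penalty on decoy binding keeps its fixed ratio.
    Kinetic metrics (k_app, k_app_o, ratios) trigger ODE integrations;
    equilibrium metrics are cheap.
    """
    if axis not in SCAN_AXES:
        raise ValueError(f"unknown scan axis {axis!r}; valid axes: {SCAN_AXES}")
    unknown = [m for m in metrics if m not in SCAN_METRICS]
    if unknown:
        raise ValueError(f"unknown metrics {unknown}; valid metrics: {SCAN_METRICS}")
    grid = np.asarray(grid, dtype=float)
    if grid.size and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    rows = []
    need_kinetics = any(m in metrics for m in ("k_app", "k_app_o", "ratio_ode"))
    for value in grid:
        pv = _apply_axis(p, axis, float(value), co_scale_decoy_kd)
        row: dict[str, float] = {axis: float(value)}
        if any(m in metrics for m in ("kd_app", "pt_fraction", "bound_fraction")):
            st = solve_equilibrium(pv)
            if "kd_app" in metrics:
                row["kd_app"] = st.kd_app
            if "pt_fraction" in metrics:
                row["pt_fraction"] = st.pt_fraction
            if "bound_fraction" in metrics:
                row["bound_fraction"] = st.bound_target_fraction
        if need_kinetics:
            rates = kapp_ratio_numeric(pv, t_end=t_end)
            for m in ("k_app", "k_app_o"):
                if m in metrics:
                    row[m] = rates[m]
            if "ratio_ode" in metrics:
                row["ratio_ode"] = rates["ratio"]
        if "ratio_approx" in metrics:
            row["ratio_approx"] = acceleration_approx(pv).ratio if pv.autoinhibition_enabled else float("nan")
        rows.append(row)

    columns = [axis] + [m for m in SCAN_METRICS if m in metrics]
    table = pd.DataFrame(rows, columns=columns if rows else columns)
    return ScanResult(axis=axis, table=table)
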