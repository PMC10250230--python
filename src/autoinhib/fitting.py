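"""Fitting procedures for the kinetic and titration observables.

Three families, mirroring how stopped-flow and anisotropy experiments
are analysed in practice:

* mono-exponential relaxation fits of time courses, yielding the
  apparent pseudo-first-order rate constant ``k_app``;
* weighted linear regression of ``k_app`` against total protein, whose
  slope is the apparent association rate constant ``k_a``;
* equilibrium binding fits of anisotropy titrations, direct (ligand
  depletion handled with the exact two-component quadratic) and
  competitive (exact three-component equilibrium solved numerically per
  point).

Fits that cannot succeed on the given data (flat traces, saturated
titrations, rate constants whose confidence interval spans zero) come
back as flagged failures rather than exceptions, so replicate batches
can be processed unattended.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from lmfit import Model
from scipy.optimize import brentq

__all__ = [
    "ExponentialFit",
    "LinearFit",
    "BindingFit",
    "fit_monoexponential",
    "fit_pseudo_first_order",
    "fit_direct_titration",
    "fit_competitive",
    "two_component_bound_fraction",
    "solve_competition_free_protein",
    "summarize_replicate_fits",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


# --------------------------------------------------------------------------
# equilibrium building blocks (shared with the synthetic generator)


def two_component_bound_fraction(p_tot, t_tot: float, kd: float):
    """Bound fraction of a probe at total protein ``p_tot`` (exact).

    Solves P + T <-> PT with ligand depletion:
    [PT] = ((P+T+Kd) - sqrt((P+T+Kd)^2 - 4 P T)) / 2, returned as
    [PT]/T_tot.  Vectorized over ``p_tot``.
    """
    p_tot = np.asarray(p_tot, dtype=float)
    if kd <= 0 or t_tot <= 0:
        raise ValueError("kd and t_tot must be > 0")
    b = p_tot + t_tot + kd
    pt = 0.5 * (b - np.sqrt(b * b - 4.0 * p_tot * t_tot))
    return pt / t_tot


def solve_competition_free_protein(
    p_tot: float, t_tot: float, c_tot: float, kd_t: float, kd_c: float
) -> float:
    """Free protein in the three-component competition equilibrium.

    Protein binds probe T (K_d = ``kd_t``) and competitor C
    (K_d = ``kd_c``) simultaneously; conservation of protein gives a
    single monotone equation for free [P], bracketed on [0, P_tot].
    """
    if p_tot < 0 or t_tot < 0 or c_tot < 0:
        raise ValueError("totals must be >= 0")
    if kd_t <= 0 or kd_c <= 0:
        raise ValueError("dissociation constants must be > 0")
    if p_tot == 0:
        return 0.0

    def g(pf: float) -> float:
        return pf + t_tot * pf / (pf + kd_t) + c_tot * pf / (pf + kd_c) - p_tot

    return brentq(g, 0.0, p_tot, xtol=1e-15, rtol=1e-14)


# --------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class ExponentialFit:
    """Mono-exponential relaxation fit v(t) = v_inf + (v0 - v_inf) e^(-k t)."""

    success: bool
    k_app: float = float("nan")            # s^-1
    amplitude: float = float("nan")        # v0 - v_inf
    v0: float = float("nan")
    plateau: float = float("nan")          # v_inf
    k_app_ci95: float = float("nan")       # 95% half-width
    amplitude_ci95: float = float("nan")
    residual_rms: float = float("nan")
    n_points: int = 0
    message: str = ""


@dataclass(frozen=True)
class LinearFit:
    """Weighted straight-line fit k_app = k_a * P_tot + b."""

    slope: float                  # nM^-1 s^-1
    intercept: float              # s^-1
    slope_ci95: float
    intercept_ci95: float
    r_squared: float
    n_points: int

    @property
    def slope_per_M(self) -> float:
        """Slope converted to the conventional M^-1 s^-1 reporting unit."""
        return self.slope * 1e9


@dataclass(frozen=True)
class BindingFit:
    """Equilibrium binding-isotherm fit of an anisotropy titration."""

    success: bool
    kd: float = float("nan")               # nM (competitor K_d for competitive fits)
    kd_ci95: float = float("nan")
    r_free: float = float("nan")
    r_bound: float = float("nan")
    r_free_ci95: float = float("nan")
    r_bound_ci95: float = float("nan")
    residual_rms: float = float("nan")
    n_points: int = 0
    probe_kd: float | None = None          # fixed probe K_d (competitive mode)
    message: str = ""


# --------------------------------------------------------------------------
# kinetic fits


def _ci(param) -> float:
    return _Z95 * param.stderr if param.stderr is not None else float("nan")


def fit_monoexponential(
    t,
    v,
    weights=None,
    *,
    dead_time: float = 0.002,
    min_amplitude: float = 1e-10,
) -> ExponentialFit:
    """Fit a single-exponential relaxation to a time course.

    Points earlier than ``dead_time`` seconds are discarded (stopped-flow
    mixing artefact); pass ``dead_time=0`` for simulated data.  Initial
    guesses come from the first/last values and a log-linearized slope.
    Returns a flagged failure (``success=False``) for flat traces,
    non-convergence, non-positive rates, or a rate CI spanning zero.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("t and v must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    mask = t >= dead_time
    t, v = t[mask], v[mask]
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)[mask]
    if t.size < 5:
        raise ValueError(f"need at least 5 points after dead-time cut, got {t.size}")

    v0_guess = float(v[0])
    vinf_guess = float(np.mean(v[-max(3, t.size // 20):]))
    amp_guess = v0_guess - vinf_guess
    if abs(amp_guess) < min_amplitude and np.ptp(v) < max(min_amplitude, 1e-6 * max(abs(vinf_guess), 1.0)):
        return ExponentialFit(success=False, n_points=t.size, message="no amplitude: trace is flat")

    # robust rate guess: coarse grid over k with the linear parameters
    # (offset, amplitude) profiled out exactly at each candidate
    span = t[-1] - t[0]
    dt_min = float(np.min(np.diff(t)))
    candidates = np.geomspace(1e-2 / span, 2.0 / dt_min, 40)
    best_sse, k_guess = np.inf, 1.0 / span
    for k in candidates:
        basis = np.column_stack([np.ones_like(t), np.exp(-k * t)])
        coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
        sse = float(np.sum((basis @ coef - v) ** 2))
        if sse < best_sse:
            best_sse, k_guess = sse, float(k)
            vinf_guess, amp_guess = float(coef[0]), float(coef[1])

    def model_fn(t, v_inf, amp, k):
        return v_inf + amp * np.exp(-k * t)

    model = Model(model_fn)
    pars = model.make_params(v_inf=vinf_guess, amp=amp_guess, k=k_guess)
    pars["k"].set(min=0.0)
    try:
        out = model.fit(v, pars, t=t, weights=w)
    except Exception as exc:  # lmfit raises on pathological inputs
        return ExponentialFit(success=False, n_points=t.size, message=f"fit error: {exc}")

    k = out.params["k"]
    amp = out.params["amp"]
    vinf = out.params["v_inf"]
    rms = float(np.sqrt(np.mean(out.residual**2)))
    k_ci = _ci(k)
    if not out.success:
        return ExponentialFit(success=False, n_points=t.size, message="optimizer did not converge")
    if k.value <= 0 or not np.isfinite(k.value):
        return ExponentialFit(success=False, n_points=t.size, message="non-positive rate")
    if np.isfinite(k_ci) and k_ci >= k.value:
        return ExponentialFit(
            success=False,
            k_app=float(k.value),
            k_app_ci95=k_ci,
            n_points=t.size,
            message="rate confidence interval spans zero",
        )
    return ExponentialFit(
        success=True,
        k_app=float(k.value),
        amplitude=float(amp.value),
        v0=float(vinf.value + amp.value),
        plateau=float(vinf.value),
        k_app_ci95=k_ci,
        amplitude_ci95=_ci(amp),
        residual_rms=rms,
        n_points=t.size,
    )


def fit_pseudo_first_order(p_tot, k_app, se=None) -> LinearFit:
    """Weighted linear regression of k_app on total protein concentration.

    In the pseudo-first-order regime (protein well below the decoy
    pool) k_app is linear in P_tot; the slope is the apparent
    association rate constant k_a.  Weights are 1/se^2 when standard
    errors are supplied; rescaling all ``se`` uniformly leaves the
    estimates unchanged.
    """
    x = np.asarray(p_tot, dtype=float)
    y = np.asarray(k_app, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct protein concentrations")
    weights = 1.0 if se is None else 1.0 / np.asarray(se, dtype=float) ** 2
    res = sm.WLS(y, sm.add_constant(x), weights=weights).fit()
    conf = res.conf_int(alpha=0.05)
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_ci95=float((conf[1][1] - conf[1][0]) / 2.0),
        intercept_ci95=float((conf[0][1] - conf[0][0]) / 2.0),
        r_squared=float(res.rsquared),
        n_points=int(x.size),
    )


# --------------------------------------------------------------------------
# titration fits


def _titration_fit(
    conc, r, model_fn, kd_guess, probe_kd=None, flat_span: float = 1e-3,
    fix_r_free: float | None = None, fix_r_bound: float | None = None,
) -> BindingFit:
    conc = np.asarray(conc, dtype=float)
    r = np.asarray(r, dtype=float)
    if conc.shape != r.shape or conc.ndim != 1:
        raise ValueError("concentration and anisotropy arrays must match")
    if conc.size < 5:
        raise ValueError(f"need at least 5 titration points, got {conc.size}")
    span = float(np.ptp(r))
    if span < flat_span:
        return BindingFit(
            success=False, n_points=conc.size, probe_kd=probe_kd,
            message="no transition: anisotropy span below resolution",
        )

    model = Model(model_fn)
    pars = model.make_params(
        kd=kd_guess, r_free=float(np.min(r)), r_bound=float(np.max(r))
    )
    pars["kd"].set(min=1e-12)
    if fix_r_free is not None:
        pars["r_free"].set(value=fix_r_free, vary=False)
    if fix_r_bound is not None:
        pars["r_bound"].set(value=fix_r_bound, vary=False)
    try:
        out = model.fit(r, pars, c=conc)
    except Exception as exc:
        return BindingFit(success=False, n_points=conc.size, probe_kd=probe_kd,
                          message=f"fit error: {exc}")
    kd = out.params["kd"]
    kd_ci = _ci(kd)
    if not out.success or not np.isfinite(kd.value):
        return BindingFit(success=False, n_points=conc.size, probe_kd=probe_kd,
                          message="optimizer did not converge")
    if np.isfinite(kd_ci) and kd_ci >= kd.value:
        return BindingFit(
            success=False, kd=float(kd.value), kd_ci95=kd_ci, n_points=conc.size,
            probe_kd=probe_kd, message="K_d unidentifiable: confidence interval spans zero",
        )
    return BindingFit(
        success=True,
        kd=float(kd.value),
        kd_ci95=kd_ci,
        r_free=float(out.params["r_free"].value),
        r_bound=float(out.params["r_bound"].value),
        r_free_ci95=_ci(out.params["r_free"]),
        r_bound_ci95=_ci(out.params["r_bound"]),
        residual_rms=float(np.sqrt(np.mean(out.residual**2))),
        n_points=conc.size,
        probe_kd=probe_kd,
    )


def fit_direct_titration(p_tot, anisotropy, probe_t_tot: float) -> BindingFit:
    """Fit K_d from a direct protein titration of a labeled probe.

    The bound fraction uses the exact two-component quadratic, so probe
    depletion at concentrations near ``probe_t_tot`` is handled; in the
    T_tot << K_d limit this reduces to the familiar hyperbola.
    """
    p_tot = np.asarray(p_tot, dtype=float)
    r = np.asarray(anisotropy, dtype=float)
    if probe_t_tot <= 0:
        raise ValueError("probe_t_tot must be > 0")

    def model_fn(c, kd, r_free, r_bound):
        f = two_component_bound_fraction(c, probe_t_tot, kd)
        return r_free + (r_bound - r_free) * f

    # half-transition guess from the midpoint crossing
    mid = 0.5 * (np.min(r) + np.max(r))
    above = np.nonzero(r >= mid)[0]
    kd_guess = float(p_tot[above[0]]) if above.size else float(np.median(p_tot))
    kd_guess = max(kd_guess, 1e-6)
    return _titration_fit(p_tot, r, model_fn, kd_guess)


def fit_competitive(
    c_tot, anisotropy, *, probe_kd: float, probe_t_tot: float, p_tot: float,
    r_free: float | None = None, r_bound: float | None = None,
) -> BindingFit:
    """Fit the competitor K_d from a competitive anisotropy titration.

    The probe K_d, probe concentration and (fixed) protein concentration
    are known; each competitor concentration is mapped to the probe
    bound fraction by solving the exact three-component competition
    equilibrium, and the competitor K_d minimizes the anisotropy
    residuals.

    A competitor series rarely reaches the free-probe plateau, which
    leaves the plateaus and K_d strongly correlated; pass ``r_free``
    (anisotropy of the probe alone, routinely measured) and/or
    ``r_bound`` to pin them, as is standard for this assay.
    """
    c = np.asarray(c_tot, dtype=float)
    r = np.asarray(anisotropy, dtype=float)
    if probe_kd <= 0 or probe_t_tot <= 0 or p_tot <= 0:
        raise ValueError("probe_kd, probe_t_tot and p_tot must be > 0")
    if c.size and np.all(c == 0):
        return BindingFit(
            success=False, n_points=c.size, probe_kd=probe_kd,
            message="competitor absent across the series",
        )

    def model_fn(c, kd, r_free, r_bound):
        f = np.array(
            [
                solve_competition_free_protein(p_tot, probe_t_tot, ci, probe_kd, kd)
                for ci in np.atleast_1d(c)
            ]
        )
        bound = f / (f + probe_kd)
        return r_free + (r_bound - r_free) * bound

    kd_guess = max(float(np.median(c[c > 0])) if np.any(c > 0) else probe_kd, 1e-6)
    return _titration_fit(c, r, model_fn, kd_guess, probe_kd=probe_kd,
                          fix_r_free=r_free, fix_r_bound=r_bound)


# --------------------------------------------------------------------------
# replicate summaries


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean +/- SEM over per-replicate fitted values."""

    mean: float
    sem: float
    n: int
    values: tuple = field(default_factory=tuple)


def summarize_replicate_fits(fits, attr: str = "k_app") -> ReplicateSummary:
    """Summarize successful per-replicate fits as mean +/- SEM."""
    values = [getattr(f, attr) for f in fits if f.success]
    if not values:
        raise ValueError("no successful fits to summarize")
    arr = np.asarray(values, dtype=float)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return ReplicateSummary(mean=float(arr.mean()), sem=sem, n=arr.size, values=tuple(values))
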