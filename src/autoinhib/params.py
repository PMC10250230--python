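"""Parameter model for the dynamic-autoinhibition target-search scheme.

A DNA-binding protein carrying a long D/E (Asp/Glu) repeat interconverts
between an uninhibited state ``P`` and an autoinhibited state ``X`` in
which the acidic tail docks onto the DNA-binding surface.  Either state
can bind the functional target site ``T`` or one of the abundant decoy
sites ``D``, giving the complexes ``PT``, ``XT``, ``PD`` and ``XD``.

Thermodynamics are specified by the autoinhibition constant
``K_ai = [X]_eq / [P]_eq`` and four dissociation constants; kinetics
additionally require the four bimolecular association rates and the
forward conformational rates.  Every reverse rate is derived from
detailed balance, so a rate set built through
:func:`derive_rate_constants` closes both thermodynamic cycles
(P-X-XT-PT and P-X-XD-PD) exactly.

Units: concentrations in nM, time in s, bimolecular rates in nM^-1 s^-1
(1e8 M^-1 s^-1 == 0.1 nM^-1 s^-1).  Unit conversion happens only at the
config-file boundary (:func:`load_parameters`).
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "EquilibriumSpec",
    "RateSpec",
    "SystemTotals",
    "ModelParameters",
    "CycleReport",
    "derive_rate_constants",
    "validate_cycle_closure",
    "make_uninhibited_reference",
    "with_updates",
    "canonical_parameters",
    "load_parameters",
    "save_parameters",
]

# complexes, used to look up k_on/k_off/K_d field names
_COMPLEXES = ("PT", "PD", "XT", "XD")

# concentration-unit factors to nM
_CONC_TO_NM = {"M": 1e9, "mM": 1e6, "uM": 1e3, "nM": 1.0, "pM": 1e-3}


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class EquilibriumSpec(_StrictModel):
    """Equilibrium constants of the scheme.

    ``K_ai`` is dimensionless; the four ``K_d`` are in nM.  The
    autoinhibited state is expected to bind more weakly than the
    uninhibited state (``K_d_PT < K_d_XT`` and ``K_d_PD < K_d_XD``);
    violating that only triggers a warning because the scheme itself
    stays well defined.
    """

    K_ai: float
    K_d_PT: float
    K_d_PD: float
    K_d_XT: float
    K_d_XD: float

    @field_validator("*")
    @classmethod
    def _finite(cls, v: float, info) -> float:
        _require_finite(info.field_name, v)
        return v

    @field_validator("K_ai")
    @classmethod
    def _kai_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"K_ai must be >= 0, got {v}")
        return v

    @field_validator("K_d_PT", "K_d_PD", "K_d_XT", "K_d_XD")
    @classmethod
    def _kd_positive(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    @model_validator(mode="after")
    def _warn_inverted_affinities(self) -> "EquilibriumSpec":
        if self.K_d_PT >= self.K_d_XT:
            warnings.warn(
                "K_d_PT >= K_d_XT: the autoinhibited state binds the target "
                "at least as tightly as the uninhibited state",
                stacklevel=2,
            )
        if self.K_d_PD >= self.K_d_XD:
            warnings.warn(
                "K_d_PD >= K_d_XD: the autoinhibited state binds decoys "
                "at least as tightly as the uninhibited state",
                stacklevel=2,
            )
        return self


class RateSpec(_StrictModel):
    """Complete rate set: association/dissociation for the four complexes
    and the conformational exchange rates of the free and bound protein."""

    k_on_PT: float
    k_on_PD: float
    k_on_XT: float
    k_on_XD: float
    k_off_PT: float
    k_off_PD: float
    k_off_XT: float
    k_off_XD: float
    k_XP: float
    k_PX: float
    k_XTPT: float
    k_PTXT: float
    k_XDPD: float
    k_PDXD: float

    @field_validator("*")
    @classmethod
    def _nonneg_finite(cls, v: float, info) -> float:
        _require_finite(info.field_name, v)
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v


class SystemTotals(_StrictModel):
    """Total (conserved) concentrations in nM."""

    P_tot: float
    T_tot: float
    D_tot: float

    @field_validator("*")
    @classmethod
    def _nonneg_finite(cls, v: float, info) -> float:
        _require_finite(info.field_name, v)
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v


class ModelParameters(_StrictModel):
    """Full parameterization of one simulated system.

    With ``autoinhibition_enabled=False`` the X-branch species (X, XT,
    XD) do not exist; the model reduces to plain two-ligand competition
    of P for target and decoys, and all X-related rates are ignored.
    """

    equilibrium: EquilibriumSpec
    rates: RateSpec
    totals: SystemTotals
    autoinhibition_enabled: bool = True

    def content_hash(self) -> str:
        """Stable short hash of the parameter content (provenance)."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class CycleReport:
    """Detailed-balance check for the two thermodynamic cycles.

    ``product`` is (reverse-rate product)/(forward-rate product) around
    P -> X -> X·L -> P·L -> P; it equals 1 for a thermodynamically
    consistent set.  A cycle with a zero rate on either branch is marked
    not applicable (``None``).
    """

    target_cycle: float | None
    decoy_cycle: float | None

    @property
    def max_deviation(self) -> float:
        devs = [abs(c - 1.0) for c in (self.target_cycle, self.decoy_cycle) if c is not None]
        return max(devs, default=0.0)


def derive_rate_constants(
    eq: EquilibriumSpec,
    *,
    k_on_PT: float,
    k_on_PD: float,
    k_on_XT: float,
    k_on_XD: float,
    k_XP: float,
    k_XTPT: float,
    k_XDPD: float,
) -> RateSpec:
    """Build the full, detailed-balance-consistent rate set.

    Reverse rates follow from the equilibrium constants:
    ``k_off_s = k_on_s * K_d_s`` for each complex ``s``,
    ``k_PX = k_XP * K_ai``,
    ``k_PTXT = k_XTPT * K_ai * K_d_PT / K_d_XT`` and
    ``k_PDXD = k_XDPD * K_ai * K_d_PD / K_d_XD``.
    """
    forward = {
        "k_on_PT": k_on_PT,
        "k_on_PD": k_on_PD,
        "k_on_XT": k_on_XT,
        "k_on_XD": k_on_XD,
        "k_XP": k_XP,
        "k_XTPT": k_XTPT,
        "k_XDPD": k_XDPD,
    }
    for name, value in forward.items():
        _require_finite(name, value)
        if value <= 0:
            raise ValueError(f"forward rate {name} must be > 0, got {value}")

    kd = {c: getattr(eq, f"K_d_{c}") for c in _COMPLEXES}
    return RateSpec(
        k_on_PT=k_on_PT,
        k_on_PD=k_on_PD,
        k_on_XT=k_on_XT,
        k_on_XD=k_on_XD,
        k_off_PT=k_on_PT * kd["PT"],
        k_off_PD=k_on_PD * kd["PD"],
        k_off_XT=k_on_XT * kd["XT"],
        k_off_XD=k_on_XD * kd["XD"],
        k_XP=k_XP,
        k_PX=k_XP * eq.K_ai,
        k_XTPT=k_XTPT,
        k_PTXT=k_XTPT * eq.K_ai * kd["PT"] / kd["XT"],
        k_XDPD=k_XDPD,
        k_PDXD=k_XDPD * eq.K_ai * kd["PD"] / kd["XD"],
    )


def _cycle_product(
    k_fwd: tuple[float, float, float, float], k_rev: tuple[float, float, float, float]
) -> float | None:
    fwd = math.prod(k_fwd)
    rev = math.prod(k_rev)
    if fwd == 0.0 or rev == 0.0:
        return None
    return rev / fwd


def validate_cycle_closure(rates: RateSpec, eq: EquilibriumSpec | None = None) -> CycleReport:
    """Report the detailed-balance products of both reaction cycles.

    The ligand concentration cancels around a cycle, so only rate
    constants enter.  Report-only: a deviation is returned, not raised.
    """
    r = rates
    target = _cycle_product(
        (r.k_PX, r.k_on_XT, r.k_XTPT, r.k_off_PT),
        (r.k_XP, r.k_off_XT, r.k_PTXT, r.k_on_PT),
    )
    decoy = _cycle_product(
        (r.k_PX, r.k_on_XD, r.k_XDPD, r.k_off_PD),
        (r.k_XP, r.k_off_XD, r.k_PDXD, r.k_on_PD),
    )
    return CycleReport(target_cycle=target, decoy_cycle=decoy)


def make_uninhibited_reference(p: ModelParameters) -> ModelParameters:
    """Reference system without autoinhibition (X, XT, XD do not exist).

    Keeps K_d_PT, K_d_PD, the P-state association rates and the totals;
    K_ai is set to 0 so the X branch carries zero flux even if evaluated.
    Idempotent.
    """
    eq = p.equilibrium.model_copy(update={"K_ai": 0.0})
    rates = p.rates.model_copy(update={"k_PX": 0.0, "k_PTXT": 0.0, "k_PDXD": 0.0})
    return ModelParameters(
        equilibrium=eq, rates=rates, totals=p.totals, autoinhibition_enabled=False
    )


def with_updates(
    p: ModelParameters,
    *,
    totals: Mapping[str, float] | None = None,
    equilibrium: Mapping[str, float] | None = None,
    forward: Mapping[str, float] | None = None,
) -> ModelParameters:
    """Copy ``p`` with some inputs changed, re-deriving all reverse rates.

    Changing e.g. ``K_ai`` through this function keeps the rate set on
    the detailed-balance manifold, which a raw field update would not.
    """
    eq = p.equilibrium.model_copy(update=dict(equilibrium or {}))
    fwd = {
        "k_on_PT": p.rates.k_on_PT,
        "k_on_PD": p.rates.k_on_PD,
        "k_on_XT": p.rates.k_on_XT,
        "k_on_XD": p.rates.k_on_XD,
        "k_XP": p.rates.k_XP,
        "k_XTPT": p.rates.k_XTPT,
        "k_XDPD": p.rates.k_XDPD,
    }
    fwd.update(dict(forward or {}))
    rates = derive_rate_constants(eq, **fwd)
    tot = p.totals.model_copy(update=dict(totals or {}))
    return ModelParameters(
        equilibrium=eq,
        rates=rates,
        totals=tot,
        autoinhibition_enabled=p.autoinhibition_enabled,
    )


def canonical_parameters(
    K_ai: float = 50.0,
    *,
    P_tot: float = 200.0,
    T_tot: float = 10.0,
    D_tot: float = 8000.0,
) -> ModelParameters:
    """The canonical HMGB1-like parameter set used throughout.

    K_d,PT = 1 nM, K_d,PD = 500 nM, K_d,XT = 1 uM, K_d,XD = 500 uM;
    all intrinsic association rates 1e8 M^-1 s^-1 (0.1 nM^-1 s^-1);
    forward conformational rates k_XP = k_XTPT = k_XDPD = 1e3 s^-1.
    Totals default to P_tot = 200 nM, T_tot = 10 nM, D_tot = 8000 nM.
    """
    eq = EquilibriumSpec(K_ai=K_ai, K_d_PT=1.0, K_d_PD=500.0, K_d_XT=1000.0, K_d_XD=5.0e5)
    rates = derive_rate_constants(
        eq,
        k_on_PT=0.1,
        k_on_PD=0.1,
        k_on_XT=0.1,
        k_on_XD=0.1,
        k_XP=1.0e3,
        k_XTPT=1.0e3,
        k_XDPD=1.0e3,
    )
    totals = SystemTotals(P_tot=P_tot, T_tot=T_tot, D_tot=D_tot)
    return ModelParameters(equilibrium=eq, rates=rates, totals=totals)


# --- config-file boundary -------------------------------------------------


def _conc_factor(unit: str) -> float:
    try:
        return _CONC_TO_NM[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(_CONC_TO_NM)}"
        ) from None


def parameters_from_dict(doc: Mapping[str, Any]) -> ModelParameters:
    """Build :class:`ModelParameters` from a plain config mapping.

    Expected keys: ``equilibrium`` (K_ai + the four K_d), ``forward_rates``
    (four k_on + three forward conformational rates), ``totals``, optional
    ``autoinhibition_enabled`` and optional ``units`` with
    ``concentration`` (M/mM/uM/nM/pM, default nM) and
    ``bimolecular_rate`` ("per_nM_per_s" or "per_M_per_s", default per_nM_per_s).
    """
    doc = dict(doc)
    units = dict(doc.pop("units", {}) or {})
    cf = _conc_factor(units.pop("concentration", "nM"))
    rate_unit = units.pop("bimolecular_rate", "per_nM_per_s")
    if units:
        raise ValueError(f"unknown unit keys: {sorted(units)}")
    if rate_unit == "per_nM_per_s":
        rf = 1.0
    elif rate_unit == "per_M_per_s":
        rf = 1e-9
    else:
        raise ValueError(
            f"unknown bimolecular_rate unit {rate_unit!r}; "
            "expected 'per_nM_per_s' or 'per_M_per_s'"
        )

    try:
        eq_doc = dict(doc.pop("equilibrium"))
        fwd_doc = dict(doc.pop("forward_rates"))
        tot_doc = dict(doc.pop("totals"))
    except KeyError as exc:
        raise ValueError(f"missing required config section: {exc.args[0]!r}") from None
    enabled = bool(doc.pop("autoinhibition_enabled", True))
    if doc:
        raise ValueError(f"unknown config keys: {sorted(doc)}")

    for key in ("K_d_PT", "K_d_PD", "K_d_XT", "K_d_XD"):
        if key in eq_doc:
            eq_doc[key] = eq_doc[key] * cf
    eq = EquilibriumSpec(**eq_doc)
    for key in ("k_on_PT", "k_on_PD", "k_on_XT", "k_on_XD"):
        if key in fwd_doc:
            fwd_doc[key] = fwd_doc[key] * rf
    rates = derive_rate_constants(eq, **fwd_doc)
    totals = SystemTotals(**{k: v * cf for k, v in tot_doc.items()})
    params = ModelParameters(
        equilibrium=eq, rates=rates, totals=totals, autoinhibition_enabled=enabled
    )
    return params if enabled else make_uninhibited_reference(params)


def load_parameters(path: str | Path) -> ModelParameters:
    """Load a YAML/JSON parameter config (see :func:`parameters_from_dict`)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValueError(f"parameter config {path} does not contain a mapping")
    return parameters_from_dict(doc)


def save_parameters(p: ModelParameters, path: str | Path) -> None:
    """Write the internal (nM, s) representation back to YAML."""
    doc = {
        "units": {"concentration": "nM", "bimolecular_rate": "per_nM_per_s"},
        "equilibrium": p.equilibrium.model_dump(),
        "forward_rates": {
            "k_on_PT": p.rates.k_on_PT,
            "k_on_PD": p.rates.k_on_PD,
            "k_on_XT": p.rates.k_on_XT,
            "k_on_XD": p.rates.k_on_XD,
            "k_XP": p.rates.k_XP,
            "k_XTPT": p.rates.k_XTPT,
            "k_XDPD": p.rates.k_XDPD,
        },
        "totals": p.totals.model_dump(),
        "autoinhibition_enabled": p.autoinhibition_enabled,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
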