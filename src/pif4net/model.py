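"""Core state, parameters and right-hand-side of the PIF4 autoinhibition network.

The model tracks six variables over diurnal time ``t`` (hours):

``B``
    photoactivated phytochrome B; produced only in light, lost by dark
    reversion/decay.
``E``
    ELF3 (evening complex); synthesised at an oscillatory, photoperiod-shaped
    rate and destabilised by COP1.
``C``
    COP1; produced at different rates in light and dark.
``P``
    PIF4 protein, the central variable.  Its transcription is repressed by
    ELF3 and -- only above a threshold concentration ``Pstar`` -- by PIF4
    itself (negative autoregulation with strength ``pself``).  COP1
    stabilises PIF4, photoactive phyB degrades it.
``F``
    GUS reporter driven by the PIF4 promoter; above the threshold the
    reporter gains a PIF4-linked production term damped by ``pFP``.
``G``
    hypocotyl length in mm; a monotone readout of PIF4-activated growth.

All molecular concentrations are in arbitrary units; time is in hours with
lights-on at diurnal phase 0.  Functions in this module are pure and
side-effect free; integration lives in :mod:`pif4net.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Union

from .errors import BranchViolationError, ConfigurationError, DomainError

__all__ = [
    "Schedule",
    "ParameterSet",
    "GenotypeSpec",
    "ModelState",
    "STATE_NAMES",
    "schedule_value",
    "elf3_production",
    "rhs",
    "steady_state_below_threshold",
]

#: order of the state vector used throughout the package
STATE_NAMES = ("B", "E", "C", "P", "F", "G")


@dataclass(frozen=True)
class Schedule:
    """Piecewise-linear diurnal schedule for an inhibition strength.

    The value descends linearly from ``max_day`` at phase 0 to ``min_val``
    at ``D1``, stays at ``min_val`` on ``(D1, D2]`` and ascends linearly to
    ``max_night`` at phase 24.  The cycle boundary carries a jump from
    ``max_night`` back to ``max_day``; the discontinuity coincides with
    lights-on.
    """

    max_day: float
    min_val: float
    max_night: float
    D1: float = 2.0
    D2: float = 6.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.D1 <= self.D2 <= 24.0):
            raise ConfigurationError(
                f"Schedule needs 0 <= D1 <= D2 <= 24, got D1={self.D1}, D2={self.D2}"
            )
        if self.min_val < 0 or self.max_day < self.min_val or self.max_night < self.min_val:
            raise ConfigurationError(
                "Schedule needs max_day, max_night >= min_val >= 0; got "
                f"max_day={self.max_day}, min_val={self.min_val}, max_night={self.max_night}"
            )


#: an inhibition strength may be a plain number or a diurnal schedule
Strength = Union[float, Schedule]


def schedule_value(t: float, sched: Strength) -> float:
    """Evaluate a scalar-or-:class:`Schedule` strength at time ``t`` (hours).

    Scalars are returned unchanged.  For schedules the diurnal phase
    ``t0 = t mod 24`` selects the piecewise-linear branch; ``t0 == 0``
    returns ``max_day`` (the next cycle has begun).
    """
    if not isinstance(sched, Schedule):
        return float(sched)
    t0 = math.fmod(t, 24.0)
    if t0 < 0.0:
        t0 += 24.0
    if t0 <= sched.D1:
        if sched.D1 == 0.0:
            return sched.max_day if t0 == 0.0 else sched.min_val
        return sched.max_day - (sched.max_day - sched.min_val) * t0 / sched.D1
    if t0 <= sched.D2:
        return sched.min_val
    return sched.min_val + (sched.max_night - sched.min_val) * (t0 - sched.D2) / (24.0 - sched.D2)


# fields that may take a different value at 27 degC
TEMPERATURE_DEPENDENT = ("pB", "kr", "pE1", "pE2", "pPE", "pCL", "k0", "Pstar", "pself")


@dataclass
class ParameterSet:
    """All rate constants, interaction strengths and thresholds of the network.

    Units: production rates conc/h (``pG`` mm/h), decay rates 1/h,
    interaction strengths 1/conc (``dEC``, ``dPB`` 1/(conc*h)),
    ``Pstar`` conc.  ``pself`` and ``pFP`` accept either a scalar or a
    :class:`Schedule` (time-varying autoinhibition).

    ``temperature_variants`` maps a temperature label (e.g. ``"22"``,
    ``"27"``) to overrides for the temperature-dependent subset
    (:data:`TEMPERATURE_DEPENDENT`).  :meth:`at_temperature` resolves them.
    """

    # phyB
    pB: float
    kr: float
    # ELF3
    pE1: float
    pE2: float
    alpha: float
    dEC: float
    dE: float
    # COP1
    pCL: float
    pCD: float
    dC: float
    # PIF4
    pP: float
    pPE: float
    pself: Strength
    dP: float
    kPC: float
    dPB: float
    Pstar: float
    # GUS reporter
    k0: float
    pF: float
    pFP: Strength
    dF: float
    # growth
    pG: float
    kG: float
    pGP: float
    pGE: float
    pGB: float
    temperature_variants: Mapping[str, Mapping[str, object]] = field(default_factory=dict)
    #: if True use (pG + kG*pGP*P) / (1 + pGE*E + pGB*B) for dG/dt instead of
    #: the default pG + kG*pGP*P / (1 + pGE*E + pGB*B)
    growth_grouping_shared_denominator: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "pB", "kr", "pE1", "pE2", "alpha", "dEC", "pCL", "pCD", "pP", "pPE",
            "kPC", "dPB", "k0", "pF", "pG", "kG", "pGP", "pGE", "pGB",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"parameter {name} must be >= 0")
        for name in ("dE", "dC", "dP", "dF"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"decay rate {name} must be > 0")
        if self.Pstar <= 0:
            raise ConfigurationError("Pstar must be > 0")
        if self.pE1 < self.pE2:
            raise ConfigurationError(
                "need pE1 >= pE2 >= 0 so the ELF3 production rate never goes negative"
            )
        for strength in (self.pself, self.pFP):
            if not isinstance(strength, Schedule) and strength < 0:
                raise ConfigurationError("pself and pFP must be >= 0")
        for label, overrides in self.temperature_variants.items():
            bad = set(overrides) - set(TEMPERATURE_DEPENDENT)
            if bad:
                raise ConfigurationError(
                    f"temperature variant {label!r} overrides non-temperature-dependent "
                    f"parameters: {sorted(bad)}"
                )

    def at_temperature(self, label: str | int | float) -> "ParameterSet":
        """Return a copy with the overrides for ``label`` applied.

        Raises :class:`ConfigurationError` if the label has no entry.
        """
        key = _canonical_label(label)
        variants = {_canonical_label(k): v for k, v in self.temperature_variants.items()}
        if key not in variants:
            raise ConfigurationError(
                f"no temperature variant for label {key!r}; "
                f"known labels: {sorted(variants)}"
            )
        return replace(self, **dict(variants[key]))


def _canonical_label(label: str | int | float) -> str:
    """Normalize a temperature label: 22, 22.0 and '22' compare equal."""
    if isinstance(label, str):
        try:
            label = float(label)
        except ValueError:
            return label
    f = float(label)
    return str(int(f)) if f == int(f) else str(f)


@dataclass(frozen=True)
class GenotypeSpec:
    """A genetic perturbation: multiplicative production factors plus overrides.

    ``mutB``/``mutE``/``mutC``/``mutP`` scale the production terms of the
    respective variables (1 = wild type, < 1 loss of function, > 1
    overexpression).  ``overrides`` may replace ``Pstar``, ``pself`` and
    ``pFP`` for this genotype -- these three are exactly the quantities the
    calibration procedure re-estimates per genotype.
    """

    name: str
    mutB: float = 1.0
    mutE: float = 1.0
    mutC: float = 1.0
    mutP: float = 1.0
    overrides: Mapping[str, object] = field(default_factory=dict)

    _ALLOWED_OVERRIDES = frozenset({"Pstar", "pself", "pFP"})

    def __post_init__(self) -> None:
        for name in ("mutB", "mutE", "mutC", "mutP"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0 for genotype {self.name!r}")
        bad = set(self.overrides) - self._ALLOWED_OVERRIDES
        if bad:
            raise ConfigurationError(
                f"genotype {self.name!r} overrides {sorted(bad)}; only "
                f"{sorted(self._ALLOWED_OVERRIDES)} may be overridden"
            )

    @property
    def is_wild_type(self) -> bool:
        return (
            self.mutB == self.mutE == self.mutC == self.mutP == 1.0
            and not self.overrides
        )

    def effective(self, params: ParameterSet) -> ParameterSet:
        """Parameters with this genotype's overrides applied (factors excluded)."""
        if not self.overrides:
            return params
        return replace(params, **dict(self.overrides))


WILD_TYPE = GenotypeSpec(name="WT")


@dataclass
class ModelState:
    """A snapshot of the six state variables at time ``t`` (hours)."""

    B: float
    E: float
    C: float
    P: float
    F: float
    G: float
    t: float = 0.0

    def as_vector(self) -> list[float]:
        return [self.B, self.E, self.C, self.P, self.F, self.G]

    @classmethod
    def from_vector(cls, y, t: float = 0.0) -> "ModelState":
        return cls(*map(float, y), t=t)

    @classmethod
    def zero(cls, t: float = 0.0) -> "ModelState":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, t=t)


def _sigmoid(x: float) -> float:
    # overflow-safe logistic
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def elf3_production(
    t: float, day_length: float, params: ParameterSet, mutE: float = 1.0
) -> float:
    """Oscillatory ELF3 synthesis rate (conc/h) at time ``t``.

    The rate swings between ``mutE*(pE1 - pE2)`` (day) and
    ``mutE*(pE1 + pE2)`` (night); ``alpha`` sets the sharpness of the
    dawn/dusk transitions.  ``day_length`` of 0 or 24 selects the constant
    dark/light limits exactly.
    """
    if not 0.0 <= day_length <= 24.0:
        raise DomainError(f"day_length must lie in [0, 24], got {day_length}")
    if day_length == 0.0:
        return mutE * (params.pE1 + params.pE2)
    if day_length == 24.0:
        return mutE * (params.pE1 - params.pE2)
    t0 = math.fmod(t, 24.0)
    if t0 < 0.0:
        t0 += 24.0
    t1 = t0 - day_length
    t2 = t0 - 24.0
    a = params.alpha
    osc = -1.0 + 2.0 * _sigmoid(a * t0) - 2.0 * _sigmoid(a * t1) + 2.0 * _sigmoid(a * t2)
    return mutE * (params.pE1 - params.pE2 * osc)


def _strength_at(t: float, params: ParameterSet, name: str) -> float:
    return schedule_value(t, getattr(params, name))


def rhs(
    t: float,
    state,
    params: ParameterSet,
    genotype: GenotypeSpec = WILD_TYPE,
    light: int = 0,
    day_length: float | None = None,
    branch: str | None = None,
):
    """Time derivative of the state vector.

    Parameters
    ----------
    t, state
        Time in hours and state ``(B, E, C, P, F, G)`` (a :class:`ModelState`
        or a length-6 sequence).
    params
        Effective parameters, already resolved for the current temperature.
        Genotype ``overrides`` are applied here.
    light
        Binary light indicator (0 dark, 1 light).
    day_length
        Photoperiod (hours) shaping the ELF3 forcing.  Defaults to
        ``24*light`` (constant conditions).
    branch
        Force the ``"above"`` or ``"below"`` threshold branch; by default the
        branch is selected by comparing P with the effective threshold
        (``P >= Pstar`` selects autoinhibition).

    Returns
    -------
    tuple of 6 floats ``(dB, dE, dC, dP, dF, dG)``.
    """
    if isinstance(state, ModelState):
        y = state.as_vector()
    else:
        y = list(state)
    B, E, C, P, F, G = y
    if min(B, E, C, P, F) < 0.0:
        raise DomainError(f"negative state component at t={t}: {y}")
    if light not in (0, 1):
        raise DomainError(f"light must be 0 or 1, got {light}")
    if day_length is None:
        day_length = 24.0 * light

    p = genotype.effective(params)
    L = float(light)

    dB = p.pB * L * (genotype.mutB - B) - p.kr * B
    dE = elf3_production(t, day_length, p, genotype.mutE) - p.dEC * C * E - p.dE * E
    dC = genotype.mutC * (p.pCL * L + p.pCD * (1.0 - L)) - p.dC * C

    if branch is None:
        branch = "above" if P >= p.Pstar else "below"
    elif branch not in ("above", "below"):
        raise DomainError(f"branch must be 'above' or 'below', got {branch!r}")

    denom = 1.0 + p.pPE * E
    if branch == "above":
        denom += _strength_at(t, p, "pself") * P
    dP = (
        genotype.mutP * p.pP / denom
        - p.dP * P / (1.0 + p.kPC * C)
        - p.dPB * B * P
    )

    dF = p.k0 - p.dF * F
    if branch == "above":
        dF += p.pF / (1.0 + _strength_at(t, p, "pFP") * P)

    growth_num = p.kG * p.pGP * P
    growth_den = 1.0 + p.pGE * E + p.pGB * B
    if p.growth_grouping_shared_denominator:
        dG = (p.pG + growth_num) / growth_den
    else:
        dG = p.pG + growth_num / growth_den

    return (dB, dE, dC, dP, dF, dG)


def steady_state_below_threshold(
    params: ParameterSet,
    genotype: GenotypeSpec = WILD_TYPE,
    light: int = 0,
) -> ModelState:
    """Closed-form fixed point on the below-threshold branch (constant forcing).

    Assumes a constant light level and the matching constant ELF3 regime
    (day length 24 h in light, 0 h in dark).  Solves the below-threshold
    branch algebraically:

    .. math::

        B^* = \\frac{p_B\\,mut_B\\,L}{p_B L + k_r},\\qquad
        C^* = \\frac{mut_C (p_{CL} L + p_{CD}(1-L))}{d_C},\\qquad
        E^* = \\frac{p_E}{d_{EC} C^* + d_E},

    then PIF4 from production/(linear loss) and the basal reporter level
    ``F* = k0/dF``.  ``G`` grows without bound and is reported as 0.

    Raises :class:`BranchViolationError` if the resulting PIF4 level does not
    satisfy ``P* < Pstar`` (the algebra only holds on that branch).
    """
    if light not in (0, 1):
        raise DomainError(f"light must be 0 or 1, got {light}")
    p = genotype.effective(params)
    L = float(light)
    B = p.pB * genotype.mutB * L / (p.pB * L + p.kr) if (p.pB * L + p.kr) > 0 else 0.0
    C = genotype.mutC * (p.pCL * L + p.pCD * (1.0 - L)) / p.dC
    pE = elf3_production(0.0, 24.0 * L, p, genotype.mutE)
    E = pE / (p.dEC * C + p.dE)
    loss = p.dP / (1.0 + p.kPC * C) + p.dPB * B
    P = (genotype.mutP * p.pP / (1.0 + p.pPE * E)) / loss
    if P >= p.Pstar:
        raise BranchViolationError(
            f"below-threshold steady state has P={P:.4g} >= Pstar={p.Pstar:.4g}; "
            "oracle inapplicable"
        )
    F = p.k0 / p.dF
    return ModelState(B=B, E=E, C=C, P=P, F=F, G=0.0, t=math.inf)
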