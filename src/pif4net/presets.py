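"""Canonical experiment presets: protocols, panels and schedule variants.

Each preset bundles a protocol, the genotype panel it is run over, the
observable read out, and (where the in-silico experiment calls for it) a
modified parameter set -- e.g. red-light and tissue-specific panels are
represented purely by a different autoinhibition strength, and the
feedback-off variants set ``pself`` to zero.

Printed strengths reused verbatim where the in-silico experiments state
them: the low/high/cotyledon autoinhibition variants 25 / 75 / 15 and the
schedule plateau window D1 = 2 h to D2 = 6 h.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable, Dict, List

from .defaults import (
    FIG_PANEL_DAY,
    LD_HARVEST_ZT,
    SD_HARVEST_ZT,
    default_parameters,
    default_registry,
)
from .errors import ConfigurationError
from .model import ParameterSet, Schedule
from .protocols import (
    EnvironmentProtocol,
    make_constant,
    make_photoperiod,
    make_shift,
)

__all__ = ["PanelPreset", "PANEL_PRESETS", "PROTOCOL_PRESETS", "get_panel_preset",
           "get_protocol_preset"]

#: printed autoinhibition strengths for the strength-variant panels
PSELF_LOW = 25.0
PSELF_HIGH = 75.0
PSELF_COTYLEDON = 15.0

_CORE_PANEL = ["WT", "pif4-101", "PIF4-OE1", "PIF4-OE2"]
_FULL_PANEL = [
    "WT", "pif4-101", "PIF4-OE1", "PIF4-OE2", "PIF4-OE3",
    "cop1-4", "cop1-6", "det1-1", "35S:COP1", "phyb-9", "35S:PHYB",
]


class PanelPreset:
    """A named, fully specified in-silico experiment."""

    def __init__(
        self,
        name: str,
        protocol: Callable[[], EnvironmentProtocol],
        genotypes: List[str],
        observable_spec: dict,
        params: Callable[[ParameterSet], ParameterSet] | None = None,
        description: str = "",
    ):
        self.name = name
        self._protocol = protocol
        self.genotypes = genotypes
        self.observable_spec = observable_spec
        self._params = params or (lambda p: p)
        self.description = description

    def protocol(self) -> EnvironmentProtocol:
        return self._protocol()

    def parameters(self, base: ParameterSet | None = None) -> ParameterSet:
        return self._params(base or default_parameters())

    def registry_subset(self):
        registry = default_registry()
        return [registry[name] for name in self.genotypes]


def _sd():
    return make_photoperiod(8, FIG_PANEL_DAY)


def _ld():
    return make_photoperiod(16, FIG_PANEL_DAY)


def _darkshift():
    return make_shift(make_constant(1, 120.0), make_constant(0, 24.0))


def _temp_shift_sd():
    return make_shift(make_photoperiod(8, 5, "22"), make_photoperiod(8, 1, "27"))


def _scheduled(p: ParameterSet) -> ParameterSet:
    # diurnal variation of both autoinhibition strengths: high at night and
    # early day, minimal mid-day (plateau over the printed 2-6 h window)
    return replace(
        p,
        pself=Schedule(max_day=12.0, min_val=4.0, max_night=12.0, D1=2.0, D2=6.0),
        pFP=Schedule(max_day=4.5, min_val=1.5, max_night=4.5, D1=2.0, D2=6.0),
    )


PROTOCOL_PRESETS: Dict[str, Callable[[], EnvironmentProtocol]] = {
    "sd": _sd,
    "ld": _ld,
    "darkshift": _darkshift,
    "temp_shift_sd": _temp_shift_sd,
    "constant_light": lambda: make_constant(1, 24.0 * FIG_PANEL_DAY),
    "constant_dark": lambda: make_constant(0, 24.0 * FIG_PANEL_DAY),
}


def _gus_spec(zt: float) -> dict:
    return {"observable": "gus", "day": FIG_PANEL_DAY, "zt": zt, "normalize": True}


_HYP_SPEC = {"observable": "hypocotyl", "day": FIG_PANEL_DAY, "normalize": True}

PANEL_PRESETS: Dict[str, PanelPreset] = {}


def _register(preset: PanelPreset) -> None:
    PANEL_PRESETS[preset.name] = preset


_register(PanelPreset(
    "gus_panel_sd", _sd, _FULL_PANEL, _gus_spec(SD_HARVEST_ZT),
    description="normalized reporter activity, short day, harvest ZT23",
))
_register(PanelPreset(
    "gus_panel_ld", _ld, _FULL_PANEL, _gus_spec(LD_HARVEST_ZT),
    description="normalized reporter activity, long day, harvest ZT4",
))
_register(PanelPreset(
    "gus_panel_sd_low_pself", _sd, _CORE_PANEL, _gus_spec(SD_HARVEST_ZT),
    params=lambda p: replace(p, pself=PSELF_LOW),
    description="low autoinhibition strength variant (pself=25)",
))
_register(PanelPreset(
    "gus_panel_sd_high_pself", _sd, _CORE_PANEL, _gus_spec(SD_HARVEST_ZT),
    params=lambda p: replace(p, pself=PSELF_HIGH),
    description="high autoinhibition strength variant (pself=75, red-light-like)",
))
_register(PanelPreset(
    "gus_panel_sd_cotyledon", _sd, _CORE_PANEL, _gus_spec(SD_HARVEST_ZT),
    params=lambda p: replace(p, pself=PSELF_COTYLEDON),
    description="cotyledon-like low autoinhibition variant (pself=15)",
))
_register(PanelPreset(
    "hypocotyl_sd", _sd, _FULL_PANEL, _HYP_SPEC,
    description="day-6 hypocotyl lengths under short day",
))
_register(PanelPreset(
    "hypocotyl_ld", _ld, _FULL_PANEL, _HYP_SPEC,
    description="day-6 hypocotyl lengths under long day",
))
for _D in (4, 8, 12, 16):
    _register(PanelPreset(
        f"hypocotyl_{_D}h", lambda D=_D: make_photoperiod(D, FIG_PANEL_DAY),
        _CORE_PANEL, _HYP_SPEC,
        description=f"day-6 hypocotyl at a {_D}-h photoperiod",
    ))
    _register(PanelPreset(
        f"hypocotyl_{_D}h_feedback_off",
        lambda D=_D: make_photoperiod(D, FIG_PANEL_DAY),
        _CORE_PANEL, _HYP_SPEC,
        params=lambda p: replace(p, pself=0.0),
        description=f"autoinhibition disabled (pself=0), {_D}-h photoperiod",
    ))
_register(PanelPreset(
    "darkshift_gus", _darkshift, _CORE_PANEL,
    {"observable": "gus", "day": 6, "zt": 12.0, "normalize": True},
    description="5 d constant light then 1 d dark; reporter mid-way through the dark day",
))
_register(PanelPreset(
    "gus_panel_temp_shift", _temp_shift_sd, _CORE_PANEL, _gus_spec(SD_HARVEST_ZT),
    description="short day, 22 degC shifted to 27 degC for the final day",
))
_register(PanelPreset(
    "gus_panel_sd_scheduled", _sd, ["WT", "PIF4-OE2"], _gus_spec(SD_HARVEST_ZT),
    params=_scheduled,
    description="time-varying autoinhibition strengths (diurnal schedules)",
))


def get_panel_preset(name: str) -> PanelPreset:
    try:
        return PANEL_PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown panel preset {name!r}; available: {sorted(PANEL_PRESETS)}"
        ) from None


def get_protocol_preset(name: str) -> EnvironmentProtocol:
    try:
        return PROTOCOL_PRESETS[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown protocol preset {name!r}; available: {sorted(PROTOCOL_PRESETS)}"
        ) from None
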