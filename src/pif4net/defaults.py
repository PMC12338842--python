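"""Packaged default calibration: parameters, genotype registry, data anchors.

The defaults are calibrated within this repository (no machine-readable
parameter values or measurements accompany the study this model describes);
docs/methods.md records how they were obtained.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .io import params_from_dict, registry_from_dict
from .model import ParameterSet
from .protocols import GenotypeRegistry, validate_registry

__all__ = [
    "default_parameters",
    "default_registry",
    "WT_HYPOCOTYL_ANCHORS_MM",
    "FIG_PANEL_DAY",
    "SD_HARVEST_ZT",
    "LD_HARVEST_ZT",
]

#: day the observables are read out (six-day-old seedlings)
FIG_PANEL_DAY = 6
#: harvest Zeitgeber times used for reporter panels
SD_HARVEST_ZT = 23.0
LD_HARVEST_ZT = 4.0

#: repo-chosen wild-type day-6 hypocotyl anchors (mm) by day length (h) at
#: 22 degC; realistic magnitudes for seedlings grown under these
#: photoperiods, used to calibrate the growth parameters.
WT_HYPOCOTYL_ANCHORS_MM = {4.0: 6.5, 8.0: 5.0, 12.0: 3.5, 16.0: 2.3}


def _load(name: str):
    with resources.files("pif4net.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def default_parameters() -> ParameterSet:
    """The shipped, repo-calibrated wild-type :class:`ParameterSet`."""
    return params_from_dict(_load("parameters.yaml"))


def default_registry() -> GenotypeRegistry:
    """The shipped genotype registry (wild type, mutants, overexpressors)."""
    registry = registry_from_dict(_load("genotypes.yaml"))
    validate_registry(registry)
    return registry
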