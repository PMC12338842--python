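"""Synthetic observation tables with the statistical structure of the assays.

The generator emulates the measurement design of the experiments the model
is calibrated against: replicate-level day-6 hypocotyl lengths (about 20
seedlings per genotype x day-length condition, spread reported as a
standard deviation in mm) and reporter-activity time courses harvested at
stated Zeitgeber times.  Hypocotyl noise is additive Gaussian (error bars
are absolute mm); reporter noise is multiplicative Gaussian, because
activities span orders of magnitude across genotypes.  Draws below zero are
truncated to zero rather than resampled so the output is a pure function of
the seed.

Every function is deterministic given ``SyntheticSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrationError, Pif4NetError
from .model import GenotypeSpec, ParameterSet
from .protocols import EnvironmentProtocol, make_photoperiod
from .simulate import SolverOptions, hypocotyl_at, integrate

__all__ = ["SyntheticSpec", "generate_hypocotyl_dataset", "generate_gus_timecourse"]

#: tidy observation-table columns shared by all generators
OBSERVATION_COLUMNS = (
    "genotype", "condition", "day_length", "temperature", "zt",
    "replicate_id", "observable", "value",
)


@dataclass
class SyntheticSpec:
    """Design of a synthetic experiment.

    Defaults mirror the emulated measurement design: day lengths
    4/8/12/16 h, 20 replicates per condition, 0.5 mm replicate spread for
    hypocotyls and 20% relative spread for reporter activity.
    """

    true_params: ParameterSet
    genotypes: Sequence[GenotypeSpec]
    seed: int
    day_lengths: Sequence[float] = (4.0, 8.0, 12.0, 16.0)
    n_replicates: int = 20
    noise_sd_hypocotyl: float = 0.5
    noise_sd_gus_relative: float = 0.2
    temperature: str = "22"
    day: int = 6
    solver_options: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.noise_sd_hypocotyl < 0 or self.noise_sd_gus_relative < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")


def generate_hypocotyl_dataset(spec: SyntheticSpec) -> pd.DataFrame:
    """Replicate-level day-``spec.day`` hypocotyl table (mm).

    For each genotype x day length the deterministic model value is
    perturbed by independent ``N(0, noise_sd_hypocotyl)`` draws, truncated
    at zero.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for genotype in spec.genotypes:
        for D in spec.day_lengths:
            proto = make_photoperiod(float(D), n_days=spec.day, temperature=spec.temperature)
            try:
                traj = integrate(spec.true_params, genotype, proto,
                                 options=spec.solver_options)
                value = hypocotyl_at(traj, spec.day)
            except Pif4NetError as exc:
                raise IntegrationError(
                    f"synthetic generation failed for genotype "
                    f"{genotype.name!r} at day_length={D}: {exc}"
                ) from exc
            noise = rng.normal(0.0, spec.noise_sd_hypocotyl, size=spec.n_replicates)
            values = np.maximum(value + noise, 0.0)
            for rep, v in enumerate(values):
                rows.append({
                    "genotype": genotype.name,
                    "condition": f"photoperiod-{D:g}h",
                    "day_length": float(D),
                    "temperature": spec.temperature,
                    "zt": np.nan,
                    "replicate_id": rep,
                    "observable": "hypocotyl",
                    "value": float(v),
                })
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))


def generate_gus_timecourse(
    spec: SyntheticSpec,
    protocol: EnvironmentProtocol,
    zt_points: Sequence[float],
    day: int | None = None,
) -> pd.DataFrame:
    """Reporter-activity table at the requested harvest times.

    ``zt_points`` are Zeitgeber hours of ``day`` (default ``spec.day``);
    each genotype x time point yields ``n_replicates`` draws of
    ``F * (1 + N(0, noise_sd_gus_relative))`` truncated at zero.
    """
    rng = np.random.default_rng(spec.seed)
    day = spec.day if day is None else day
    times = [(day - 1) * 24.0 + float(zt) for zt in zt_points]
    for t in times:
        if not 0.0 <= t <= protocol.total_duration:
            raise ConfigurationError(
                f"harvest time {t} h outside protocol duration "
                f"{protocol.total_duration} h"
            )
    rows = []
    for genotype in spec.genotypes:
        try:
            traj = integrate(spec.true_params, genotype, protocol,
                             options=spec.solver_options)
        except Pif4NetError as exc:
            raise IntegrationError(
                f"synthetic generation failed for genotype {genotype.name!r}: {exc}"
            ) from exc
        for zt, t in zip(zt_points, times):
            value = float(traj.value("F", t))
            noise = rng.normal(0.0, spec.noise_sd_gus_relative, size=spec.n_replicates)
            values = np.maximum(value * (1.0 + noise), 0.0)
            seg, local = protocol.segment_at(t)
            for rep, v in enumerate(values):
                rows.append({
                    "genotype": genotype.name,
                    "condition": "timecourse",
                    "day_length": seg.effective_day_length,
                    "temperature": seg.temperature,
                    "zt": float(zt),
                    "replicate_id": rep,
                    "observable": "gus",
                    "value": float(v),
                })
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))
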