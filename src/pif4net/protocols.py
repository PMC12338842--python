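"""Light/temperature environments and the genotype registry.

An :class:`EnvironmentProtocol` is an ordered list of contiguous segments.
Each segment is either a repeating photoperiod (``day_length`` hours of light
per 24 h cycle, lights-on at the segment-local phase 0) or a constant
explicit light level.  Segments also carry a temperature label that selects
a parameter variant (22 or 27 degC in the shipped calibration).

Zeitgeber convention: ZT0 = lights-on; phases are measured from the start of
the segment, so shifting protocols (e.g. five days of constant light followed
by a day of dark) restart their diurnal clock at the shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

from .errors import ConfigurationError, DomainError
from .model import GenotypeSpec

__all__ = [
    "Segment",
    "EnvironmentProtocol",
    "GenotypeRegistry",
    "light_indicator",
    "make_photoperiod",
    "make_constant",
    "make_shift",
    "validate_registry",
]


@dataclass(frozen=True)
class Segment:
    """A stretch of the environment with fixed photoperiod and temperature.

    Exactly one of ``day_length`` (repeating photoperiod) or ``light``
    (constant explicit level) must be given.
    """

    duration: float
    day_length: float | None = None
    light: int | None = None
    temperature: str = "22"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("segment duration must be > 0")
        if (self.day_length is None) == (self.light is None):
            raise ConfigurationError(
                "exactly one of day_length or light must be set on a segment"
            )
        if self.day_length is not None and not 0.0 <= self.day_length <= 24.0:
            raise DomainError(f"day_length must lie in [0, 24], got {self.day_length}")
        if self.light is not None and self.light not in (0, 1):
            raise DomainError(f"explicit light must be 0 or 1, got {self.light}")

    @property
    def effective_day_length(self) -> float:
        """Day length governing the ELF3 forcing inside this segment."""
        if self.day_length is not None:
            return self.day_length
        return 24.0 * self.light

    def light_at(self, local_t: float) -> int:
        """Light indicator at ``local_t`` hours after the segment start."""
        if self.light is not None:
            return self.light
        phase = local_t % 24.0
        return 1 if phase < self.day_length else 0


@dataclass(frozen=True)
class EnvironmentProtocol:
    """Ordered, contiguous environment segments starting at t = 0."""

    segments: Tuple[Segment, ...]

    def __init__(self, segments: Iterable[Segment]):
        object.__setattr__(self, "segments", tuple(segments))
        if not self.segments:
            raise ConfigurationError("a protocol needs at least one segment")

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def segment_starts(self) -> List[float]:
        starts, t = [], 0.0
        for s in self.segments:
            starts.append(t)
            t += s.duration
        return starts

    def segment_at(self, t: float) -> Tuple[Segment, float]:
        """Segment containing time ``t`` and the segment-local time.

        Boundary instants belong to the later segment; ``t == total_duration``
        belongs to the last one.
        """
        if not 0.0 <= t <= self.total_duration:
            raise DomainError(
                f"t={t} outside protocol range [0, {self.total_duration}]"
            )
        start = 0.0
        for seg in self.segments:
            if t < start + seg.duration:
                return seg, t - start
            start += seg.duration
        return self.segments[-1], t - (start - self.segments[-1].duration)

    def temperatures(self) -> set:
        return {s.temperature for s in self.segments}

    def breakpoints(self) -> List[float]:
        """Sorted times of every light transition and segment boundary.

        These are the points where the right-hand side of the ODE system
        jumps for environmental reasons; the integrator restarts there.
        """
        pts = {0.0, self.total_duration}
        start = 0.0
        for seg in self.segments:
            pts.add(start)
            if seg.day_length is not None and 0.0 < seg.day_length < 24.0:
                day = 0.0
                while day < seg.duration:
                    on = start + day
                    off = start + day + seg.day_length
                    pts.add(min(on, start + seg.duration))
                    if off < start + seg.duration:
                        pts.add(off)
                    day += 24.0
            start += seg.duration
        return sorted(p for p in pts if 0.0 <= p <= self.total_duration)

    def transition_events(self) -> List[Tuple[float, str]]:
        """(time, kind) for light_on / light_off / temp_shift transitions."""
        events: List[Tuple[float, str]] = []
        start = 0.0
        prev_light = None
        prev_temp = None
        for seg in self.segments:
            if prev_temp is not None and seg.temperature != prev_temp:
                events.append((start, "temp_shift"))
            if seg.day_length is not None and 0.0 < seg.day_length < 24.0:
                day = 0.0
                while day < seg.duration:
                    on = start + day
                    off = start + day + seg.day_length
                    if prev_light != 1:
                        events.append((on, "light_on"))
                    prev_light = 1
                    if off <= start + seg.duration:
                        events.append((off, "light_off"))
                        prev_light = 0
                    day += 24.0
            else:
                level = seg.light_at(0.0)
                if prev_light is not None and level != prev_light:
                    events.append((start, "light_on" if level else "light_off"))
                elif prev_light is None and level == 1:
                    events.append((start, "light_on"))
                prev_light = level
            prev_temp = seg.temperature
            start += seg.duration
        return [(t, k) for t, k in sorted(events) if t <= self.total_duration]


#: mapping of genotype name to its specification
GenotypeRegistry = Dict[str, GenotypeSpec]


def light_indicator(t: float, protocol: EnvironmentProtocol) -> int:
    """Binary light level at time ``t`` of the protocol (domain-checked)."""
    seg, local = protocol.segment_at(t)
    return seg.light_at(local)


def make_photoperiod(
    day_length: float, n_days: int, temperature: str | int = "22"
) -> EnvironmentProtocol:
    """``n_days`` repeats of a ``day_length``-hour photoperiod."""
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    seg = Segment(
        duration=24.0 * n_days, day_length=float(day_length), temperature=str(temperature)
    )
    return EnvironmentProtocol([seg])


def make_constant(
    light: int, duration: float, temperature: str | int = "22"
) -> EnvironmentProtocol:
    """A constant-light (or constant-dark) stretch."""
    return EnvironmentProtocol(
        [Segment(duration=float(duration), light=int(light), temperature=str(temperature))]
    )


def make_shift(
    first: EnvironmentProtocol, second: EnvironmentProtocol
) -> EnvironmentProtocol:
    """Concatenate two protocols (the second starts when the first ends)."""
    return EnvironmentProtocol(tuple(first.segments) + tuple(second.segments))


def validate_registry(registry: GenotypeRegistry) -> None:
    """Check the registry invariants: WT present with unit factors."""
    if "WT" not in registry:
        raise ConfigurationError("genotype registry must contain 'WT'")
    if not registry["WT"].is_wild_type:
        raise ConfigurationError("'WT' entry must have unit factors and no overrides")
    for name, spec in registry.items():
        if spec.name != name:
            raise ConfigurationError(
                f"registry key {name!r} does not match genotype name {spec.name!r}"
            )
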