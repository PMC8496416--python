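"""Stimulus bookkeeping: screen geometry, field of view, the contrast
ladder, accommodative demand, and trial scheduling.

The reference display is a 1920 x 1200 px screen with 0.252 mm pixel pitch
viewed from 75 cm, giving a field of roughly 36 x 23 degrees.  The drifting
vertical grating moves horizontally at 2.3 deg/s and is shown at one of 39
log-spaced Michelson-contrast levels between ~0.03% and ~66%; a trial ends
after 4 s or as soon as a robust OKN is detected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ConfigError

__all__ = [
    "ScreenGeometry",
    "StimulusSpec",
    "ExperimentPlan",
    "TrialSlot",
    "DEFAULT_SF_SET",
    "field_of_view",
    "contrast_ladder",
    "accommodative_demand",
    "plan_experiment",
]

#: spatial frequencies of the reference protocol (cycles per degree)
DEFAULT_SF_SET: Tuple[float, ...] = (0.7, 1.5, 2.6, 3.7, 5.2, 6.5)


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display description."""

    resolution_px: Tuple[int, int] = (1920, 1200)
    pixel_pitch_mm: float = 0.252
    viewing_distance_cm: float = 75.0

    def __post_init__(self) -> None:
        if (
            min(self.resolution_px) <= 0
            or self.pixel_pitch_mm <= 0
            or self.viewing_distance_cm <= 0
        ):
            raise ConfigError("screen geometry values must be positive")

    def px_to_deg(self, px: float) -> float:
        """Visual angle subtended by ``px`` pixels, centered on the line of
        sight (small-extent conversion used at ingestion of pixel data)."""
        mm = px * self.pixel_pitch_mm
        return 2.0 * math.degrees(
            math.atan(mm / (2.0 * self.viewing_distance_cm * 10.0))
        )


def field_of_view(geometry: ScreenGeometry) -> Tuple[float, float]:
    """(horizontal, vertical) field of view in degrees.

    ``angle = 2 atan(extent / (2 distance))`` per axis.
    """
    d_mm = geometry.viewing_distance_cm * 10.0
    out = []
    for npx in geometry.resolution_px:
        extent = npx * geometry.pixel_pitch_mm
        out.append(2.0 * math.degrees(math.atan(extent / (2.0 * d_mm))))
    return out[0], out[1]


def contrast_ladder(
    n_levels: int = 39, lo: float = 0.0003, hi: float = 0.66
) -> np.ndarray:
    """Log-uniformly spaced ascending contrast levels with exact endpoints."""
    if not (0 < lo < hi <= 1):
        raise ConfigError("need 0 < lo < hi <= 1")
    if n_levels < 2:
        raise ConfigError("need at least two levels")
    return np.geomspace(lo, hi, n_levels)


def accommodative_demand(distance_cm: float) -> float:
    """Accommodative demand in diopters: 100 / distance_cm."""
    if distance_cm <= 0:
        raise ConfigError("distance must be positive")
    return 100.0 / distance_cm


@dataclass(frozen=True)
class StimulusSpec:
    """One drifting-grating presentation."""

    sf_cpd: float
    contrast: float
    velocity_dps: float = 2.3
    direction: int = 1          # +1 rightward, -1 leftward (signed nasal/temporal)
    duration_max_s: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.contrast <= 1):
            raise ConfigError("contrast must be a Michelson fraction in (0, 1]")
        if self.direction not in (-1, 1):
            raise ConfigError("direction must be +1 or -1")
        if self.sf_cpd <= 0 or self.velocity_dps <= 0:
            raise ConfigError("sf and velocity must be positive")

    def mirrored(self) -> "StimulusSpec":
        return StimulusSpec(
            self.sf_cpd,
            self.contrast,
            self.velocity_dps,
            -self.direction,
            self.duration_max_s,
        )


@dataclass(frozen=True)
class TrialSlot:
    """One scheduled presentation slot (contrast filled in adaptively)."""

    condition: str
    sf_cpd: float
    direction: int
    index: int


@dataclass
class ExperimentPlan:
    """Session layout: tested SFs, defocus conditions, trials per SF.

    The inter-trial cross (1.25 deg, 1.3 s) is carried as metadata only; it
    is the blink window of the protocol, not something the detector sees.
    """

    sf_set: Sequence[float] = DEFAULT_SF_SET
    defocus_conditions: Sequence[str] = ("0.0D",)
    n_trials_per_sf: int = 64
    velocity_dps: float = 2.3
    timeout_s: float = 4.0
    cross_size_deg: float = 1.25
    cross_duration_s: float = 1.3


def plan_experiment(plan: ExperimentPlan, seed: int) -> List[TrialSlot]:
    """Deterministic randomized schedule.

    Per defocus condition the SF order is shuffled; within each SF block the
    two drift directions fill equal counts of the ``n_trials_per_sf`` slots
    in shuffled order.  An odd trial count is split ceil/floor with a
    warning.
    """
    rng = np.random.default_rng(seed)
    n = plan.n_trials_per_sf
    if n % 2:
        warnings.warn(
            f"odd n_trials_per_sf={n}: directions split "
            f"{n // 2 + 1}/{n // 2}",
            stacklevel=2,
        )
    schedule: List[TrialSlot] = []
    for condition in plan.defocus_conditions:
        sfs = list(plan.sf_set)
        rng.shuffle(sfs)
        for sf in sfs:
            dirs = np.array([1] * ((n + 1) // 2) + [-1] * (n // 2))
            rng.shuffle(dirs)
            for i, d in enumerate(dirs):
                schedule.append(
                    TrialSlot(
                        condition=condition,
                        sf_cpd=float(sf),
                        direction=int(d),
                        index=i,
                    )
                )
    return schedule
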