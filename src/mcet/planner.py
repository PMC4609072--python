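"""Human-scale treatment-time planning from per-spot lesion yield.

Extrapolates the single-focal-spot yield measured in the rodent model to a
clinical target: a cylindrical myocardial region of given diameter and wall
thickness is tiled with focal spots, each delivering a known macrolesion
volume per treatment interval.  A static beam treats spot by spot; a swept
beam revisits every spot once per imaging frame, compressing the schedule
by the frame rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["PlanInput", "PlanResult", "plan_treatment"]


@dataclass(frozen=True)
class PlanInput:
    """Target geometry and per-spot yield.

    Defaults describe a 4-cm-diameter region of a 21-mm-thick hypertrophic
    left ventricular wall, treated in 5-minute focal spots that each yield
    a 50-uL macrolesion at 20 % microlesion density, with a 56-fps swept
    beam and no axial stacking.
    """

    target_diameter_cm: float = 4.0
    wall_thickness_mm: float = 21.0
    per_spot_volume_ul: float = 50.0
    per_spot_time_min: float = 5.0
    target_density_pct: float = 20.0
    frame_rate_fps: float = 56.0
    axial_stacking_factor: int = 1
    sweep_efficiency: float = 1.0  # optional derating of the swept beam

    def __post_init__(self) -> None:
        positive = (
            self.per_spot_volume_ul,
            self.per_spot_time_min,
            self.target_density_pct,
            self.frame_rate_fps,
            self.axial_stacking_factor,
            self.sweep_efficiency,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("per-spot yield, timing and rates must be positive")
        if self.target_diameter_cm < 0 or self.wall_thickness_mm < 0:
            raise ValueError("target geometry cannot be negative")


@dataclass(frozen=True)
class PlanResult:
    """Treatment volume and durations; exact values with display rounding.

    ``n_spots`` is the exact ratio of target to per-spot volume; displayed
    spot counts are rounded up to whole spots.  The swept duration divides
    the static duration by the frame rate (times the optional efficiency).
    """

    target_volume_ml: float
    n_spots: float
    static_duration_min: float
    swept_duration_min: float

    @property
    def n_spots_display(self) -> int:
        return math.ceil(self.n_spots)

    @property
    def target_volume_display(self) -> float:
        return round(self.target_volume_ml, 1)

    @property
    def per_spot_time_min(self) -> float:
        return self.static_duration_min / self.n_spots if self.n_spots else 0.0

    @property
    def static_duration_display(self) -> int:
        """Whole-spot duration in whole minutes (ceil(n_spots) x spot time)."""
        return round(self.n_spots_display * self.per_spot_time_min)

    @property
    def swept_duration_display(self) -> int:
        if self.static_duration_min == 0:
            return 0
        frame_rate = self.static_duration_min / self.swept_duration_min
        return round(self.static_duration_display / frame_rate)

    def report(self) -> dict:
        return {
            "target_volume_mL": self.target_volume_display,
            "n_spots": self.n_spots_display,
            "static_duration_min": self.static_duration_display,
            "swept_duration_min": self.swept_duration_display,
        }


def plan_treatment(plan: PlanInput = PlanInput()) -> PlanResult:
    """Cylinder target volume, spot count and static/swept durations.

    ``V = pi (d/2)^2 t`` (26.4 mL for the defaults); the static duration is
    the spot count times the per-spot time (2640 min for the defaults with
    whole spots) and the swept beam divides it by the frame rate (47 min at
    56 fps).  Axial stacking divides the spot count.
    """
    radius_cm = plan.target_diameter_cm / 2.0
    thickness_cm = plan.wall_thickness_mm / 10.0
    volume_ml = math.pi * radius_cm**2 * thickness_cm  # cm^3 == mL
    n_spots = volume_ml * 1000.0 / plan.per_spot_volume_ul / plan.axial_stacking_factor
    static = n_spots * plan.per_spot_time_min
    swept = static / (plan.frame_rate_fps * plan.sweep_efficiency)
    return PlanResult(volume_ml, n_spots, static, swept)
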