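"""Cohort-level simulation experiments chaining the generator and pipeline.

Convenience drivers that mirror the in-vivo study designs: groups of
simulated animals treated at different focal pressures (or infusion
durations), each scored with the full reslicing pipeline, feeding the
dose-response and group-summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exposure import BurstSchedule, build_burst_schedule
from .field import PressureField
from .histo import (
    AxisUndefinedError,
    BeamAxisFit,
    DiskStack,
    Macrolesion,
    NoMacrolesionError,
    disk_dose_response,
    fit_beam_axis,
    macrolesion_metrics,
    reslice_disks,
)
from .synthlesion import LesionModel, MicrolesionSet, TissueSlab, simulate_microlesions

__all__ = ["AnimalResult", "score_lesions", "run_pressure_cohorts"]

# Default exposure protocol of the rodent experiments: bursts every four
# heartbeats at a 360-bpm heart rate for five minutes -> 450 bursts.
DEFAULT_SCHEDULE = build_burst_schedule(360.0, 4, 300.0)


@dataclass
class AnimalResult:
    """Scored outcome of one simulated animal."""

    peak_mpa: float
    lesions: MicrolesionSet
    disks: DiskStack
    macro: Macrolesion | None

    @property
    def mean_radius_mm(self) -> float:
        """Macrolesion mean radius; zero when no macrolesion formed."""
        return self.macro.mean_radius_mm if self.macro is not None else 0.0


def score_lesions(
    lesions: MicrolesionSet,
    model: LesionModel,
    disk_thickness_mm: float = 0.5,
    min_count: int = 3,
) -> tuple[DiskStack, Macrolesion | None]:
    """Axis fit, reslice and macrolesion summary of one lesion cloud.

    Returns an empty disk stack and ``None`` for clouds too sparse to
    characterise (fewer than three lesions or no occupied disk).
    """
    try:
        axis = fit_beam_axis(lesions)
    except AxisUndefinedError:
        axis = BeamAxisFit(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.0)
        return DiskStack((), disk_thickness_mm, axis), None
    disks = reslice_disks(lesions, axis, disk_thickness_mm, min_count)
    try:
        macro = macrolesion_metrics(disks, lesions, model)
    except NoMacrolesionError:
        macro = None
    return disks, macro


def run_pressure_cohorts(
    fld: PressureField,
    model: LesionModel,
    slab: TissueSlab = TissueSlab(),
    schedule: BurstSchedule = DEFAULT_SCHEDULE,
    pressures_mpa: tuple[float, ...] = (2.0, 2.8, 4.0),
    n_animals: int = 5,
    seed: int = 0,
    disk_thickness_mm: float = 0.5,
    voxel_mm: float = 0.1,
) -> dict[float, list[AnimalResult]]:
    """Simulate and score cohorts of animals at several focal pressures.

    The stored field is rescaled linearly to each cohort's focal peak; each
    animal gets an independent seeded Monte-Carlo draw and is scored with
    the reslicing pipeline.
    """
    rng = np.random.default_rng(seed)
    out: dict[float, list[AnimalResult]] = {}
    for peak in pressures_mpa:
        scaled = fld.scaled(peak)
        cohort = []
        for _ in range(n_animals):
            lesions = simulate_microlesions(
                scaled, schedule, slab, model, seed=rng, voxel_mm=voxel_mm
            )
            disks, macro = score_lesions(lesions, model, disk_thickness_mm)
            cohort.append(AnimalResult(peak, lesions, disks, macro))
        out[peak] = cohort
    return out


def pooled_dose_response(
    cohorts: dict[float, list[AnimalResult]], fld: PressureField
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-disk (on-axis pressure, density) points across cohorts."""
    xs, ys = [], []
    for peak, animals in cohorts.items():
        for animal in animals:
            if len(animal.disks) == 0:
                continue
            p, d = disk_dose_response(animal.disks, fld, peak_mpa=peak)
            xs.append(p)
            ys.append(d)
    if not xs:
        return np.empty(0), np.empty(0)
    return np.concatenate(xs), np.concatenate(ys)
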