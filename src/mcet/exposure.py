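"""Pulse-train modulation, ECG-gated burst scheduling and exposure integrals.

A treatment burst is a train of short tone pulses at a fixed pulse
repetition frequency (PRF) under an amplitude envelope.  A square envelope
(constant amplitude) models a static focal beam; a Gaussian envelope models
the exposure a tissue voxel experiences as a swept/scanned beam passes by.
The space-time effective-exposure integral sums, per pulse, the beam volume
whose peak rarefactional pressure exceeds the lesion-formation threshold;
the Gaussian:square ratio of this integral is the predicted efficiency of a
swept beam relative to an equal-peak static beam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field import DEFAULT_LESION_THRESHOLD_MPA, PressureField, suprathreshold_volume

__all__ = [
    "PulseTrain",
    "BurstSchedule",
    "ExposureIntegral",
    "DegenerateEnvelopeError",
    "build_pulse_train",
    "build_burst_schedule",
    "exposure_integral",
    "swept_static_ratio",
]


class DegenerateEnvelopeError(ValueError):
    """Envelope too short to contain a single pulse."""


@dataclass(frozen=True)
class PulseTrain:
    """Amplitude-modulated pulse train.

    ``pulse_times_ms`` are the pulse instants (ms, envelope maximum at 0 for
    the Gaussian kind, envelope start at 0 for the square kind) and
    ``pulse_amplitudes_mpa`` the per-pulse peak rarefactional amplitudes.
    ``envelope_width_ms`` is the square width or the Gaussian FWHM.
    """

    envelope_kind: str
    peak_amplitude_mpa: float
    prf_khz: float
    envelope_width_ms: float
    pulse_times_ms: np.ndarray
    pulse_amplitudes_mpa: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.pulse_amplitudes_mpa < 0):
            raise ValueError("pulse amplitudes must be non-negative")
        spacing = np.diff(self.pulse_times_ms)
        if spacing.size and not np.allclose(spacing, 1.0 / self.prf_khz):
            raise ValueError("pulse spacing must equal 1/prf")

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_times_ms)


@dataclass(frozen=True)
class BurstSchedule:
    """ECG-gated burst timing: one burst every ``trigger_every`` heartbeats."""

    heart_rate_bpm: float
    trigger_every: int
    treatment_duration_s: float
    burst_times_s: np.ndarray

    @property
    def n_bursts(self) -> int:
        return len(self.burst_times_s)

    @property
    def interval_s(self) -> float:
        return self.trigger_every * 60.0 / self.heart_rate_bpm

    def bursts_in_window(self, start_s: float, end_s: float) -> int:
        """Bursts falling inside [start, end) -- e.g. the infusion window."""
        t = self.burst_times_s
        return int(np.count_nonzero((t >= start_s) & (t < end_s)))


@dataclass(frozen=True)
class ExposureIntegral:
    """Space-time effective exposure: sum of per-pulse volumes x time weight."""

    value_ul_s: float
    per_pulse_volumes_ul: np.ndarray
    time_weight_s: float


def build_pulse_train(
    kind: str,
    peak_mpa: float = 4.0,
    width_ms: float = 2.0,
    prf_khz: float = 4.0,
) -> PulseTrain:
    """Construct a square- or Gaussian-modulated pulse train.

    Square: pulses at spacing 1/prf spanning the width, all at the peak
    amplitude (a 2-ms envelope at 4 kHz holds 8 pulses).  Gaussian: pulses
    sampled symmetrically about the envelope maximum with amplitudes
    ``peak * 2**(-(2 t / FWHM)**2)``, so the amplitude at t = +/-FWHM/2 is
    exactly half the peak; one pulse coincides with the envelope maximum and
    the train is truncated at one FWHM from the maximum (amplitudes below
    1/16 of the peak are dropped).
    """
    if width_ms <= 0 or prf_khz <= 0 or peak_mpa <= 0:
        raise ValueError("peak, width and prf must be positive")
    spacing = 1.0 / prf_khz
    if width_ms < spacing:
        raise DegenerateEnvelopeError(
            f"envelope of {width_ms} ms holds less than one pulse at {prf_khz} kHz"
        )
    if kind == "square":
        n = int(round(width_ms * prf_khz))
        times = np.arange(n) * spacing
        amps = np.full(n, peak_mpa)
    elif kind == "gaussian":
        k_max = int(np.floor(width_ms / spacing))
        ks = np.arange(-k_max, k_max + 1)
        times = ks * spacing
        amps = peak_mpa * 2.0 ** (-((2.0 * times / width_ms) ** 2))
    else:
        raise ValueError(f"unknown envelope kind: {kind!r}")
    return PulseTrain(kind, peak_mpa, prf_khz, width_ms, times, amps)


def build_burst_schedule(
    heart_rate_bpm: float,
    trigger_every: int = 4,
    duration_s: float = 300.0,
) -> BurstSchedule:
    """Evenly spaced ECG-triggered burst times starting at t = 0.

    The inter-burst interval is ``trigger_every * 60 / heart_rate``; all
    burst times are strictly below the treatment duration.
    """
    if heart_rate_bpm <= 0:
        raise ValueError("heart rate must be positive")
    if trigger_every < 1:
        raise ValueError("trigger_every must be at least 1")
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    interval = trigger_every * 60.0 / heart_rate_bpm
    n = int(np.ceil(duration_s / interval - 1e-12))
    times = np.arange(n) * interval
    return BurstSchedule(heart_rate_bpm, trigger_every, duration_s, times)


def exposure_integral(
    train: PulseTrain,
    field: PressureField,
    p_l: float = DEFAULT_LESION_THRESHOLD_MPA,
    time_weight_s: float | None = None,
) -> ExposureIntegral:
    """Space-time effective exposure of a pulse train (uL.s).

    The field scales linearly per pulse (free-field assumption): for a pulse
    of amplitude A the suprathreshold volume is that of the field rescaled
    by ``A / focal_peak``, equivalently the volume above ``p_l *
    focal_peak / A`` in the stored field.  Only pulses whose rescaled focal
    peak strictly exceeds the threshold count as lesion-capable; the rest
    contribute zero volume.  The default time weight is the pulse repetition
    interval ``1 / prf`` (the absolute normalisation of the integral is a
    reporting convention; ratios between trains are normalisation-free).
    """
    if time_weight_s is None:
        time_weight_s = 1.0e-3 / train.prf_khz  # pulse repetition interval, s
    volumes = np.zeros(train.n_pulses)
    for i, amp in enumerate(train.pulse_amplitudes_mpa):
        rescaled_peak = field.focal_peak * amp / train.peak_amplitude_mpa
        if not rescaled_peak > p_l:  # strict: edge pulses are not lesion-capable
            continue
        volumes[i] = suprathreshold_volume(field, p_l * field.focal_peak / rescaled_peak)
    value = float(volumes.sum() * time_weight_s)
    return ExposureIntegral(value, volumes, time_weight_s)


def swept_static_ratio(
    field: PressureField,
    p_l: float = DEFAULT_LESION_THRESHOLD_MPA,
    peak_mpa: float = 4.0,
    width_ms: float = 2.0,
    prf_khz: float = 4.0,
) -> dict:
    """Gaussian:square exposure-integral ratio at equal peak (percent).

    Returns a report with both absolute integrals (uL.s, using the default
    1/prf time weight) and the normalisation-free percentage ratio.
    """
    square = build_pulse_train("square", peak_mpa, width_ms, prf_khz)
    gauss = build_pulse_train("gaussian", peak_mpa, width_ms, prf_khz)
    e_sq = exposure_integral(square, field, p_l)
    e_ga = exposure_integral(gauss, field, p_l)
    return {
        "square_uL_s": e_sq.value_ul_s,
        "gaussian_uL_s": e_ga.value_ul_s,
        "ratio_pct": 100.0 * e_ga.value_ul_s / e_sq.value_ul_s,
    }
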