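"""Axisymmetric pressure field of a focused single-element therapy transducer.

The therapy source is a spherically curved bowl (concave single element)
driven by a short tone burst.  The linear, lossless water-path field is
computed with the spatial impulse-response method: for a spherical cap the
velocity-potential impulse response at any field point has a closed form,

    h(t) = c * R_c * alpha(ct) / (pi * d),

where ``R_c`` is the radius of curvature (= geometric focal length), ``d``
the distance of the field point from the centre of curvature and ``alpha``
the half-arc angle of the iso-distance circle that lies on the cap.  The
pressure waveform follows from  p = rho * d/dt (v * h)  and the map stored
here is the per-pulse peak rarefactional (negative) pressure amplitude,
normalised so that its spatial maximum equals the configured focal peak.

Axisymmetry lets the field be stored as a half-plane over (radial, axial)
coordinates; rotating it about the beam axis yields the 3-D beam volume.
Units: mm for geometry, MPa for pressure, uL for volumes (1 mm^3 = 1 uL).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "TransducerSpec",
    "GridSpec",
    "PressureField",
    "ThresholdRegion",
    "FieldResolutionError",
    "NoLesionRegionError",
    "compute_field",
    "threshold_region",
    "beam_mean_radius",
    "suprathreshold_volume",
]


class FieldResolutionError(ValueError):
    """Grid too coarse to resolve the focal lobe."""


class NoLesionRegionError(ValueError):
    """No part of the field exceeds the lesion-formation threshold."""


# Default lesion-formation threshold (free-field peak rarefactional pressure).
DEFAULT_LESION_THRESHOLD_MPA = 2.0


@dataclass(frozen=True)
class TransducerSpec:
    """Geometry and drive of the focused therapy transducer.

    Defaults describe a 1.9-cm diameter, 3.8-cm focal length single-element
    bowl excited at 1.5 MHz with 5-cycle bursts and a 4 MPa peak
    rarefactional pressure amplitude (PRPA) at the focus.
    """

    aperture_diameter_mm: float = 19.0
    focal_length_mm: float = 38.0
    center_frequency_mhz: float = 1.5
    cycles_per_pulse: int = 5
    sound_speed_m_s: float = 1500.0
    focal_peak_pressure_mpa: float = 4.0

    def __post_init__(self) -> None:
        vals = (
            self.aperture_diameter_mm,
            self.focal_length_mm,
            self.center_frequency_mhz,
            self.cycles_per_pulse,
            self.sound_speed_m_s,
            self.focal_peak_pressure_mpa,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all transducer parameters must be positive")
        if self.aperture_diameter_mm >= 2 * self.focal_length_mm:
            raise ValueError("aperture diameter must be smaller than twice the focal length")

    @property
    def wavelength_mm(self) -> float:
        return self.sound_speed_m_s / 1000.0 / self.center_frequency_mhz

    @property
    def f_number(self) -> float:
        return self.focal_length_mm / self.aperture_diameter_mm

    def predicted_lateral_width_mm(self) -> float:
        """A-priori estimate of the -6 dB focal-lobe lateral full width.

        Uses the standard focused-aperture beamwidth scaling
        ``w = 1.41 * lambda * F/D``; used only to validate grid resolution
        before the field is computed.
        """
        return 1.41 * self.wavelength_mm * self.f_number


@dataclass(frozen=True)
class GridSpec:
    """Half-plane sampling grid for the field map.

    ``z`` spans the beam axis (z=0 at the transducer apex), ``r`` the radial
    coordinate.  Defaults place >= 25 samples across the focal lobe.
    """

    r_max_mm: float = 5.0
    dr_mm: float = 0.05
    z_min_mm: float | None = None  # default focal_length - 25
    z_max_mm: float | None = None  # default focal_length + 25
    dz_mm: float = 0.25

    def coords(self, spec: TransducerSpec) -> tuple[np.ndarray, np.ndarray]:
        z_min = self.z_min_mm if self.z_min_mm is not None else spec.focal_length_mm - 25.0
        z_max = self.z_max_mm if self.z_max_mm is not None else spec.focal_length_mm + 25.0
        r = np.arange(0.0, self.r_max_mm + 0.5 * self.dr_mm, self.dr_mm)
        z = np.arange(z_min, z_max + 0.5 * self.dz_mm, self.dz_mm)
        return r, z


@dataclass
class PressureField:
    """Axisymmetric map of peak rarefactional pressure amplitude.

    ``amplitude[i, j]`` is the per-pulse peak negative pressure (MPa) at
    radial position ``r_coords[i]`` and axial position ``z_coords[j]``.
    Only the r >= 0 half-plane is stored; the field at (-r, z) equals the
    field at (r, z) by axisymmetry.
    """

    r_coords: np.ndarray
    z_coords: np.ndarray
    amplitude: np.ndarray
    focal_peak: float

    def __post_init__(self) -> None:
        self.r_coords = np.asarray(self.r_coords, dtype=float)
        self.z_coords = np.asarray(self.z_coords, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.shape != (self.r_coords.size, self.z_coords.size):
            raise ValueError("amplitude shape must be (len(r), len(z))")
        if np.any(np.diff(self.r_coords) <= 0) or self.r_coords[0] != 0.0:
            raise ValueError("r_coords must increase monotonically from 0")
        if np.any(np.diff(self.z_coords) <= 0):
            raise ValueError("z_coords must increase monotonically")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")

    @property
    def focus_index(self) -> tuple[int, int]:
        return tuple(np.unravel_index(np.argmax(self.amplitude), self.amplitude.shape))

    def at(self, r: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of the amplitude at (|r|, z); 0 outside."""
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (self.r_coords, self.z_coords),
            self.amplitude,
            bounds_error=False,
            fill_value=0.0,
        )
        scalar = np.isscalar(r) and np.isscalar(z)
        r_arr, z_arr = np.broadcast_arrays(np.abs(np.asarray(r, float)), np.asarray(z, float))
        pts = np.stack([r_arr, z_arr], axis=-1)
        out = interp(pts)
        return float(out[0]) if scalar else out

    def scaled(self, peak: float) -> "PressureField":
        """Linearly rescaled copy with the given focal peak (linear model)."""
        factor = peak / self.focal_peak
        return PressureField(self.r_coords, self.z_coords, self.amplitude * factor, peak)

    def boundary_radius(self, threshold: float) -> np.ndarray:
        """Largest radius with amplitude >= threshold, per axial sample.

        The crossing is located by linear interpolation between the last
        suprathreshold sample and its outward neighbour; zero where the
        whole column is below threshold.
        """
        return _boundary_radius(self.amplitude, self.r_coords, threshold)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            r_coords=self.r_coords,
            z_coords=self.z_coords,
            amplitude=self.amplitude,
            focal_peak=np.array(self.focal_peak),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PressureField":
        with np.load(path) as data:
            return cls(
                data["r_coords"], data["z_coords"], data["amplitude"], float(data["focal_peak"])
            )


@dataclass
class ThresholdRegion:
    """Geometry of the beam region above a lesion-formation threshold.

    ``lateral_extent`` is the full width of the suprathreshold set measured
    at the axial position of the field maximum; ``axial_extent`` is its
    length along r = 0.  ``volume`` is the solid of revolution of the
    boundary radius about the beam axis (uL).
    """

    threshold: float
    lateral_extent: float
    axial_extent: float
    z_coords: np.ndarray
    boundary_radius_mm: np.ndarray
    volume: float

    @property
    def is_empty(self) -> bool:
        return self.volume == 0.0 and not np.any(self.boundary_radius_mm > 0)

    def boundary_radius(self, z: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(z, float), self.z_coords, self.boundary_radius_mm)

    def report(self) -> dict:
        return {
            "threshold_MPa": self.threshold,
            "lateral_extent_mm": self.lateral_extent,
            "axial_extent_mm": self.axial_extent,
            "volume_uL": self.volume,
        }


# ---------------------------------------------------------------------------
# field computation
# ---------------------------------------------------------------------------

def compute_field(
    spec: TransducerSpec = TransducerSpec(),
    grid: GridSpec = GridSpec(),
    *,
    n_radius_samples: int = 128,
    oversample: int = 16,
    max_harmonic: float = 3.0,
) -> PressureField:
    """Compute the pulsed pressure amplitude field of the focused bowl.

    For every grid point the closed-form spatial impulse response of the
    spherical cap is sampled over the point's arrival-time window, Fourier
    transformed, multiplied with the tone-burst spectrum and the time
    derivative taken in the frequency domain; the per-pulse peak negative
    pressure is then read off the reconstructed waveform.  The map is
    normalised so its maximum equals ``spec.focal_peak_pressure_mpa``.

    Parameters
    ----------
    n_radius_samples:
        Samples across each point's arrival window (quadrature resolution).
    oversample:
        Temporal sampling rate as a multiple of the centre frequency.
    max_harmonic:
        Spectrum truncation, in multiples of the centre frequency.
    """
    r, z = grid.coords(spec)
    lobe = spec.predicted_lateral_width_mm()
    if lobe / grid.dr_mm < 8:
        raise FieldResolutionError(
            f"radial step {grid.dr_mm} mm places fewer than 8 samples across the "
            f"predicted {lobe:.2f} mm focal lobe"
        )

    c = spec.sound_speed_m_s / 1000.0  # mm/us
    f0 = spec.center_frequency_mhz  # cycles/us
    rc = spec.focal_length_mm
    ap = spec.aperture_diameter_mm / 2.0
    theta_a = np.arcsin(ap / rc)

    rr, zz = np.meshgrid(r, z, indexing="ij")
    pts_r = rr.ravel()
    pts_z = zz.ravel()
    n_pts = pts_r.size

    d = np.sqrt(pts_r**2 + (pts_z - rc) ** 2)
    d = np.maximum(d, 1e-6)
    cospsi = np.clip((rc - pts_z) / d, -1.0, 1.0)
    psi = np.arccos(cospsi)
    sinpsi = np.sin(psi)

    # arrival window: surface polar angles about the field-point direction
    th_lo = np.clip(psi - theta_a, 0.0, np.pi)
    th_hi = np.clip(psi + theta_a, 0.0, np.pi)
    r_a = np.sqrt(rc**2 + d**2 - 2 * rc * d * np.cos(th_lo))
    r_b = np.sqrt(rc**2 + d**2 - 2 * rc * d * np.cos(th_hi))
    r_lo = np.minimum(r_a, r_b)
    r_hi = np.maximum(r_a, r_b)

    u = np.linspace(0.0, 1.0, n_radius_samples)
    r_grid = r_lo[:, None] + (r_hi - r_lo)[:, None] * u[None, :]
    d_r = (r_hi - r_lo) / (n_radius_samples - 1)

    costh = np.clip((rc**2 + d[:, None] ** 2 - r_grid**2) / (2 * rc * d[:, None]), -1.0, 1.0)
    sinth = np.sqrt(1.0 - costh**2)
    denom = sinth * sinpsi[:, None]
    num = np.cos(theta_a) - costh * cospsi[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        carg = np.where(
            denom > 1e-12,
            num / np.maximum(denom, 1e-300),
            np.where(num <= 0.0, -1.0, 1.0),
        )
    alpha = np.arccos(np.clip(carg, -1.0, 1.0))  # half-arc angle on the cap

    # tone burst and time/frequency grid
    t_burst = spec.cycles_per_pulse / f0
    spread = float((r_hi - r_lo).max()) / c
    t_rec = t_burst + spread + 2.0
    fs = oversample * f0
    n_t = int(2 ** np.ceil(np.log2(t_rec * fs)))
    freqs = np.fft.rfftfreq(n_t, d=1.0 / fs)
    t_vec = np.arange(n_t) / fs
    v = np.where(t_vec <= t_burst, np.sin(2 * np.pi * f0 * t_vec), 0.0)
    v_f = np.fft.rfft(v)

    weights = np.ones(n_radius_samples)
    weights[0] = weights[-1] = 0.5
    alpha_w = alpha * weights[None, :]

    h_f = np.zeros((n_pts, freqs.size), dtype=complex)
    active = np.nonzero((freqs > 0) & (freqs <= max_harmonic * f0))[0]
    rel = r_grid - r_lo[:, None]
    for j in active:
        k = 2 * np.pi * freqs[j] / c
        h_f[:, j] = (alpha_w * np.exp(-1j * k * rel)).sum(axis=1) * d_r
    h_f *= (rc / (np.pi * d))[:, None] / c

    p_f = v_f[None, :] * h_f * (1j * 2 * np.pi * freqs)[None, :]
    p_t = np.fft.irfft(p_f, n=n_t, axis=1)
    pnp = np.maximum(-p_t, 0.0).max(axis=1).reshape(r.size, z.size)

    pnp *= spec.focal_peak_pressure_mpa / pnp.max()
    return PressureField(r, z, pnp, spec.focal_peak_pressure_mpa)


# ---------------------------------------------------------------------------
# threshold-region geometry
# ---------------------------------------------------------------------------

def _boundary_radius(amplitude: np.ndarray, r: np.ndarray, threshold: float) -> np.ndarray:
    """Largest radius with amplitude >= threshold per column, subpixel."""
    n_r, n_z = amplitude.shape
    above = amplitude >= threshold
    any_above = above.any(axis=0)
    # outermost suprathreshold sample per column
    idx = np.where(any_above, n_r - 1 - np.argmax(above[::-1, :], axis=0), 0)
    br = np.zeros(n_z)
    cols = np.nonzero(any_above)[0]
    for j in cols:
        i = idx[j]
        if i == n_r - 1:
            br[j] = r[-1]
        else:
            hi, lo = amplitude[i, j], amplitude[i + 1, j]
            frac = (hi - threshold) / (hi - lo) if hi > lo else 0.0
            br[j] = r[i] + frac * (r[i + 1] - r[i])
    return br


def _axis_extent(values: np.ndarray, coords: np.ndarray, threshold: float) -> float:
    """Length of the suprathreshold interval along a 1-D profile, subpixel."""
    above = values >= threshold
    if not above.any():
        return 0.0
    idx = np.nonzero(above)[0]
    i0, i1 = idx.min(), idx.max()
    lo = coords[i0]
    if i0 > 0 and values[i0] > values[i0 - 1]:
        lo -= (values[i0] - threshold) / (values[i0] - values[i0 - 1]) * (coords[i0] - coords[i0 - 1])
    hi = coords[i1]
    if i1 < values.size - 1 and values[i1] > values[i1 + 1]:
        hi += (values[i1] - threshold) / (values[i1] - values[i1 + 1]) * (coords[i1 + 1] - coords[i1])
    return float(hi - lo)


def threshold_region(field: PressureField, p_l: float = DEFAULT_LESION_THRESHOLD_MPA) -> ThresholdRegion:
    """Geometry and volume of the region with amplitude >= p_l.

    The suprathreshold set is closed (amplitude equal to the threshold is
    inside).  Volume is the solid of revolution of the boundary radius,
    integrated with the trapezoidal rule; an empty region is a valid result
    with zero volume.
    """
    if p_l <= 0:
        raise ValueError("threshold must be positive")
    br = field.boundary_radius(p_l)
    volume = float(np.trapezoid(np.pi * br**2, field.z_coords))
    if not np.any(br > 0):
        return ThresholdRegion(p_l, 0.0, 0.0, field.z_coords, br, 0.0)

    _, j_focus = field.focus_index
    lateral = 2.0 * float(_boundary_radius(field.amplitude[:, j_focus : j_focus + 1], field.r_coords, p_l)[0])
    axial = _axis_extent(field.amplitude[0, :], field.z_coords, p_l)
    return ThresholdRegion(p_l, lateral, axial, field.z_coords, br, volume)


def suprathreshold_volume(field: PressureField, p_l: float) -> float:
    """Solid-of-revolution volume (uL) of the region with amplitude >= p_l."""
    br = field.boundary_radius(p_l)
    return float(np.trapezoid(np.pi * br**2, field.z_coords))


def beam_mean_radius(field: PressureField, p_l: float = DEFAULT_LESION_THRESHOLD_MPA) -> float:
    """Axial average of the suprathreshold boundary radius (mm).

    Averages boundary_radius(z) over the axial samples where it is positive;
    raises :class:`NoLesionRegionError` for an empty region.
    """
    br = field.boundary_radius(p_l)
    occupied = br > 0
    if not occupied.any():
        raise NoLesionRegionError(f"no part of the field exceeds {p_l} MPa")
    return float(br[occupied].mean())


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

def spec_from_config(cfg: dict) -> tuple[TransducerSpec, GridSpec, float]:
    """Build (TransducerSpec, GridSpec, threshold) from a config mapping.

    Recognised keys: aperture_mm, focus_mm, freq_MHz, cycles, peak_MPa,
    threshold_MPa and an optional ``grid`` sub-mapping with r_max_mm, dr_mm,
    z_min_mm, z_max_mm, dz_mm.
    """
    spec = TransducerSpec(
        aperture_diameter_mm=cfg.get("aperture_mm", 19.0),
        focal_length_mm=cfg.get("focus_mm", 38.0),
        center_frequency_mhz=cfg.get("freq_MHz", 1.5),
        cycles_per_pulse=cfg.get("cycles", 5),
        sound_speed_m_s=cfg.get("sound_speed_m_s", 1500.0),
        focal_peak_pressure_mpa=cfg.get("peak_MPa", 4.0),
    )
    g = cfg.get("grid", {})
    grid = GridSpec(
        r_max_mm=g.get("r_max_mm", 5.0),
        dr_mm=g.get("dr_mm", 0.05),
        z_min_mm=g.get("z_min_mm"),
        z_max_mm=g.get("z_max_mm"),
        dz_mm=g.get("dz_mm", 0.25),
    )
    return spec, grid, cfg.get("threshold_MPa", DEFAULT_LESION_THRESHOLD_MPA)


def write_report(region: ThresholdRegion, mean_radius: float, path: str | Path) -> None:
    report = dict(region.report(), mean_radius_mm=mean_radius)
    Path(path).write_text(json.dumps(report, indent=2))
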