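"""Paraxial design math for chirped-AOD raster scanning.

A linear frequency chirp travelling across an acousto-optical deflector (AOD)
acts on the optical beam like a moving cylindrical lens: the instantaneous
deflection angle sweeps while the beam acquires a constant divergence set by
the chirp rate.  With matched chirps on an orthogonal AOD pair, that
divergence is identical on both axes and can be compensated by a single
spherical convex lens (the divergence compensation lens, DvCL) placed after
the pair.  The functions here compute, in closed form:

* the equivalent focal length of the chirp "lens",
* the line time needed to collimate the beam through a given DvCL,
* full-frame geometry (pixels, frame rate, FOV, pixel size, dark periphery),
* the axial focal shift obtained by detuning the chirp rate
  (multi-layer scanning),
* ultrafast-pulse utilities (autocorrelation deconvolution, dispersive
  broadening).

All quantities are SI unless a name says otherwise.  The model is thin-lens
paraxial throughout; diffraction efficiency and aberrations are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "AODSpec",
    "RelaySpec",
    "ChirpProgram",
    "FrameGeometry",
    "PulseSpec",
    "InvalidSpecError",
    "ConfigurationError",
    "DegenerateFrameError",
    "InfeasibleScanError",
    "chirp_focal_length",
    "nominal_line_time",
    "nominal_chirp_rate",
    "chirp_program_for_dvcl",
    "raster_frame_geometry",
    "fov_and_pixel_size",
    "focal_depth_shift",
    "transition_time",
    "dark_periphery_fraction",
    "pulse_from_autocorrelation",
    "pulse_broadening",
    "gdd_for_broadening",
]

_LN2 = math.log(2.0)


class InvalidSpecError(ValueError):
    """A physical spec (AOD or relay) is inconsistent or non-physical."""


class ConfigurationError(ValueError):
    """A required optional element (e.g. the DvCL) is missing."""


class DegenerateFrameError(ValueError):
    """The requested chirp program yields fewer than 2 pixels per line."""


class InfeasibleScanError(ValueError):
    """Line timing cannot accommodate the AOD transition time."""


@dataclass(frozen=True)
class AODSpec:
    """Physical constants of the deflector pair.

    acoustic_velocity : m/s, speed of the acoustic wave in the crystal.
        Default 650 m/s (TeO2 slow-shear mode).
    bandwidth : Hz, frequency span of the linear chirp (default 30 MHz).
    center_frequency : Hz, informational carrier frequency.
    aperture : m, clear input aperture of the deflector.
    beam_diameter : m, illuminated beam diameter; sets the acoustic fill
        (transition) time between scan lines.
    """

    acoustic_velocity: float = 650.0
    bandwidth: float = 30e6
    center_frequency: float = 90e6
    aperture: float = 15e-3
    beam_diameter: float = 8.45e-3

    def __post_init__(self) -> None:
        for name in ("acoustic_velocity", "bandwidth", "center_frequency",
                     "aperture", "beam_diameter"):
            if not getattr(self, name) > 0:
                raise InvalidSpecError(f"AODSpec.{name} must be positive")
        if self.beam_diameter > self.aperture:
            raise InvalidSpecError("beam_diameter exceeds the AOD aperture")


@dataclass(frozen=True)
class RelaySpec:
    """Wavelength and focal lengths of the relay from AOD to sample.

    f_dvcl is the divergence compensation lens; ``None`` means the lens is
    removed (random-access pointing mode), in which case raster-mode
    calculations raise :class:`ConfigurationError`.
    """

    wavelength: float = 920e-9
    f_dvcl: Optional[float] = 1.000
    f_scan: float = 0.100
    f_tube: float = 0.200
    f_objective: float = 0.018

    def __post_init__(self) -> None:
        if not 200e-9 < self.wavelength < 2000e-9:
            raise InvalidSpecError("wavelength outside (200 nm, 2000 nm)")
        for name in ("f_scan", "f_tube", "f_objective"):
            if not getattr(self, name) > 0:
                raise InvalidSpecError(f"RelaySpec.{name} must be positive")
        if self.f_dvcl is not None and not self.f_dvcl > 0:
            raise InvalidSpecError("f_dvcl must be positive or None")

    def require_dvcl(self) -> float:
        if self.f_dvcl is None:
            raise ConfigurationError(
                "raster-mode calculation requires a DvCL (RelaySpec.f_dvcl)")
        return self.f_dvcl


@dataclass(frozen=True)
class ChirpProgram:
    """A concrete line-scan program: chirp rate, line time, digitizer rate.

    ``line_time_rounding`` is the quantum used when *reporting* line times
    (default 0.1 us); set to ``None`` for the continuous (un-quantized)
    convention.
    """

    chirp_rate: float
    line_time: float
    sample_rate: float = 10e6
    line_time_rounding: Optional[float] = 0.1e-6

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise InvalidSpecError("sample_rate must be positive")
        if not self.line_time > 0:
            raise InvalidSpecError("line_time must be positive")


@dataclass(frozen=True)
class FrameGeometry:
    """Derived geometry of one raster frame."""

    pixels_per_line: int
    lines_per_frame: int
    frame_rate: float
    pixel_size: float
    fov_width: float
    dark_fraction: float


@dataclass(frozen=True)
class PulseSpec:
    """An ultrafast pulse: FWHM width, shape, and group delay dispersion."""

    width_fwhm: float
    shape: str = "sech2"
    gdd: float = 0.0

    def __post_init__(self) -> None:
        if not self.width_fwhm > 0:
            raise InvalidSpecError("width_fwhm must be positive")
        if self.shape not in ("sech2", "gaussian"):
            raise InvalidSpecError(f"unknown pulse shape {self.shape!r}")


# ---------------------------------------------------------------------------
# Chirp lens and line timing
# ---------------------------------------------------------------------------

def chirp_focal_length(aod: AODSpec, relay: RelaySpec,
                       chirp_rate: float) -> float:
    """Equivalent focal length of the chirp-induced cylindrical lens.

    ``F = v**2 / (lambda * |r|)`` with the sign of the chirp rate carried
    through (positive = diverging for an up-chirp).  A zero rate returns
    ``+inf`` (no focal power).
    """
    if not math.isfinite(chirp_rate):
        raise InvalidSpecError("chirp_rate must be finite")
    if chirp_rate == 0.0:
        return math.inf
    v = aod.acoustic_velocity
    lam = relay.wavelength
    return v * v / (lam * chirp_rate)


def nominal_chirp_rate(aod: AODSpec, relay: RelaySpec) -> float:
    """Chirp rate (Hz/s) whose divergence the DvCL exactly collimates."""
    f = relay.require_dvcl()
    v = aod.acoustic_velocity
    return v * v / (relay.wavelength * f)


def nominal_line_time(aod: AODSpec, relay: RelaySpec,
                      rounding: Optional[float] = 0.1e-6) -> float:
    """Time to chirp across the full AOD bandwidth at the nominal rate.

    ``T = B * lambda * f_dvcl / v**2``.  By default the result is quantized
    to the 0.1-us reporting grid; pass ``rounding=None`` for the continuous
    value.
    """
    f = relay.require_dvcl()
    v = aod.acoustic_velocity
    t = aod.bandwidth * relay.wavelength * f / (v * v)
    if rounding is not None:
        t = round(t / rounding) * rounding
    return t


def chirp_program_for_dvcl(aod: AODSpec, relay: RelaySpec,
                           sample_rate: float = 10e6,
                           rounding: Optional[float] = 0.1e-6
                           ) -> ChirpProgram:
    """Build the chirp program that collimates through the configured DvCL."""
    t = nominal_line_time(aod, relay, rounding=rounding)
    return ChirpProgram(chirp_rate=aod.bandwidth / t, line_time=t,
                        sample_rate=sample_rate, line_time_rounding=rounding)


# ---------------------------------------------------------------------------
# Frame geometry
# ---------------------------------------------------------------------------

def _pixels_per_line(line_time: float, sample_rate: float) -> int:
    # floor with a one-ppm guard against float representation of the
    # quantized line time (e.g. 65.3 us * 10 MHz must count as 653)
    n = line_time * sample_rate
    return int(math.floor(n + 1e-6))


def fov_and_pixel_size(aod: AODSpec, relay: RelaySpec,
                       pixels_per_line: int) -> tuple[float, float]:
    """Field of view and pixel size at the sample plane.

    The AOD sweeps a full mechanical angle ``lambda*B/v``; the scan/tube
    telescope relays it with angular magnification ``f_scan/f_tube`` onto the
    objective pupil, so the FOV is ``(lambda*B/v)*(f_scan/f_tube)*f_obj``.
    """
    if pixels_per_line < 1:
        raise InvalidSpecError("pixels_per_line must be >= 1")
    scan_angle = relay.wavelength * aod.bandwidth / aod.acoustic_velocity
    fov = scan_angle * (relay.f_scan / relay.f_tube) * relay.f_objective
    return fov, fov / pixels_per_line


def transition_time(aod: AODSpec) -> float:
    """Acoustic fill time between scan lines: beam diameter / velocity."""
    return aod.beam_diameter / aod.acoustic_velocity


def dark_periphery_fraction(program: ChirpProgram, transition: float) -> float:
    """Fraction of the line period lost to the inter-line transition."""
    if transition < 0:
        raise InvalidSpecError("transition time must be non-negative")
    if transition >= program.line_time:
        raise InfeasibleScanError(
            f"transition time {transition:.3g} s >= line time "
            f"{program.line_time:.3g} s")
    return transition / program.line_time


def raster_frame_geometry(aod: AODSpec, relay: RelaySpec,
                          program: ChirpProgram) -> FrameGeometry:
    """Full-frame geometry under the quantized-line-time convention.

    Pixels per line = floor(line_time * sample_rate); the slow-axis chirp
    range is set one pixel short, so lines per frame = pixels - 1 and the
    frame rate is 1 / (lines * line_time).
    """
    ppl = _pixels_per_line(program.line_time, program.sample_rate)
    if ppl < 2:
        raise DegenerateFrameError(
            f"{ppl} pixel(s) per line; need at least 2")
    lines = ppl - 1
    frame_rate = 1.0 / (lines * program.line_time)
    fov, px = fov_and_pixel_size(aod, relay, ppl)
    dark = dark_periphery_fraction(program, transition_time(aod))
    return FrameGeometry(pixels_per_line=ppl, lines_per_frame=lines,
                         frame_rate=frame_rate, pixel_size=px,
                         fov_width=fov, dark_fraction=dark)


# ---------------------------------------------------------------------------
# Multi-layer depth control
# ---------------------------------------------------------------------------

def focal_depth_shift(aod: AODSpec, relay: RelaySpec,
                      chirp_rate: float) -> float:
    """Axial focus shift from detuning the chirp rate (thin-lens, exact).

    Residual vergence after the DvCL is ``V0 = 1/f_dvcl - 1/F_chirp``; the
    afocal scan/tube telescope maps it to the objective pupil as
    ``V1 = V0*(f_scan/f_tube)**2``; the focus then sits at
    ``1/(1/f_obj + V1)`` from the objective.  Sign convention: positive
    shift = focus farther from the objective (deeper into the sample).  The
    shift is zero at the nominal rate, monotonic in the rate, and
    approximately linear near nominal.
    """
    f_dvcl = relay.require_dvcl()
    if chirp_rate == 0.0:
        raise InfeasibleScanError(
            "zero chirp rate: no chirp lens, defocus is unbounded")
    v = aod.acoustic_velocity
    # 1/F_chirp without the infinity special case
    inv_f_chirp = relay.wavelength * chirp_rate / (v * v)
    v0 = 1.0 / f_dvcl - inv_f_chirp
    v1 = v0 * (relay.f_scan / relay.f_tube) ** 2
    f_obj = relay.f_objective
    denom = 1.0 / f_obj + v1
    if denom <= 0:
        raise InfeasibleScanError("beam too convergent: focus beyond infinity")
    return 1.0 / denom - f_obj


# ---------------------------------------------------------------------------
# Ultrafast pulse utilities
# ---------------------------------------------------------------------------

_DECONV = {"sech2": 0.65, "gaussian": 1.0 / math.sqrt(2.0)}


def pulse_from_autocorrelation(ac_fwhm: float, shape: str = "sech2") -> float:
    """Pulse FWHM from an intensity-autocorrelation FWHM.

    Uses the standard deconvolution factors: 0.65 for a sech^2 pulse,
    1/sqrt(2) for a Gaussian pulse.
    """
    if not ac_fwhm > 0:
        raise InvalidSpecError("autocorrelation FWHM must be positive")
    try:
        factor = _DECONV[shape]
    except KeyError:
        raise InvalidSpecError(
            f"unknown pulse shape {shape!r}; expected 'sech2' or 'gaussian'"
        ) from None
    return factor * ac_fwhm


def pulse_broadening(pulse: PulseSpec) -> float:
    """Pulse width after group delay dispersion.

    Gaussian-equivalent formula
    ``tau_out = tau_in * sqrt(1 + (4*ln2*GDD/tau_in**2)**2)``, applied to both
    shapes (exact sech^2 propagation differs by a few percent and is not
    modelled).  Even in the sign of the GDD.
    """
    tau = pulse.width_fwhm
    x = 4.0 * _LN2 * pulse.gdd / (tau * tau)
    return tau * math.sqrt(1.0 + x * x)


def gdd_for_broadening(tau_in: float, tau_out: float) -> float:
    """Magnitude of GDD that broadens ``tau_in`` to ``tau_out`` (both FWHM)."""
    if not tau_in > 0 or tau_out < tau_in:
        raise InvalidSpecError("need tau_out >= tau_in > 0")
    ratio = tau_out / tau_in
    return tau_in * tau_in * math.sqrt(ratio * ratio - 1.0) / (4.0 * _LN2)


def _with_dvcl(relay: RelaySpec, f_dvcl: float) -> RelaySpec:
    """Convenience: the same relay with a different DvCL."""
    return replace(relay, f_dvcl=f_dvcl)
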