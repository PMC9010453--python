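"""Calibrated sound spectra and species-specific noise assessment.

Imaging-rig noise is broadband, so a power spectral density (dB SPL/Hz)
cannot be compared directly against hearing thresholds, which are measured
with pure tones (dB SPL).  The assessment implemented here integrates the
noise spectrum through a bank of auditory filters whose bandwidths follow
the experimental species' frequency selectivity, producing an *excitation
pattern* in dB SPL that can sit on the same axes as the audiogram.  The
two-step report is then:

1. a calibrated PSD at 1-Hz resolution (``compute_psd``), and
2. the species excitation pattern against the hearing threshold
   (``excitation_pattern`` + ``threshold_exceedance``).

Auditory filters are symmetric, level-independent rounded-exponential
(roex) filters ``W(g) = (1 + p*g) * exp(-p*g)`` with ``g = |f - fc| / fc``
and ``p = 4*fc / Bs(fc)``, so that the equivalent rectangular bandwidth of
the filter equals the species tuning bandwidth ``Bs(fc)``.  Level-dependent
asymmetry and specific-loudness compression of full loudness models are
deliberately not implemented.

Reference pressure is 20 uPa throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import yaml
from scipy import signal as _signal
from scipy.interpolate import PchipInterpolator

P_REF = 20e-6          # Pa
DB_FLOOR = -120.0      # dB SPL/Hz sentinel for zero-power bins
DEFAULT_CROSSOVER_HZ = 23e3

__all__ = [
    "CalibratedRecording",
    "PowerSpectrumDensity",
    "SpeciesProfile",
    "ExcitationPattern",
    "ExceedanceSummary",
    "DataQualityError",
    "CoverageError",
    "ProfileRangeError",
    "compute_psd",
    "band_level",
    "merge_psds",
    "roex_weights",
    "excitation_pattern",
    "threshold_exceedance",
    "load_species_profile",
    "save_species_profile",
    "microphone_noise_floor",
    "builtin_species",
]


class DataQualityError(ValueError):
    """Recording contains NaN/Inf or clipped samples."""


class CoverageError(ValueError):
    """Spectra do not cover the requested band or crossover."""


class ProfileRangeError(ValueError):
    """Query outside the species' stated hearing range."""


@dataclass
class CalibratedRecording:
    """A pressure-calibrated sound recording.

    ``samples`` are in Pa.  Use :meth:`from_wav` to apply microphone
    sensitivity and amplifier gain to a raw WAV file.
    """

    samples: np.ndarray
    sample_rate: float = 200e3
    mic_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @classmethod
    def from_wav(cls, path: Union[str, Path],
                 sensitivity_mv_per_pa: Optional[float] = None,
                 gain_db: float = 0.0,
                 full_scale_volts: float = 1.0,
                 mic_id: str = "") -> "CalibratedRecording":
        """Read a WAV file and convert to Pa.

        Integer PCM is normalized to [-1, 1) full scale, scaled to volts by
        ``full_scale_volts``, then to Pa via the microphone sensitivity
        (mV/Pa) and amplifier gain (dB).  If a JSON sidecar ``<path>.json``
        exists with keys ``sensitivity_mv_per_pa``, ``gain_db``,
        ``full_scale_volts`` and ``mic_id``, it supplies any argument not
        given explicitly.
        """
        from scipy.io import wavfile

        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = {}
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        if sensitivity_mv_per_pa is None:
            sensitivity_mv_per_pa = meta.get("sensitivity_mv_per_pa")
        if sensitivity_mv_per_pa is None:
            raise ValueError("microphone sensitivity (mV/Pa) is required")
        gain_db = meta.get("gain_db", gain_db)
        full_scale_volts = meta.get("full_scale_volts", full_scale_volts)
        mic_id = mic_id or meta.get("mic_id", "")

        rate, data = wavfile.read(path)
        data = np.asarray(data)
        if data.ndim > 1:
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / float(np.iinfo(data.dtype).max + 1)
        else:
            data = data.astype(float)
        volts = data * full_scale_volts
        pa = volts / (sensitivity_mv_per_pa * 1e-3 * 10 ** (gain_db / 20.0))
        return cls(samples=pa, sample_rate=float(rate), mic_id=mic_id)


@dataclass
class PowerSpectrumDensity:
    """PSD on a uniform 1-Hz grid, in dB SPL/Hz re 20 uPa."""

    frequencies: np.ndarray
    levels: np.ndarray
    mic_id: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.frequencies.shape != self.levels.shape:
            raise ValueError("frequencies and levels must match in shape")
        if self.frequencies.size >= 2:
            df = np.diff(self.frequencies)
            if not np.allclose(df, 1.0, atol=1e-6):
                raise ValueError("frequency grid must be uniform at 1 Hz")
        if not np.all(np.isfinite(self.levels)):
            raise ValueError("levels must be finite (use the dB floor)")

    def to_csv(self, path: Union[str, Path]) -> None:
        import pandas as pd
        pd.DataFrame({"frequency_hz": self.frequencies,
                      "level_db": self.levels}).to_csv(path, index=False)


def compute_psd(recording: CalibratedRecording,
                method: str = "fft",
                clip_limit: Optional[float] = None) -> PowerSpectrumDensity:
    """Power spectral density binned to 1-Hz resolution.

    ``method='fft'`` Fourier-transforms the entire record and power-sums the
    native FFT bins into 1-Hz bins centred on integer frequencies (the
    single-FFT convention).  ``method='welch'`` averages 1-s Hann segments
    with 50% overlap for lower variance.  Output bins are dB SPL/Hz; since
    the bin width is 1 Hz, each bin's level is also the band level of that
    bin.  The DC component is removed before analysis, so summing bin powers
    recovers the mean-square (AC) pressure.
    """
    x = recording.samples
    if not np.all(np.isfinite(x)):
        raise DataQualityError("recording contains NaN or Inf samples")
    if clip_limit is not None and np.sum(np.abs(x) >= clip_limit) > 2:
        raise DataQualityError("recording appears clipped")
    fs = recording.sample_rate
    if x.size < fs:
        raise ValueError("need at least 1 s of samples for 1-Hz bins")

    if method == "fft":
        x = x - x.mean()
        n = x.size
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        # one-sided power per FFT bin (Pa^2), Parseval-exact
        power = (np.abs(spec) ** 2) / (n * n)
        power[1:] *= 2.0
        if n % 2 == 0:
            power[-1] /= 2.0
        centers = np.arange(1, int(np.floor(fs / 2.0)))
        idx = np.rint(freqs).astype(int)
        binned = np.bincount(idx, weights=power,
                             minlength=centers[-1] + 1)
        # fold sub-0.5 Hz residue into the first bin so no power is lost
        bin_power = binned[1:centers.size + 1]
        bin_power[0] += binned[0]
    elif method == "welch":
        nper = int(fs)
        freqs, pxx = _signal.welch(x - x.mean(), fs=fs, window="hann",
                                   nperseg=nper, noverlap=nper // 2,
                                   detrend=False)
        centers = np.arange(1, int(np.floor(fs / 2.0)))
        interp = np.interp(centers, freqs, pxx)
        bin_power = interp * 1.0  # Pa^2/Hz * 1 Hz
    else:
        raise ValueError(f"unknown PSD method {method!r}")

    with np.errstate(divide="ignore"):
        levels = 10.0 * np.log10(bin_power / P_REF ** 2)
    levels = np.maximum(levels, DB_FLOOR)
    return PowerSpectrumDensity(frequencies=centers.astype(float),
                                levels=levels, mic_id=recording.mic_id)


def band_level(psd: PowerSpectrumDensity, f_lo: float, f_hi: float) -> float:
    """Total level (dB SPL) of the band [f_lo, f_hi].

    Powers of all 1-Hz bins whose centre lies in the band are summed:
    ``10*log10(sum 10**(L_i/10) * 1 Hz)``.
    """
    if not f_lo < f_hi:
        raise ValueError("need f_lo < f_hi")
    sel = (psd.frequencies >= f_lo) & (psd.frequencies <= f_hi)
    if not np.any(sel):
        raise CoverageError(
            f"no PSD bins inside [{f_lo:g}, {f_hi:g}] Hz")
    return float(10.0 * np.log10(np.sum(10.0 ** (psd.levels[sel] / 10.0))))


def merge_psds(low: PowerSpectrumDensity, high: PowerSpectrumDensity,
               crossover: float = DEFAULT_CROSSOVER_HZ
               ) -> PowerSpectrumDensity:
    """Combine two microphones' spectra at a crossover frequency.

    The output takes ``low`` strictly below the crossover and ``high`` at or
    above it (the low-noise-floor microphone covers the audio band, the
    extended-range microphone the ultrasound band).
    """
    lo_sel = low.frequencies < crossover
    hi_sel = high.frequencies >= crossover
    f = np.concatenate([low.frequencies[lo_sel], high.frequencies[hi_sel]])
    if f.size == 0:
        raise CoverageError("merged spectrum is empty")
    if np.any(np.diff(f) != 1.0):
        raise CoverageError(
            f"spectra leave a gap at the {crossover:g} Hz crossover")
    levels = np.concatenate([low.levels[lo_sel], high.levels[hi_sel]])
    mic = f"{low.mic_id}+{high.mic_id}" if low.mic_id or high.mic_id else ""
    return PowerSpectrumDensity(frequencies=f, levels=levels, mic_id=mic)


# ---------------------------------------------------------------------------
# Species profiles
# ---------------------------------------------------------------------------

@dataclass
class SpeciesProfile:
    """Hearing threshold curve and tuning-bandwidth function of a species.

    The threshold is a set of audiogram anchor points interpolated with a
    monotone cubic in (log f, dB); queries outside the anchors raise rather
    than extrapolate.  The tuning bandwidth follows a log-log power law
    ``Bs(f) = bw_a * f**bw_b`` (Hz), valid over the same range.
    """

    species: str
    threshold_freqs: np.ndarray
    threshold_db: np.ndarray
    bw_a: float
    bw_b: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.threshold_freqs = np.asarray(self.threshold_freqs, dtype=float)
        self.threshold_db = np.asarray(self.threshold_db, dtype=float)
        if self.threshold_freqs.size < 2:
            raise ValueError("need at least two audiogram anchor points")
        if np.any(np.diff(self.threshold_freqs) <= 0):
            raise ValueError("threshold frequencies must be increasing")
        if not self.bw_a > 0:
            raise ValueError("bandwidth power-law coefficient must be > 0")
        self._interp = PchipInterpolator(np.log(self.threshold_freqs),
                                         self.threshold_db)

    @property
    def f_min(self) -> float:
        return float(self.threshold_freqs[0])

    @property
    def f_max(self) -> float:
        return float(self.threshold_freqs[-1])

    def threshold(self, freq) -> np.ndarray:
        f = np.asarray(freq, dtype=float)
        if np.any(f < self.f_min) or np.any(f > self.f_max):
            raise ProfileRangeError(
                f"threshold query outside [{self.f_min:g}, {self.f_max:g}] "
                f"Hz for {self.species}")
        return self._interp(np.log(f))

    def bandwidth(self, freq) -> np.ndarray:
        f = np.asarray(freq, dtype=float)
        if np.any(f < self.f_min) or np.any(f > self.f_max):
            raise ProfileRangeError(
                f"bandwidth query outside the hearing range of "
                f"{self.species}")
        return self.bw_a * f ** self.bw_b

    def default_grid(self, points_per_octave: int = 64) -> np.ndarray:
        """Log-spaced excitation grid spanning the hearing range."""
        n_oct = np.log2(self.f_max / self.f_min)
        n = max(2, int(np.ceil(n_oct * points_per_octave)) + 1)
        return np.geomspace(self.f_min, self.f_max, n)


# Packaged profiles.  Audiogram anchors and bandwidth power laws are
# coarse approximations assembled from published behavioral/physiological
# data; re-digitize from the primary sources before publication-grade use.
_BUILTIN_PROFILES = {
    "marmoset": dict(
        threshold_freqs=[125, 250, 500, 1000, 2000, 4000, 6000, 8000,
                         12000, 16000, 24000, 32000, 36000],
        threshold_db=[44.0, 36.0, 29.0, 25.0, 21.0, 14.0, 11.5, 10.6,
                      13.0, 17.0, 24.0, 32.0, 38.0],
        bw_a=0.105, bw_b=1.0,
        provenance=("approximation - behavioral audiogram and critical "
                    "bandwidth anchors for Callithrix jacchus"),
    ),
    "mouse_cba": dict(
        threshold_freqs=[1000, 2000, 4000, 8000, 12000, 16000, 24000,
                         32000, 48000, 64000],
        threshold_db=[70.0, 55.0, 35.0, 20.0, 15.0, 13.0, 18.0, 25.0,
                      35.0, 55.0],
        bw_a=0.25, bw_b=1.0,
        provenance=("approximation - CBA/CaJ audiogram, physiological "
                    "tuning bandwidths"),
    ),
    "mouse_c57bl6": dict(
        threshold_freqs=[1000, 2000, 4000, 8000, 16000, 24000, 32000,
                         48000],
        threshold_db=[75.0, 60.0, 40.0, 25.0, 20.0, 30.0, 45.0, 65.0],
        bw_a=0.25, bw_b=1.0,
        provenance=("approximation - C57BL/6J audiogram (age-related "
                    "high-frequency loss), physiological bandwidths"),
    ),
}


def builtin_species() -> list[str]:
    return sorted(_BUILTIN_PROFILES)


def load_species_profile(name_or_path: Union[str, Path]) -> SpeciesProfile:
    """Load a packaged profile by name or a custom profile from YAML."""
    key = str(name_or_path).lower()
    if key in _BUILTIN_PROFILES:
        d = _BUILTIN_PROFILES[key]
        return SpeciesProfile(species=key, **d)
    path = Path(name_or_path)
    if not path.exists():
        raise KeyError(
            f"unknown species {name_or_path!r}; available: "
            f"{', '.join(builtin_species())} (or a YAML file path)")
    d = yaml.safe_load(path.read_text())
    return SpeciesProfile(
        species=d["species"],
        threshold_freqs=d["threshold_freqs"],
        threshold_db=d["threshold_db"],
        bw_a=float(d["bw_a"]), bw_b=float(d["bw_b"]),
        provenance=d.get("provenance", ""))


def save_species_profile(profile: SpeciesProfile,
                         path: Union[str, Path]) -> None:
    d = dict(species=profile.species,
             threshold_freqs=[float(v) for v in profile.threshold_freqs],
             threshold_db=[float(v) for v in profile.threshold_db],
             bw_a=float(profile.bw_a), bw_b=float(profile.bw_b),
             provenance=profile.provenance)
    Path(path).write_text(yaml.safe_dump(d))


def microphone_noise_floor(frequencies,
                           mic: str = "bk4189") -> PowerSpectrumDensity:
    """Model self-noise PSD of the packaged calibration microphones.

    Flat electrical floors (about -26 dB SPL/Hz for the low-noise audio
    microphone, -21 dB SPL/Hz for the extended-range one, anchored at
    10 kHz) with a gentle 1/f rise below 100 Hz.  This is a smooth model of
    manufacturer-documented orders of magnitude, used as a reference
    spectrum; it is not a measurement.
    """
    base = {"bk4189": -26.0, "bk4191": -21.0}
    try:
        b = base[mic]
    except KeyError:
        raise KeyError(f"unknown microphone model {mic!r}") from None
    f = np.asarray(frequencies, dtype=float)
    levels = b + 10.0 * np.log10(1.0 + 100.0 / np.maximum(f, 1.0))
    return PowerSpectrumDensity(frequencies=f, levels=levels, mic_id=mic)


# ---------------------------------------------------------------------------
# Excitation patterns
# ---------------------------------------------------------------------------

@dataclass
class ExcitationPattern:
    """Auditory-filter outputs (dB SPL) on a log-spaced frequency grid."""

    center_frequencies: np.ndarray
    excitation: np.ndarray
    species: str = ""

    def __post_init__(self) -> None:
        self.center_frequencies = np.asarray(self.center_frequencies, float)
        self.excitation = np.asarray(self.excitation, float)
        if self.center_frequencies.shape != self.excitation.shape:
            raise ValueError("grid and excitation must match in shape")


def roex_weights(freqs, fc: float, bs: float) -> np.ndarray:
    """Rounded-exponential filter weights at frequencies ``freqs``.

    ``W(g) = (1 + p*g) exp(-p*g)`` with ``g = |f - fc|/fc`` and
    ``p = 4*fc/bs``, so the equivalent rectangular bandwidth is ``bs``.
    """
    f = np.asarray(freqs, dtype=float)
    if not (fc > 0 and bs > 0):
        raise ValueError("fc and bandwidth must be positive")
    g = np.abs(f - fc) / fc
    p = 4.0 * fc / bs
    return (1.0 + p * g) * np.exp(-p * g)


def excitation_pattern(psd: PowerSpectrumDensity,
                       profile: SpeciesProfile,
                       grid=None) -> ExcitationPattern:
    """Pass a PSD through the species' roex filter bank.

    ``E(fc) = 10*log10( sum_f W(f; fc) * 10**(PSD(f)/10) * 1 Hz )`` in dB
    SPL.  The default grid is 64 points per octave across the species'
    hearing range.  The filters are level independent, so adding k dB to
    every PSD bin adds exactly k dB to every excitation value.
    """
    if grid is None:
        grid = profile.default_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < profile.f_min) or np.any(grid > profile.f_max):
        raise ProfileRangeError(
            "excitation grid extends outside the species hearing range")
    power = 10.0 ** (psd.levels / 10.0)  # (Pa/20uPa)^2 per 1-Hz bin
    exc = np.empty_like(grid)
    for i, fc in enumerate(grid):
        w = roex_weights(psd.frequencies, fc, float(profile.bandwidth(fc)))
        exc[i] = np.sum(w * power)
    with np.errstate(divide="ignore"):
        exc_db = 10.0 * np.log10(exc)
    exc_db = np.maximum(exc_db, DB_FLOOR)
    return ExcitationPattern(center_frequencies=grid, excitation=exc_db,
                             species=profile.species)


@dataclass
class ExceedanceSummary:
    """Excitation minus threshold, with its summary statistics."""

    frequencies: np.ndarray
    exceedance_db: np.ndarray
    max_exceedance_db: float
    frequency_of_max_hz: float
    n_bands_above: int


def threshold_exceedance(ep: ExcitationPattern,
                         profile: SpeciesProfile) -> ExceedanceSummary:
    """Compare an excitation pattern against the species hearing threshold.

    Positive exceedance at any frequency means the sound is expected to
    excite the species' auditory system there.
    """
    thr = profile.threshold(ep.center_frequencies)
    exc = ep.excitation - thr
    i = int(np.argmax(exc))
    return ExceedanceSummary(
        frequencies=ep.center_frequencies,
        exceedance_db=exc,
        max_exceedance_db=float(exc[i]),
        frequency_of_max_hz=float(ep.center_frequencies[i]),
        n_bands_above=int(np.sum(exc > 0.0)))
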