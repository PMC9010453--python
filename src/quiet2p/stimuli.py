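"""Calibrated tone-pip stimuli and reproducible session schedules.

Two experiment designs are supported:

* a *sweep* session: a sequence of pure-tone pips stepping by semitones
  (ratio 2**(1/12)) at a fixed level, played ascending or descending;
* an *FRA mapping* session: a frequency x level grid of pip-triplet
  trials, pseudo-randomized per cycle with a seeded permutation, repeated
  for a number of cycles.

Pips are sine tones with sine-squared (cos^2) on/off ramps.  Waveforms are
produced in Pa and divided by a calibration reference (Pa per output unit)
so that the rendered RMS corresponds to the requested dB SPL re 20 uPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

P_REF = 20e-6
SEMITONE = 2.0 ** (1.0 / 12.0)

__all__ = [
    "TonePip",
    "StimulusGrid",
    "SessionSchedule",
    "ScheduleEntry",
    "make_pip",
    "make_semitone_sequence",
    "make_fra_grid",
    "make_session_schedule",
    "render_trial_audio",
    "render_pip_train",
    "write_wav",
]


@dataclass(frozen=True)
class TonePip:
    """A single pure-tone pip."""

    frequency: float
    level_db_spl: float
    duration: float = 0.2
    ramp: float = 0.020
    sample_rate: float = 200e3

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError("frequency must be positive")
        if self.frequency >= self.sample_rate / 2.0:
            raise ValueError("frequency at or above Nyquist")
        if 2.0 * self.ramp > self.duration:
            raise ValueError("2*ramp must not exceed the pip duration")


@dataclass(frozen=True)
class StimulusGrid:
    """The frequency x level trial-type grid and within-trial timing."""

    frequencies: tuple
    levels: tuple
    pip_count_per_trial: int = 3
    pre_s: float = 0.6
    stimulus_s: float = 0.6
    post_s: float = 1.8

    def __post_init__(self) -> None:
        if len(self.frequencies) == 0 or len(self.levels) == 0:
            raise ValueError("grid must have frequencies and levels")
        if self.pip_count_per_trial < 1:
            raise ValueError("need at least one pip per trial")

    @property
    def n_trial_types(self) -> int:
        return len(self.frequencies) * len(self.levels)

    @property
    def trial_duration(self) -> float:
        return self.pre_s + self.stimulus_s + self.post_s

    @property
    def pip_duration(self) -> float:
        return self.stimulus_s / self.pip_count_per_trial

    def cells(self) -> list:
        """All (frequency, level) cells in row-major order."""
        return [(f, l) for f in self.frequencies for l in self.levels]


@dataclass(frozen=True)
class ScheduleEntry:
    trial_index: int
    cycle: int
    frequency: float
    level_db_spl: float
    t_start_s: float


@dataclass(frozen=True)
class SessionSchedule:
    """An ordered, seed-reproducible list of trials."""

    trials: tuple
    cycles: int
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.trial_index, t.cycle, t.frequency, t.level_db_spl,
              t.t_start_s) for t in self.trials],
            columns=["trial_index", "cycle", "frequency_hz",
                     "level_db_spl", "t_start_s"])

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def _envelope(n: int, ramp_samples: int) -> np.ndarray:
    """cos^2 (sine-squared) onset/offset envelope; end samples exactly 0."""
    env = np.ones(n)
    if ramp_samples > 0:
        k = np.arange(ramp_samples)
        r = np.sin(0.5 * np.pi * k / ramp_samples) ** 2
        env[:ramp_samples] = r
        env[n - ramp_samples:] = r[::-1]
    env[0] = 0.0
    env[-1] = 0.0
    return env


def make_pip(pip: TonePip, calibration_ref: float = 1.0) -> np.ndarray:
    """Render one pip.

    ``calibration_ref`` is the pressure (Pa) produced per unit of output
    amplitude; the plateau RMS of the returned waveform times
    ``calibration_ref`` equals the requested dB SPL re 20 uPa.
    """
    if not calibration_ref > 0:
        raise ValueError("calibration_ref must be positive")
    n = int(round(pip.duration * pip.sample_rate))
    t = np.arange(n) / pip.sample_rate
    amp_pa = math.sqrt(2.0) * P_REF * 10.0 ** (pip.level_db_spl / 20.0)
    ramp_n = int(round(pip.ramp * pip.sample_rate))
    env = _envelope(n, ramp_n)
    return (amp_pa / calibration_ref) * env * np.sin(
        2.0 * np.pi * pip.frequency * t)


def make_semitone_sequence(start: float, n_pips: int,
                           direction: str = "ascending") -> np.ndarray:
    """Pip frequencies stepping by exactly one semitone.

    The descending sequence is the element-wise reverse of the ascending
    one (identical frequency set).
    """
    if n_pips < 1:
        raise ValueError("need at least one pip")
    asc = start * SEMITONE ** np.arange(n_pips)
    if direction == "ascending":
        return asc
    if direction == "descending":
        return asc[::-1].copy()
    raise ValueError(f"unknown direction {direction!r}")


def make_fra_grid(start: float = 440.0, step_semitones: int = 2,
                  n_freqs: int = 31, level_lo: float = 5.0,
                  level_hi: float = 65.0, level_step: float = 15.0,
                  **timing) -> StimulusGrid:
    """Build the frequency x level mapping grid.

    Defaults: 31 frequencies from 440 Hz in 2-semitone steps (5 octaves, up
    to 14080 Hz) crossed with 5 levels from 5 to 65 dB SPL in 15-dB steps,
    giving 155 trial types.  A 25-frequency, 4-octave variant (top frequency
    7040 Hz) is available via ``n_freqs=25``.
    """
    n_steps = (level_hi - level_lo) / level_step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("level range is not divisible by level_step")
    freqs = start * (SEMITONE ** step_semitones) ** np.arange(n_freqs)
    levels = level_lo + level_step * np.arange(int(round(n_steps)) + 1)
    return StimulusGrid(frequencies=tuple(float(f) for f in freqs),
                        levels=tuple(float(l) for l in levels), **timing)


def make_session_schedule(grid: StimulusGrid, cycles: int = 10,
                          seed: int = 0) -> SessionSchedule:
    """Pseudo-randomize the grid into trials.

    Each cycle is an independent seeded permutation of the full grid, so
    every (frequency, level) cell appears exactly once per cycle; trials are
    laid back-to-back in time.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    rng = np.random.default_rng(seed)
    cells = grid.cells()
    trials = []
    idx = 0
    for cycle in range(cycles):
        order = rng.permutation(len(cells))
        for j in order:
            f, l = cells[j]
            trials.append(ScheduleEntry(
                trial_index=idx, cycle=cycle, frequency=f,
                level_db_spl=l, t_start_s=idx * grid.trial_duration))
            idx += 1
    return SessionSchedule(trials=tuple(trials), cycles=cycles, seed=seed)


def schedule_from_csv(path: Union[str, Path],
                      seed: int = -1) -> SessionSchedule:
    """Rebuild a schedule from its CSV export (inverse of ``to_csv``)."""
    df = pd.read_csv(path)
    trials = tuple(ScheduleEntry(int(r.trial_index), int(r.cycle),
                                 float(r.frequency_hz),
                                 float(r.level_db_spl), float(r.t_start_s))
                   for r in df.itertuples())
    cycles = int(df["cycle"].max()) + 1 if len(df) else 0
    return SessionSchedule(trials=trials, cycles=cycles, seed=seed)


def grid_from_schedule(schedule: SessionSchedule, **timing) -> StimulusGrid:
    """Recover the frequency x level grid implied by a schedule."""
    freqs = tuple(sorted({t.frequency for t in schedule.trials}))
    levels = tuple(sorted({t.level_db_spl for t in schedule.trials}))
    return StimulusGrid(frequencies=freqs, levels=levels, **timing)


def render_trial_audio(trial, grid: StimulusGrid,
                       sample_rate: float = 200e3,
                       calibration_ref: float = 1.0) -> np.ndarray:
    """Render one mapping trial: silence, a contiguous pip train, silence.

    ``trial`` is a (frequency, level) pair; the pips fill the stimulus
    window exactly (no inter-pip gap).
    """
    freq, level = float(trial[0]), float(trial[1])
    if freq >= sample_rate / 2.0:
        raise ValueError("trial frequency at or above Nyquist")
    n_total = int(round(grid.trial_duration * sample_rate))
    wav = np.zeros(n_total)
    pip = TonePip(frequency=freq, level_db_spl=level,
                  duration=grid.pip_duration, sample_rate=sample_rate)
    one = make_pip(pip, calibration_ref)
    start = int(round(grid.pre_s * sample_rate))
    for k in range(grid.pip_count_per_trial):
        wav[start + k * one.size: start + (k + 1) * one.size] = one
    return wav


def render_pip_train(frequencies: Sequence[float], level_db_spl: float,
                     duration: float = 0.2, ramp: float = 0.020,
                     sample_rate: float = 200e3,
                     calibration_ref: float = 1.0) -> np.ndarray:
    """Concatenate equal-level pips at the given frequencies (sweep)."""
    parts = [make_pip(TonePip(frequency=float(f), level_db_spl=level_db_spl,
                              duration=duration, ramp=ramp,
                              sample_rate=sample_rate), calibration_ref)
             for f in frequencies]
    return np.concatenate(parts)


def write_wav(path: Union[str, Path], waveform: np.ndarray,
              sample_rate: float, pcm16: bool = False) -> None:
    """Write a waveform as float32 (default) or scaled PCM16 WAV."""
    from scipy.io import wavfile

    w = np.asarray(waveform)
    if pcm16:
        peak = np.max(np.abs(w)) or 1.0
        w = np.round(w / peak * 32767).astype(np.int16)
    else:
        w = w.astype(np.float32)
    wavfile.write(Path(path), int(sample_rate), w)
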