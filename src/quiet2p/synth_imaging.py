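"""Ground-truth-labelled synthetic two-photon sessions.

Generates movies with the statistical structure the FRA pipeline assumes:
tone-tuned neurons with V/I/O-shaped frequency-response areas, slow
calcium-indicator kinetics, a neuropil background, shot-like noise, and
rigid tissue motion made of a fast heartbeat component (~4 Hz) plus a slow
drift, capped at a few pixels per axis.  Every quantity that the analysis
estimates (dF/F, FRA, BF/BL, frame displacements) is available as ground
truth, so the pipeline can be validated closed-loop without any recorded
data.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .fra_pipeline import Movie, ROIMask
from .stimuli import SessionSchedule, StimulusGrid

# reference levels of the standard mapping grid, used by the V/I level gain
LEVEL_REF_LO = 5.0
LEVEL_REF_HI = 65.0

__all__ = [
    "NeuronGroundTruth",
    "SimConfig",
    "SimSession",
    "DensityError",
    "make_population",
    "fra_response",
    "calcium_kernel",
    "simulate_trace",
    "render_session",
]


class DensityError(RuntimeError):
    """Could not place the requested number of non-overlapping somas."""


@dataclass(frozen=True)
class NeuronGroundTruth:
    """Everything the simulator knows about one neuron.

    ``fra_shape`` selects the tuning surface: 'V' widens its frequency
    bandwidth with level, 'I' keeps it constant (both with a monotone level
    gain, so their best level is the highest tested level), and 'O' is a
    separable Gaussian bump peaked at (bf, bl).  ``level_slope`` is the
    sigmoid slope (dB) for V/I and the level Gaussian sigma (dB) for O.
    Kinetics default to a slow genetically encoded calcium indicator
    (GCaMP6s-like: 0.2 s rise, 1.5 s decay).
    """

    center: Tuple[float, float]
    radius: float
    bf: float
    bl: float
    fra_shape: str
    bandwidth_octaves: float = 1.0
    level_slope: float = 10.0
    peak_amplitude: float = 0.5
    rise_tau: float = 0.2
    decay_tau: float = 1.5
    baseline_f: float = 100.0

    def __post_init__(self) -> None:
        if self.fra_shape not in ("V", "I", "O"):
            raise ValueError(f"unknown FRA shape {self.fra_shape!r}")
        if self.peak_amplitude < 0:
            raise ValueError("peak amplitude must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Imaging and noise parameters of a simulated session.

    Defaults mirror the full-frame raster mode (653 x 652 px at 23.5 fps,
    0.585 um pixels); tests typically shrink the frame and frame rate.
    Noise is Gaussian with variance ``read_noise_sd**2 + gain * signal``
    (a Gaussian approximation to shot noise).  Motion is a per-axis 4-Hz
    sinusoid plus a linear drift across the session; the sum of amplitudes
    must stay within ``motion_cap_px``.
    """

    frame_shape: Tuple[int, int] = (653, 652)
    frame_rate: float = 23.5
    pixel_size: float = 0.585e-6
    n_neurons: int = 50
    soma_radius_px: float = 3.0
    gain: float = 1.0
    read_noise_sd: float = 2.0
    neuropil_level: float = 20.0
    heartbeat_freq: float = 4.0
    heartbeat_amp_px: float = 2.0
    drift_px: float = 3.0
    motion_cap_px: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("need at least one neuron")
        if self.heartbeat_amp_px + self.drift_px > self.motion_cap_px + 1e-9:
            raise ValueError(
                "heartbeat amplitude + drift exceeds the motion cap")


@dataclass
class SimSession:
    """A rendered session plus its ground truth."""

    movie: Movie
    rois: List[ROIMask]
    displacements: pd.DataFrame      # frame, dy_px, dx_px (content motion)
    population: List[NeuronGroundTruth]
    dff: np.ndarray                  # (n_neurons, n_frames) noise-free dF/F


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def make_population(config: SimConfig, grid: StimulusGrid,
                    max_tries: int = 20000) -> List[NeuronGroundTruth]:
    """Sample a non-overlapping tuned population.

    Best frequencies are log-uniform over the grid's frequency range;
    O-shaped neurons draw their best level uniformly from the grid levels
    (so low best levels such as 20 dB SPL occur), while V/I neurons peak at
    the highest level by construction.  Soma centres keep a pairwise
    distance greater than twice the soma radius.
    """
    rng = np.random.default_rng([config.seed, 0])
    H, W = config.frame_shape
    r = config.soma_radius_px
    margin = r + 1.0
    if H - 2 * margin <= 0 or W - 2 * margin <= 0:
        raise DensityError("frame too small for the soma radius")
    fmin, fmax = min(grid.frequencies), max(grid.frequencies)
    centers: List[Tuple[float, float]] = []
    tries = 0
    while len(centers) < config.n_neurons:
        if tries >= max_tries:
            raise DensityError(
                f"placed {len(centers)}/{config.n_neurons} somas after "
                f"{max_tries} tries; lower n_neurons or the soma radius")
        tries += 1
        c = (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin))
        if all((c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2 > (2 * r) ** 2
               for o in centers):
            centers.append(c)

    population = []
    for i, c in enumerate(centers):
        shape = rng.choice(["V", "I", "O"])
        bf = math.exp(rng.uniform(math.log(fmin), math.log(fmax)))
        if shape == "O":
            bl = float(rng.choice(grid.levels))
        else:
            bl = float(max(grid.levels))
        population.append(NeuronGroundTruth(
            center=c, radius=r, bf=bf, bl=bl, fra_shape=str(shape),
            bandwidth_octaves=float(rng.uniform(0.5, 1.5)),
            level_slope=float(rng.uniform(8.0, 15.0)),
            peak_amplitude=float(rng.uniform(0.1, 1.0)),
            baseline_f=float(rng.uniform(80.0, 120.0))))
    return population


# ---------------------------------------------------------------------------
# Tuning surfaces
# ---------------------------------------------------------------------------

def _level_gain(level, slope: float) -> np.ndarray:
    """Monotone sigmoid level gain, ~0 at the low end, ->1 at the top."""
    mid = 0.5 * (LEVEL_REF_LO + LEVEL_REF_HI)
    return 1.0 / (1.0 + np.exp(-(np.asarray(level, float) - mid) / slope))


def fra_response(neuron: NeuronGroundTruth, frequency, level) -> np.ndarray:
    """Expected dF/F response amplitude at (frequency, level).

    V: Gaussian in log2 frequency whose sigma widens with level, times a
    monotone level gain.  I: fixed sigma, same gain.  O: separable
    Gaussians in log2 frequency and level, peaked at (bf, bl).
    """
    f = np.asarray(frequency, dtype=float)
    L = np.asarray(level, dtype=float)
    x = np.log2(f / neuron.bf)
    sigma0 = neuron.bandwidth_octaves / 2.0
    if neuron.fra_shape == "O":
        freq_part = np.exp(-x * x / (2.0 * sigma0 * sigma0))
        lvl = np.exp(-(L - neuron.bl) ** 2
                     / (2.0 * neuron.level_slope ** 2))
        return neuron.peak_amplitude * freq_part * lvl
    frac = np.clip((L - LEVEL_REF_LO) / (LEVEL_REF_HI - LEVEL_REF_LO),
                   0.0, 1.0)
    if neuron.fra_shape == "V":
        sigma = sigma0 * (0.6 + 0.8 * frac)
    else:  # I-shape: level-independent bandwidth
        sigma = np.broadcast_to(sigma0, frac.shape) if frac.shape else sigma0
    freq_part = np.exp(-x * x / (2.0 * sigma * sigma))
    return neuron.peak_amplitude * freq_part * _level_gain(L,
                                                           neuron.level_slope)


# ---------------------------------------------------------------------------
# Calcium dynamics
# ---------------------------------------------------------------------------

def calcium_kernel(t, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Double-exponential calcium impulse response, unit peak.

    ``h(t) = (1 - exp(-t/rise)) * exp(-t/decay)`` for t >= 0, normalized so
    its maximum (at ``t* = rise * ln(1 + decay/rise)``) is 1.
    """
    t = np.asarray(t, dtype=float)
    h = np.where(t >= 0,
                 (1.0 - np.exp(-np.maximum(t, 0.0) / rise_tau))
                 * np.exp(-np.maximum(t, 0.0) / decay_tau), 0.0)
    t_peak = rise_tau * math.log1p(decay_tau / rise_tau)
    peak = ((1.0 - math.exp(-t_peak / rise_tau))
            * math.exp(-t_peak / decay_tau))
    return h / peak


def simulate_trace(neuron: NeuronGroundTruth, schedule: SessionSchedule,
                   grid: StimulusGrid, frame_rate: float,
                   n_frames: Optional[int] = None) -> np.ndarray:
    """Noise-free dF/F trace of one neuron across a whole session.

    Each trial contributes ``fra_response(f, L)`` times the calcium kernel
    anchored at the stimulus onset (trial start + pre-stimulus time);
    contributions from successive trials superpose linearly.
    """
    fpt = int(round(grid.trial_duration * frame_rate))
    if n_frames is None:
        n_frames = schedule.n_trials * fpt
    t = np.arange(n_frames) / frame_rate
    dff = np.zeros(n_frames)
    support = int(math.ceil((neuron.rise_tau + 6.0 * neuron.decay_tau)
                            * frame_rate))
    for trial in schedule.trials:
        amp = float(fra_response(neuron, trial.frequency,
                                 trial.level_db_spl))
        if amp == 0.0:
            continue
        onset = trial.t_start_s + grid.pre_s
        i0 = int(math.ceil(onset * frame_rate - 1e-9))
        i1 = min(n_frames, i0 + support)
        if i0 >= n_frames:
            continue
        dff[i0:i1] += amp * calcium_kernel(t[i0:i1] - onset,
                                           neuron.rise_tau,
                                           neuron.decay_tau)
    return dff


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _soma_patch(neuron: NeuronGroundTruth, frame_shape: Tuple[int, int]):
    """Gaussian soma profile on a local patch: (r0, c0, patch array)."""
    cy, cx = neuron.center
    half = int(math.ceil(2.0 * neuron.radius))
    r0 = max(0, int(math.floor(cy)) - half)
    r1 = min(frame_shape[0], int(math.floor(cy)) + half + 1)
    c0 = max(0, int(math.floor(cx)) - half)
    c1 = min(frame_shape[1], int(math.floor(cx)) + half + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    sigma = neuron.radius / 2.0
    return r0, c0, np.exp(-d2 / (2.0 * sigma * sigma)).astype(np.float32)


def _soma_mask(neuron: NeuronGroundTruth, frame_shape: Tuple[int, int],
               label: str) -> ROIMask:
    cy, cx = neuron.center
    rr = int(math.ceil(neuron.radius))
    r0 = max(0, int(math.floor(cy)) - rr)
    r1 = min(frame_shape[0], int(math.floor(cy)) + rr + 1)
    c0 = max(0, int(math.floor(cx)) - rr)
    c1 = min(frame_shape[1], int(math.floor(cx)) + rr + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= neuron.radius ** 2
    return ROIMask(rows=yy[inside], cols=xx[inside], label=label,
                   kind="soma")


def true_displacements(config: SimConfig, n_frames: int) -> np.ndarray:
    """Per-frame content displacement (dy, dx) of the motion model.

    Heartbeat sinusoid plus linear drift per axis, expressed about the
    session-mean position (zero-mean): the absolute offset of a session is
    arbitrary, and registration can only recover alignment relative to its
    own reference, so zero-mean motion keeps ground-truth ROI coordinates
    valid on the registered movie.
    """
    rng = np.random.default_rng([config.seed, 2])
    t = np.arange(n_frames) / config.frame_rate
    phases = rng.uniform(0, 2 * np.pi, size=2)
    drift_dir = rng.choice([-1.0, 1.0], size=2)
    frac = t / max(t[-1], 1e-12) if n_frames > 1 else np.zeros(1)
    disp = np.empty((n_frames, 2))
    for ax in range(2):
        disp[:, ax] = (config.heartbeat_amp_px
                       * np.sin(2 * np.pi * config.heartbeat_freq * t
                                + phases[ax])
                       + drift_dir[ax] * config.drift_px * frac)
    return disp - disp.mean(axis=0)


def render_session(population: Sequence[NeuronGroundTruth],
                   config: SimConfig, schedule: SessionSchedule,
                   grid: StimulusGrid) -> SimSession:
    """Render a full session movie with ground truth.

    Frames are a static background (neuropil plus soma baselines) plus each
    soma's profile modulated by its dF/F trace, rigidly shifted by the
    motion model (cubic-spline interpolation -- deliberately different from
    the registration engine's bilinear interpolation), with Gaussian
    shot-like noise added last.  With motion and noise disabled
    (amplitudes/SDs at zero), the pipeline recovers the simulated dF/F up
    to small discretization effects.
    """
    H, W = config.frame_shape
    fpt = int(round(grid.trial_duration * config.frame_rate))
    n_frames = schedule.n_trials * fpt
    trial_bounds = tuple((i * fpt, (i + 1) * fpt)
                         for i in range(schedule.n_trials))

    patches = [_soma_patch(nrn, config.frame_shape) for nrn in population]
    base = np.full((H, W), config.neuropil_level, dtype=np.float32)
    for nrn, (r0, c0, p) in zip(population, patches):
        base[r0:r0 + p.shape[0], c0:c0 + p.shape[1]] += (
            np.float32(nrn.baseline_f) * p)

    dff = np.stack([simulate_trace(nrn, schedule, grid, config.frame_rate,
                                   n_frames) for nrn in population]
                   ).astype(np.float32)

    moving = (config.heartbeat_amp_px > 0 or config.drift_px > 0)
    disp = (true_displacements(config, n_frames) if moving
            else np.zeros((n_frames, 2)))
    noisy = config.read_noise_sd > 0 or config.gain > 0
    rng = np.random.default_rng([config.seed, 1])

    frames = np.empty((n_frames, H, W), dtype=np.float32)
    for ti in range(n_frames):
        img = base.copy()
        for ni, (nrn, (r0, c0, p)) in enumerate(zip(population, patches)):
            a = dff[ni, ti]
            if a != 0.0:
                img[r0:r0 + p.shape[0], c0:c0 + p.shape[1]] += (
                    np.float32(nrn.baseline_f) * a * p)
        if moving:
            img = ndimage.shift(img, disp[ti], order=3,
                                mode="nearest").astype(np.float32)
        if noisy:
            var = config.read_noise_sd ** 2 + config.gain * np.clip(
                img, 0.0, None)
            img = img + rng.standard_normal((H, W)).astype(
                np.float32) * np.sqrt(var, dtype=np.float32)
        frames[ti] = img

    movie = Movie(frames=frames, frame_rate=config.frame_rate,
                  pixel_size=config.pixel_size, trial_bounds=trial_bounds)
    rois = [_soma_mask(nrn, config.frame_shape, label=f"n{idx:03d}")
            for idx, nrn in enumerate(population)]
    table = pd.DataFrame({"frame": np.arange(n_frames),
                          "dy_px": disp[:, 0], "dx_px": disp[:, 1]})
    return SimSession(movie=movie, rois=rois, displacements=table,
                      population=list(population), dff=dff)
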