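"""From imaging movies to frequency-response-area (FRA) maps.

The pipeline mirrors standard practice for trial-structured two-photon
calcium imaging:

1. motion correction with a two-stage hierarchical protocol: all frames of
   a trial are registered to a template averaged over the 10 middle frames
   of that trial, the per-trial average images are then registered across
   trials, and the cross-trial shifts are folded back into every frame;
2. fluorescence extraction per ROI (mean over ROI pixels);
3. neuropil decontamination: the mean fluorescence of a 5-pixel-wide ring
   around each cell, scaled by 0.4, is subtracted from the cell trace;
4. normalization to dF/F with F0 the mean pre-stimulus fluorescence of each
   trial, and the response amplitude taken as the mean dF/F over the
   stimulus window;
5. per-cell FRA matrices over the frequency x level grid, with the best
   frequency (BF) and best level (BL) defined by the maximal mean response.

The registration engine is a rigid subpixel translation estimated by
cross-correlation; the two-stage *protocol* is what matters here, and the
engine is pluggable in principle.  Coordinates are 0-based (row, col);
displacements follow image-content motion (template -> frame), so a frame
is corrected by shifting it back by minus its displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .stimuli import SessionSchedule, StimulusGrid

NEUROPIL_FACTOR = 0.4
RING_WIDTH_PX = 5
TEMPLATE_FRAMES = 10

__all__ = [
    "Movie",
    "ROIMask",
    "Trace",
    "FRAMatrix",
    "ProtocolError",
    "BaselineError",
    "estimate_rigid_shift",
    "apply_displacement",
    "register_session",
    "neuropil_ring",
    "extract_trace",
    "neuropil_subtract",
    "compute_dff",
    "response_amplitude",
    "trial_frame_windows",
    "trial_response_amplitudes",
    "build_fra",
    "best_frequency_level",
]


class ProtocolError(ValueError):
    """Trial structure cannot support the registration protocol."""


class BaselineError(ValueError):
    """Non-positive baseline fluorescence; cell flagged unusable."""


@dataclass
class Movie:
    """A time-ordered stack of frames with trial structure.

    ``trial_bounds`` holds (start, stop) frame indices per trial
    (half-open).
    """

    frames: np.ndarray
    frame_rate: float = 23.5
    pixel_size: float = 0.585e-6
    trial_bounds: Optional[Tuple[Tuple[int, int], ...]] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.trial_bounds is not None:
            self.trial_bounds = tuple(
                (int(a), int(b)) for a, b in self.trial_bounds)
            for a, b in self.trial_bounds:
                if not 0 <= a < b <= self.frames.shape[0]:
                    raise ValueError("trial bounds outside the movie")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def n_trials(self) -> int:
        if self.trial_bounds is None:
            raise ProtocolError("movie has no trial boundaries")
        return len(self.trial_bounds)


@dataclass
class ROIMask:
    """A set of (row, col) pixels with a label and a kind."""

    rows: np.ndarray
    cols: np.ndarray
    label: str = ""
    kind: str = "soma"

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        if self.rows.size == 0 or self.rows.shape != self.cols.shape:
            raise ValueError("ROI must be a non-empty set of (row, col)")
        if self.kind not in ("soma", "process", "neuropil_ring"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")

    @classmethod
    def from_mask(cls, mask: np.ndarray, label: str = "",
                  kind: str = "soma") -> "ROIMask":
        rows, cols = np.nonzero(mask)
        return cls(rows=rows, cols=cols, label=label, kind=kind)

    def to_mask(self, shape: Tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m

    @property
    def n_pixels(self) -> int:
        return self.rows.size


@dataclass
class Trace:
    """A per-frame fluorescence (or dF/F) time series for one ROI."""

    values: np.ndarray
    frame_rate: float
    label: str = ""
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if self.stage not in ("raw", "neuropil_corrected", "dff"):
            raise ValueError(f"unknown trace stage {self.stage!r}")


@dataclass
class FRAMatrix:
    """Per-cell response matrix over the frequency x level grid."""

    frequencies: np.ndarray
    levels: np.ndarray
    mean: np.ndarray            # (n_freqs, n_levels)
    per_trial: np.ndarray       # (n_freqs, n_levels, n_reps), NaN-padded
    n_reps: np.ndarray          # (n_freqs, n_levels) trial counts
    label: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, float)
        self.levels = np.asarray(self.levels, float)
        nf, nl = self.frequencies.size, self.levels.size
        if self.mean.shape != (nf, nl):
            raise ValueError("mean matrix shape mismatch")
        if self.per_trial.shape[:2] != (nf, nl):
            raise ValueError("per-trial array shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        f, l = np.meshgrid(self.frequencies, self.levels, indexing="ij")
        return pd.DataFrame({"frequency_hz": f.ravel(),
                             "level_db_spl": l.ravel(),
                             "mean_dff": self.mean.ravel(),
                             "n_reps": self.n_reps.ravel()})


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def estimate_rigid_shift(frame: np.ndarray, template: np.ndarray,
                         upsample_factor: int = 20) -> Tuple[float, float]:
    """Subpixel displacement of image content from template to frame.

    Maximizes the cross-correlation between the two images, refined to
    subpixel precision by Fourier upsampling around the integer peak.
    Antisymmetric: ``shift(a, b) == -shift(b, a)`` to within a small
    fraction of a pixel.
    """
    frame = np.asarray(frame, dtype=float)
    template = np.asarray(template, dtype=float)
    if frame.shape != template.shape:
        raise ValueError("frame and template must share a shape")
    if np.ptp(template) == 0 or np.ptp(frame) == 0:
        raise ValueError("constant image: cross-correlation is degenerate")
    shift, _, _ = phase_cross_correlation(
        template, frame, upsample_factor=upsample_factor,
        normalization=None)
    # phase_cross_correlation returns the shift that moves `frame` onto
    # `template`; content displacement is its negation
    return float(-shift[0]), float(-shift[1])


def apply_displacement(frame: np.ndarray,
                       displacement: Tuple[float, float],
                       order: int = 1) -> np.ndarray:
    """Undo a content displacement (shift the frame back by -displacement).

    Bilinear interpolation with replicated edges by default; deliberately a
    different interpolator from the spline shifts used by the simulator.
    """
    dy, dx = displacement
    return ndimage.shift(np.asarray(frame, dtype=float), (-dy, -dx),
                         order=order, mode="nearest")


def _trial_template(frames: np.ndarray,
                    upsample_factor: int = 20) -> np.ndarray:
    """Aligned average of the TEMPLATE_FRAMES frames mid-trial.

    Averaging moving frames directly would smear the template and bias the
    subsequent frame registration toward zero (every frame correlates best
    with its own smeared copy), so the template frames are first registered
    to the central one and averaged after correction.
    """
    n = frames.shape[0]
    if n < TEMPLATE_FRAMES:
        raise ProtocolError(
            f"trial has {n} frames; the protocol needs at least "
            f"{TEMPLATE_FRAMES} for the template")
    start = (n - TEMPLATE_FRAMES) // 2
    window = frames[start:start + TEMPLATE_FRAMES]
    anchor = window[TEMPLATE_FRAMES // 2]
    aligned = [
        apply_displacement(f, estimate_rigid_shift(f, anchor,
                                                   upsample_factor))
        for f in window]
    return np.mean(aligned, axis=0)


def _two_stage_pass(frames: np.ndarray, trial_bounds,
                    upsample_factor: int) -> np.ndarray:
    """One pass of the hierarchical protocol; per-frame displacements."""
    T = frames.shape[0]
    disp = np.zeros((T, 2))
    trial_means = []
    for a, b in trial_bounds:
        chunk = frames[a:b]
        template = _trial_template(chunk, upsample_factor)
        corrected = np.empty_like(chunk, dtype=float)
        for i in range(chunk.shape[0]):
            d = estimate_rigid_shift(chunk[i], template, upsample_factor)
            disp[a + i] = d
            corrected[i] = apply_displacement(chunk[i], d)
        trial_means.append(corrected.mean(axis=0))
    trial_means = np.asarray(trial_means)

    reference = trial_means.mean(axis=0)
    for ti, (a, b) in enumerate(trial_bounds):
        d = estimate_rigid_shift(trial_means[ti], reference,
                                 upsample_factor)
        disp[a:b] += d
    return disp


def register_session(movie: Movie, upsample_factor: int = 20,
                     tol: float = 0.05, max_iter: int = 4
                     ) -> Tuple[Movie, pd.DataFrame]:
    """Two-stage hierarchical rigid registration, iterated to convergence.

    Each pass applies the protocol: (1) within each trial, every frame is
    registered to a template averaged across the 10 middle frames of that
    trial; (2) the per-trial average images are registered to their grand
    average and the cross-trial shifts are folded back into every frame of
    the trial.  Passes repeat on the provisionally corrected movie until
    the largest displacement update drops below ``tol`` pixels (or
    ``max_iter`` passes), accumulating the total displacement; the
    returned movie applies that total to the raw frames in a single
    interpolation.

    Returns the corrected movie and a per-frame displacement table with
    columns frame, trial, dy_px, dx_px.
    """
    if movie.trial_bounds is None:
        raise ProtocolError("registration requires trial boundaries")
    T = movie.n_frames
    total = np.zeros((T, 2))
    current = np.asarray(movie.frames, dtype=float)
    for _ in range(max_iter):
        delta = _two_stage_pass(current, movie.trial_bounds,
                                upsample_factor)
        total += delta
        current = np.empty_like(movie.frames, dtype=float)
        for i in range(T):
            current[i] = apply_displacement(movie.frames[i],
                                            tuple(total[i]))
        if np.max(np.abs(delta)) < tol:
            break

    trial_of = np.zeros(T, dtype=int)
    for ti, (a, b) in enumerate(movie.trial_bounds):
        trial_of[a:b] = ti
    table = pd.DataFrame({"frame": np.arange(T), "trial": trial_of,
                          "dy_px": total[:, 0], "dx_px": total[:, 1]})
    corrected_movie = Movie(frames=current, frame_rate=movie.frame_rate,
                            pixel_size=movie.pixel_size,
                            trial_bounds=movie.trial_bounds)
    return corrected_movie, table


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def neuropil_ring(roi: ROIMask, frame_shape: Tuple[int, int],
                  width: int = RING_WIDTH_PX) -> ROIMask:
    """A ``width``-pixel-wide ring around the ROI, excluding the ROI.

    The ring is the morphological dilation of the ROI by a Euclidean disk
    of radius ``width`` minus the ROI itself, clipped to the frame; it
    starts at the ROI boundary (no gap).
    """
    if width < 1:
        raise ValueError("ring width must be >= 1 pixel")
    mask = roi.to_mask(frame_shape)
    dilated = ndimage.binary_dilation(mask, structure=disk(width))
    ring = dilated & ~mask
    if not ring.any():
        raise ValueError("neuropil ring is empty after clipping")
    return ROIMask.from_mask(ring, label=f"{roi.label}_ring",
                             kind="neuropil_ring")


def extract_trace(movie: Movie, roi: ROIMask) -> Trace:
    """Mean fluorescence over the ROI pixels, per frame."""
    shape = movie.frame_shape
    if roi.rows.max() >= shape[0] or roi.cols.max() >= shape[1]:
        raise ValueError("ROI extends outside the frame")
    flat = movie.frames.reshape(movie.n_frames, -1)
    idx = roi.rows * shape[1] + roi.cols
    values = flat[:, idx].mean(axis=1)
    return Trace(values=values, frame_rate=movie.frame_rate,
                 label=roi.label, stage="raw")


def neuropil_subtract(f_roi: Trace, f_ring: Trace,
                      factor: float = NEUROPIL_FACTOR) -> Trace:
    """Subtract the scaled ring signal from the cell signal, per frame."""
    if f_roi.values.size != f_ring.values.size:
        raise ValueError("cell and ring traces differ in length")
    return Trace(values=f_roi.values - factor * f_ring.values,
                 frame_rate=f_roi.frame_rate, label=f_roi.label,
                 stage="neuropil_corrected")


def compute_dff(trace: Trace, prestim_frames) -> Trace:
    """(F - F0)/F0 with F0 the mean fluorescence over the pre-stimulus
    frames.  A non-positive F0 raises :class:`BaselineError` (the cell is
    flagged, not clipped)."""
    pres = np.asarray(trace.values[prestim_frames], dtype=float)
    if pres.size == 0:
        raise ValueError("empty pre-stimulus window")
    f0 = pres.mean()
    if f0 <= 0:
        raise BaselineError(
            f"non-positive baseline F0={f0:.3g} for ROI {trace.label!r}")
    return Trace(values=(trace.values - f0) / f0,
                 frame_rate=trace.frame_rate, label=trace.label,
                 stage="dff")


def response_amplitude(dff: Trace, stim_frames) -> float:
    """Mean dF/F over the stimulus-presentation window."""
    window = np.asarray(dff.values[stim_frames], dtype=float)
    if window.size == 0:
        raise ValueError("empty stimulus window")
    return float(window.mean())


def trial_frame_windows(frame_rate: float,
                        pre_window: Tuple[float, float] = (0.0, 0.6),
                        stim_window: Tuple[float, float] = (0.6, 1.2)
                        ) -> Tuple[slice, slice]:
    """Frame-index slices (relative to trial start) for the pre-stimulus
    and stimulus windows, given times in seconds (half-open intervals)."""
    def to_slice(w):
        a = int(np.ceil(w[0] * frame_rate - 1e-9))
        b = int(np.ceil(w[1] * frame_rate - 1e-9))
        if b <= a:
            raise ValueError("window shorter than one frame")
        return slice(a, b)
    return to_slice(pre_window), to_slice(stim_window)


def trial_response_amplitudes(movie: Movie, roi: ROIMask,
                              ring: Optional[ROIMask] = None,
                              neuropil_factor: float = NEUROPIL_FACTOR,
                              pre_window: Tuple[float, float] = (0.0, 0.6),
                              stim_window: Tuple[float, float] = (0.6, 1.2)
                              ) -> np.ndarray:
    """Per-trial response amplitudes for one ROI.

    Neuropil correction (if a ring is given) precedes dF/F; dF/F is
    computed per trial with that trial's pre-stimulus baseline.  Trials
    whose baseline is non-positive yield NaN.
    """
    if movie.trial_bounds is None:
        raise ProtocolError("movie has no trial boundaries")
    trace = extract_trace(movie, roi)
    if ring is not None:
        trace = neuropil_subtract(trace, extract_trace(movie, ring),
                                  neuropil_factor)
    pre_sl, stim_sl = trial_frame_windows(movie.frame_rate, pre_window,
                                          stim_window)
    out = np.empty(movie.n_trials)
    for ti, (a, b) in enumerate(movie.trial_bounds):
        seg = Trace(values=trace.values[a:b], frame_rate=movie.frame_rate,
                    label=trace.label, stage=trace.stage)
        try:
            dff = compute_dff(seg, pre_sl)
            out[ti] = response_amplitude(dff, stim_sl)
        except BaselineError:
            out[ti] = np.nan
    return out


# ---------------------------------------------------------------------------
# FRA
# ---------------------------------------------------------------------------

def build_fra(responses: np.ndarray, schedule: SessionSchedule,
              grid: StimulusGrid, label: str = "") -> FRAMatrix:
    """Group per-trial amplitudes by (frequency, level).

    The cell mean is the average over that cell's repetitions; per-trial
    values are retained (NaN-padded).  Grid cells with no trials are
    flagged by ``n_reps == 0`` and NaN means.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.size != schedule.n_trials:
        raise ValueError("one response per scheduled trial is required")
    freqs = np.asarray(grid.frequencies)
    levels = np.asarray(grid.levels)
    fi = {f: i for i, f in enumerate(freqs)}
    li = {l: j for j, l in enumerate(levels)}
    buckets = [[[] for _ in levels] for _ in freqs]
    for t, r in zip(schedule.trials, responses):
        try:
            buckets[fi[t.frequency]][li[t.level_db_spl]].append(r)
        except KeyError:
            raise ValueError(
                f"trial ({t.frequency}, {t.level_db_spl}) not in the grid"
            ) from None
    max_reps = max((len(c) for row in buckets for c in row), default=0)
    per_trial = np.full((freqs.size, levels.size, max(max_reps, 1)), np.nan)
    n_reps = np.zeros((freqs.size, levels.size), dtype=int)
    for i in range(freqs.size):
        for j in range(levels.size):
            vals = buckets[i][j]
            n_reps[i, j] = len(vals)
            per_trial[i, j, :len(vals)] = vals
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(per_trial, axis=2)
    if np.any(n_reps == 0):
        import warnings
        warnings.warn("incomplete session: some grid cells have no trials",
                      stacklevel=2)
    return FRAMatrix(frequencies=freqs, levels=levels, mean=mean,
                     per_trial=per_trial, n_reps=n_reps, label=label)


def best_frequency_level(fra: FRAMatrix) -> Tuple[float, float]:
    """(BF, BL): the frequency and level of the maximal mean response.

    Exact ties are broken toward the lowest level, then the lowest
    frequency.
    """
    mean = fra.mean
    if np.all(np.isnan(mean)):
        raise ValueError("FRA is all-NaN; best cell is undefined")
    m = np.nanmax(mean)
    ties = np.argwhere(mean == m)
    # sort by (level index, frequency index): lowest level wins, then
    # lowest frequency
    j, i = min((int(j), int(i)) for i, j in ties)
    return float(fra.frequencies[i]), float(fra.levels[j])


def map_best_frequency(movie: Movie, rois: Sequence[ROIMask],
                       schedule: SessionSchedule, grid: StimulusGrid,
                       neuropil_factor: float = NEUROPIL_FACTOR,
                       ring_width: int = RING_WIDTH_PX,
                       pre_window: Tuple[float, float] = (0.0, 0.6),
                       stim_window: Tuple[float, float] = (0.6, 1.2)
                       ) -> pd.DataFrame:
    """BF/BL map for a set of ROIs on an (already registered) movie.

    Runs extraction, neuropil correction, per-trial dF/F, FRA assembly and
    the BF/BL argmax for every ROI.  Returns one row per ROI with columns
    label, bf_hz, bl_db_spl, peak_dff.
    """
    rows = []
    for roi in rois:
        ring = neuropil_ring(roi, movie.frame_shape, width=ring_width)
        amps = trial_response_amplitudes(
            movie, roi, ring, neuropil_factor=neuropil_factor,
            pre_window=pre_window, stim_window=stim_window)
        fra = build_fra(amps, schedule, grid, label=roi.label)
        bf, bl = best_frequency_level(fra)
        rows.append((roi.label, bf, bl, float(np.nanmax(fra.mean))))
    return pd.DataFrame(rows, columns=["label", "bf_hz", "bl_db_spl",
                                       "peak_dff"])
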