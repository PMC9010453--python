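"""Registration, trace extraction, dF/F, FRA assembly and BF/BL maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from quiet2p import fra_pipeline as fp
from quiet2p import stimuli as st
from quiet2p import synth_imaging as si


def _cell_image(shape=(64, 64), seed=0, n_blobs=12):
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(8, shape[0] - 8), rng.uniform(8, shape[1] - 8)
        img += rng.uniform(50, 150) * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.0 ** 2))
    return img + 20.0


# ------------------------------------------------------------ shifts ----

def test_shift_zero_for_identical_images():
    img = _cell_image()
    assert fp.estimate_rigid_shift(img, img) == (0.0, 0.0)


def test_shift_recovers_integer_translation():
    img = _cell_image(seed=1)
    moved = np.roll(np.roll(img, 3, axis=0), -2, axis=1)
    dy, dx = fp.estimate_rigid_shift(moved, img)
    assert dy == pytest.approx(3.0, abs=0.1)
    assert dx == pytest.approx(-2.0, abs=0.1)


def test_shift_recovers_subpixel_translation():
    img = _cell_image(seed=2)
    moved = ndimage.shift(img, (1.5, 0.0), order=3, mode="nearest")
    dy, dx = fp.estimate_rigid_shift(moved, img)
    assert dy == pytest.approx(1.5, abs=0.25)
    assert dx == pytest.approx(0.0, abs=0.25)


def test_shift_antisymmetric():
    a = _cell_image(seed=3)
    b = ndimage.shift(a, (0.7, -1.2), order=3, mode="nearest")
    fwd = np.array(fp.estimate_rigid_shift(a, b))
    rev = np.array(fp.estimate_rigid_shift(b, a))
    assert np.all(np.abs(fwd + rev) < 0.05)


def test_shift_rejects_constant_image():
    img = _cell_image()
    with pytest.raises(ValueError):
        fp.estimate_rigid_shift(img, np.ones_like(img))


# ------------------------------------------------------- registration ----

def _static_session(n_trials=2, fpt=15, shape=(48, 48), seed=5):
    img = _cell_image(shape, seed=seed)
    frames = np.repeat(img[None], n_trials * fpt, axis=0)
    bounds = tuple((i * fpt, (i + 1) * fpt) for i in range(n_trials))
    return fp.Movie(frames=frames, frame_rate=10.0, trial_bounds=bounds)


def test_register_static_session_is_identity():
    movie = _static_session()
    _, disp = fp.register_session(movie)
    assert np.all(np.abs(disp[["dy_px", "dx_px"]].to_numpy()) < 0.1)


def test_register_requires_trials_and_min_length():
    movie = _static_session()
    movie.trial_bounds = None
    with pytest.raises(fp.ProtocolError):
        fp.register_session(movie)
    short = _static_session(n_trials=1, fpt=5)
    with pytest.raises(fp.ProtocolError):
        fp.register_session(short)


def test_register_recovers_global_shift():
    """A globally shifted movie is aligned back to the unshifted content
    away from the edges."""
    base = _cell_image((48, 48), seed=6)
    # zero-mean shifts so the registration reference coincides with `base`
    shifts = [(0.0, 0.0), (2.0, -1.0), (-2.0, 1.0)]
    frames = []
    for dy, dx in shifts:
        for _ in range(12):
            frames.append(ndimage.shift(base, (dy, dx), order=3,
                                        mode="nearest"))
    movie = fp.Movie(frames=np.asarray(frames), frame_rate=10.0,
                     trial_bounds=((0, 12), (12, 24), (24, 36)))
    corrected, disp = fp.register_session(movie)
    d = disp.groupby("trial")[["dy_px", "dx_px"]].mean().to_numpy()
    rel = d - d.mean(axis=0)
    expect = np.asarray(shifts) - np.mean(shifts, axis=0)
    assert np.all(np.abs(rel - expect) < 0.1)
    interior = (slice(6, -6), slice(6, -6))
    dyn = np.ptp(base)
    for f in corrected.frames:
        assert np.mean(np.abs(f[interior] - base[interior])) < 0.01 * dyn


def test_register_idempotent_after_convergence(tiny_session):
    corrected, _ = fp.register_session(tiny_session["session"].movie,
                                       upsample_factor=50)
    _, disp2 = fp.register_session(corrected, upsample_factor=50)
    assert np.all(np.abs(disp2[["dy_px", "dx_px"]].to_numpy()) < 0.1)


# ------------------------------------------------------------- rings ----

def test_ring_of_single_pixel_is_disk_minus_center():
    from skimage.morphology import disk

    roi = fp.ROIMask(rows=[20], cols=[20])
    ring = fp.neuropil_ring(roi, (41, 41), width=5)
    expect = disk(5).astype(bool)
    expect[5, 5] = False
    got = ring.to_mask((41, 41))[15:26, 15:26]
    assert np.array_equal(got, expect)


def test_ring_disjoint_from_roi():
    rng = np.random.default_rng(8)
    for _ in range(50):
        r, c = rng.integers(5, 40, size=2)
        rad = rng.integers(1, 4)
        yy, xx = np.mgrid[:48, :48]
        mask = (yy - r) ** 2 + (xx - c) ** 2 <= rad ** 2
        roi = fp.ROIMask.from_mask(mask)
        ring = fp.neuropil_ring(roi, (48, 48))
        assert not np.any(ring.to_mask((48, 48)) & mask)


def test_ring_matches_brute_force_enumeration():
    """Ring of a disk ROI equals the set of outside pixels within
    Euclidean distance `width` of some ROI pixel."""
    yy, xx = np.mgrid[:40, :40]
    mask = (yy - 20) ** 2 + (xx - 20) ** 2 <= 5 ** 2
    roi = fp.ROIMask.from_mask(mask)
    ring = fp.neuropil_ring(roi, (40, 40), width=5).to_mask((40, 40))
    brute = np.zeros((40, 40), dtype=bool)
    rr, cc = np.nonzero(mask)
    for y in range(40):
        for x in range(40):
            if mask[y, x]:
                continue
            d2 = (rr - y) ** 2 + (cc - x) ** 2
            if d2.min() <= 25:
                brute[y, x] = True
    assert np.array_equal(ring, brute)


# ------------------------------------------------------------ traces ----

def _trace(values, stage="raw"):
    return fp.Trace(values=np.asarray(values, float), frame_rate=10.0,
                    stage=stage)


def test_neuropil_subtract():
    out = fp.neuropil_subtract(_trace([10.0] * 5), _trace([5.0] * 5))
    assert np.allclose(out.values, 8.0)
    ident = fp.neuropil_subtract(_trace([7.0] * 5), _trace([5.0] * 5),
                                 factor=0.0)
    assert np.allclose(ident.values, 7.0)
    zero = fp.neuropil_subtract(_trace([5.0] * 5), _trace([5.0] * 5),
                                factor=1.0)
    assert np.allclose(zero.values, 0.0)
    with pytest.raises(ValueError):
        fp.neuropil_subtract(_trace([1.0] * 4), _trace([1.0] * 5))


def test_compute_dff():
    tr = _trace([1.0, 1.0, 1.2, 1.4])
    dff = fp.compute_dff(tr, slice(0, 2))
    assert np.allclose(dff.values, [0.0, 0.0, 0.2, 0.4])
    assert dff.stage == "dff"
    # constant trace -> all zeros
    const = fp.compute_dff(_trace([3.0] * 6), slice(0, 3))
    assert np.allclose(const.values, 0.0)
    with pytest.raises(fp.BaselineError):
        fp.compute_dff(_trace([-1.0, -1.0, 2.0]), slice(0, 2))


def test_dff_prestim_mean_is_zero():
    rng = np.random.default_rng(11)
    for _ in range(100):
        tr = _trace(rng.uniform(0.5, 2.0, size=30))
        dff = fp.compute_dff(tr, slice(0, 10))
        assert dff.values[:10].mean() == pytest.approx(0.0, abs=1e-12)


def test_response_amplitude():
    dff = _trace([0.0, 0.3, 0.3, 0.3, 0.1], stage="dff")
    assert fp.response_amplitude(dff, slice(1, 4)) == pytest.approx(0.3)
    assert fp.response_amplitude(dff, slice(4, 5)) == pytest.approx(0.1)
    rng = np.random.default_rng(12)
    v = rng.normal(size=50)
    assert fp.response_amplitude(_trace(v, "dff"), slice(10, 35)) == \
        pytest.approx(v[10:35].sum() / 25)


def test_pipeline_invariances():
    """Scaling the movie by k leaves dF/F unchanged; a ring proportional to
    the cell trace acts as a pure gain and leaves dF/F unchanged too."""
    rng = np.random.default_rng(13)
    n, fpt = 6, 12
    frames = rng.uniform(50, 60, size=(n * fpt, 16, 16))
    bounds = tuple((i * fpt, (i + 1) * fpt) for i in range(n))
    roi = fp.ROIMask(rows=[8, 8, 9], cols=[8, 9, 8])
    m1 = fp.Movie(frames=frames, frame_rate=10.0, trial_bounds=bounds)
    m2 = fp.Movie(frames=3.7 * frames, frame_rate=10.0, trial_bounds=bounds)
    a1 = fp.trial_response_amplitudes(m1, roi)
    a2 = fp.trial_response_amplitudes(m2, roi)
    assert np.allclose(a1, a2, atol=1e-12)

    t = fp.extract_trace(m1, roi)
    ring_prop = fp.Trace(values=0.5 * t.values, frame_rate=10.0)
    sub = fp.neuropil_subtract(t, ring_prop, factor=0.4)
    d_plain = fp.compute_dff(
        fp.Trace(values=t.values[:fpt], frame_rate=10.0), slice(0, 6))
    d_sub = fp.compute_dff(
        fp.Trace(values=sub.values[:fpt], frame_rate=10.0), slice(0, 6))
    assert np.allclose(d_plain.values, d_sub.values, atol=1e-12)


# --------------------------------------------------------------- FRA ----

def _grid_and_schedule(cycles=2, seed=1):
    grid = st.make_fra_grid(n_freqs=4, level_lo=5.0, level_hi=65.0,
                            level_step=30.0)
    return grid, st.make_session_schedule(grid, cycles=cycles, seed=seed)


def test_build_fra_uniform_and_counts():
    grid, sched = _grid_and_schedule(cycles=3)
    fra = fp.build_fra(np.full(sched.n_trials, 0.42), sched, grid)
    assert np.allclose(fra.mean, 0.42)
    assert np.all(fra.n_reps == 3)
    # trial count conserved
    assert fra.n_reps.sum() == sched.n_trials


def test_build_fra_matches_groupby_oracle():
    grid, sched = _grid_and_schedule(cycles=4, seed=7)
    rng = np.random.default_rng(14)
    resp = rng.normal(size=sched.n_trials)
    fra = fp.build_fra(resp, sched, grid)
    df = sched.to_frame().assign(resp=resp)
    oracle = df.groupby(["frequency_hz", "level_db_spl"])["resp"].mean()
    for i, f in enumerate(fra.frequencies):
        for j, l in enumerate(fra.levels):
            assert fra.mean[i, j] == pytest.approx(oracle[(f, l)])


def test_build_fra_standard_session_reps(small_grid):
    sched = st.make_session_schedule(small_grid, cycles=10, seed=0)
    fra = fp.build_fra(np.zeros(sched.n_trials), sched, small_grid)
    assert np.all(fra.n_reps == 10)


def test_best_frequency_level():
    grid, sched = _grid_and_schedule()
    fra = fp.build_fra(np.zeros(sched.n_trials), sched, grid)
    # uniform FRA -> tie rule: lowest level, then lowest frequency
    assert fp.best_frequency_level(fra) == (grid.frequencies[0],
                                            grid.levels[0])
    fra.mean[2, 1] = 1.0
    assert fp.best_frequency_level(fra) == (grid.frequencies[2],
                                            grid.levels[1])
    fra.mean[:] = np.nan
    with pytest.raises(ValueError):
        fp.best_frequency_level(fra)
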