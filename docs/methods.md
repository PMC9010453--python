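# Methods

This note documents the models behind `quiet2p`, the defaults and why,
the numerical conventions, and what the synthetic-data tests do and do not
establish.

## Scan optics

**Model.** Thin-lens paraxial optics throughout. A linear chirp of rate
`r` (Hz/s) on an AOD with acoustic velocity `v` behaves as a cylindrical
lens with focal length `F = v^2 / (lambda * |r|)`; its sign follows the
divergence (an up-chirp diverges the beam). The DvCL of focal length
`f_dvcl` collimates the nominal rate, so the nominal line time over the
chirp bandwidth `B` is `T = B * lambda * f_dvcl / v^2`. The scan/tube
lens pair is treated as an afocal 4f relay (AOD at the scan-lens front
focus, objective pupil at the tube-lens back focus) with angular
magnification `f_scan/f_tube`; the FOV is
`(lambda*B/v) * (f_scan/f_tube) * f_objective`. Detuning the chirp rate
leaves a residual vergence `V0 = 1/f_dvcl - 1/F(r)` after the DvCL, which
the relay maps exactly (B = C = 0 in the block ray matrix) to
`V1 = V0 * (f_scan/f_tube)^2` at the objective pupil; the focus sits at
`1/(1/f_obj + V1)`, so the axial shift is
`dz = -V1 f_obj^2 / (1 + V1 f_obj)` — exactly linear in the chirp rate in
`V1`, and approximately `-V1 f_obj^2` for the small shifts of interest.
Sign convention: **positive `dz` = deeper** (farther from the objective);
a faster-than-nominal chirp diverges the beam and focuses deeper. The
implementation is validated against an independent ray-transfer-matrix
trace of the DvCL–scan–tube–objective chain (agreement required to <1%
for |dz| < 100 um).

**Key defaults.**

| parameter | default | rationale |
|---|---|---|
| acoustic velocity | 650 m/s | TeO2 slow-shear mode; reproduces the 65.3-us and 0.585-um anchors exactly |
| chirp bandwidth | 30 MHz | drive-electronics chirp span |
| wavelength | 920 nm | GCaMP two-photon excitation |
| f_dvcl / f_scan / f_tube / f_obj | 1.0 / 0.100 / 0.200 / 0.018 m | 1000-mm DvCL, 100/200-mm relay, 10x objective on the 180-mm tube standard; all configurable |
| beam diameter | 8.45 mm | *inferred*, not measured: back-solved so that the acoustic fill time `d/v` is ~13 us; the published transition-time convention is not reproduced here |
| digitizer rate | 10 MHz | one pixel per sample |
| line-time quantum | 0.1 us | reporting convention, below |

**Quantization convention.** Line times are rounded to 0.1 us and
`pixels_per_line = floor(line_time * 10 MHz)`; the slow axis is chirped
one pixel short (`lines = pixels - 1`), and
`frame_rate = 1/(lines * line_time)`. This is the only combination that
simultaneously yields 23.5, 41.7 and 93.8 fps for the 1000/750/500-mm
DvCLs; an un-quantized mode (`rounding=None`) is also exposed. A one-ppm
guard is added before the floor so that the exact-product case (65.3 us x
10 MHz = 653) is not lost to float representation.

**Pulses.** Autocorrelation deconvolution uses the standard shape
factors (0.65 for sech^2, 1/sqrt(2) for Gaussian). Dispersive broadening
uses the Gaussian-equivalent formula
`tau_out = tau_in * sqrt(1 + (4 ln2 GDD / tau_in^2)^2)` for both shapes;
exact sech^2 propagation differs by a few percent and is deliberately not
modelled. `gdd_for_broadening` is its closed-form inverse.

## Acoustic noise assessment

**PSD.** The default estimator follows the single-record convention: the
whole record is Fourier transformed and the one-sided FFT-bin powers are
summed into 1-Hz bins centred on integer frequencies, which makes the bin
sum Parseval-exact against the mean-square (AC) pressure; the DC
component is removed first. A Welch option (1-s Hann segments, 50%
overlap) is available for variance reduction. Levels are dB SPL/Hz re
20 uPa with a -120 dB floor sentinel for empty bins. Dual-microphone
spectra are merged by taking the low-noise microphone below the crossover
(default 23 kHz) and the extended-range microphone above; the merged grid
must remain gap-free.

**Excitation patterns.** Filters are symmetric, level-independent
roex(p): `W(g) = (1+pg)exp(-pg)`, `p = 4 fc / Bs(fc)`, so the equivalent
rectangular bandwidth equals the species tuning bandwidth `Bs`. The
excitation grid defaults to 64 points/octave over the species' hearing
range. Because the filters are level independent, excitation is exactly
linear in dB offsets of the input spectrum — a property test. The
level-dependent asymmetric filters and specific-loudness compression of
full loudness models are out of scope by design; `roex_weights` is the
extension hook.

**Species profiles.** Audiogram anchors are interpolated with a monotone
cubic (PCHIP) in (log f, dB); queries outside the anchors raise rather
than extrapolate. Tuning bandwidths are log-log power laws
`Bs(f) = a f^b`. The packaged marmoset, CBA/CaJ and C57BL/6J profiles are
**coarse approximations** of published behavioral/physiological data
(marmoset threshold anchored at 10.6 dB SPL @ 8 kHz, bandwidth ~10.5% of
centre frequency; mouse bandwidths broader at ~25%); their provenance
strings say so, and publication-grade use should re-digitize the primary
sources. `microphone_noise_floor` is a smooth model of the calibration
microphones' documented self-noise orders of magnitude (-26 and
-21 dB SPL/Hz near 10 kHz with a 1/f rise below 100 Hz), used as a
reference spectrum, not a measurement. No outer/middle-ear or free-field
corrections are applied.

## Stimuli

Tone pips are sine carriers with sine-squared (cos^2) on/off ramps
(default 0.2-s pips, 20-ms ramps); first and last samples are exactly
zero. Amplitudes are calibrated so the plateau RMS matches the requested
dB SPL re 20 uPa through a `calibration_ref` (Pa per output unit).
Semitone sequences are exactly geometric (ratio 2^(1/12)); descending is
the element-wise reverse of ascending. The mapping grid defaults to 31
frequencies from 440 Hz in 2-semitone steps — i.e. 5 octaves, topping out
at 14080 Hz — crossed with 5 levels (5–65 dB SPL, 15-dB steps): 155 trial
types. A 25-frequency/4-octave variant (top 7040 Hz) is available via
`n_freqs=25`; both conventions appear in the auditory mapping literature
and the grid is fully parametric. Trials are 3 s (0.6 pre / 0.6 stimulus
/ 1.8 post) with three contiguous pips filling the stimulus window (3 x
0.2 s leaves no room for gaps). Pseudo-randomization is an independent
seeded permutation per cycle; every grid cell appears exactly once per
cycle and schedules are bijections grid x cycles -> trials.

## FRA pipeline

**Registration.** The engine is rigid subpixel translation: the
cross-correlation peak (un-normalized, via `phase_cross_correlation` with
Fourier upsampling; default quantum 0.05 px) between frame and template,
with the sign convention displacement = content motion (template ->
frame); frames are corrected by the negated displacement using bilinear
interpolation with replicated edges. The protocol is hierarchical: within
each trial all frames register to a template built from the 10 middle
frames; then the per-trial averages register to their grand average and
the cross-trial shift folds back into every frame. Two deliberate
refinements of the naive reading: (1) the 10 template frames are first
registered to the central frame and averaged *after* correction — a
straight average of moving frames smears the template and biases the
frame registration toward zero lag (each frame matches its own smeared
copy; in simulation this inflated the residual from ~0.04 px RMSE to
~1.2 px); (2) the two-stage pass is iterated, accumulating displacements
and re-estimating on the provisionally corrected movie, until the largest
update is below `tol` (default 0.05 px, max 4 passes), after which the
protocol is idempotent. The final movie applies the accumulated
displacement to the raw frames in a single interpolation. Non-rigid
registration is out of scope.

**Traces.** ROI fluorescence is the mean over ROI pixels (mean rather
than sum, for gain invariance). The neuropil ring is the morphological
dilation of the ROI by a Euclidean disk of radius 5 px minus the ROI
(no gap), and the correction is `F_cell - 0.4 * F_ring` per frame.
`Delta F/F = (F - F0)/F0` with `F0` the mean over the pre-stimulus window
of each trial (frames in [0, 0.6) s; stimulus window [0.6, 1.2) s; both
configurable). A non-positive `F0` flags the cell (NaN amplitude for that
trial) instead of clipping. The response amplitude is the mean dF/F over
the stimulus window; correction precedes normalization. FRA cells average
the amplitudes of their repetitions; BF/BL is the argmax of the mean
matrix with exact ties broken toward the lowest level, then the lowest
frequency. No responsiveness criterion is applied when mapping BF/BL.

## Synthetic sessions

The simulator emulates the statistical structure the pipeline assumes —
and only that: Gaussian-profile somas (sigma = radius/2) on a constant
neuropil background, response surfaces of three classical FRA classes
(V: log-frequency Gaussian whose width grows with level, times a
monotone sigmoid level gain; I: fixed width, same gain; O: separable
Gaussians in log-frequency and level peaked at (bf, bl)), a
double-exponential calcium impulse response
`(1 - e^{-t/0.2 s}) e^{-t/1.5 s}` (GCaMP6s-like) superposing linearly
across trials, rigid motion (per-axis 4-Hz sinusoid, default 2 px, plus a
linear drift, default 3 px, capped at 5 px total, expressed about the
session-mean position since the absolute offset is arbitrary and
registration can only recover relative alignment — this keeps the
ground-truth ROI coordinates valid on the registered movie, as they are
for ROIs drawn on a corrected recording), and Gaussian noise
with variance `read^2 + gain * signal` (a Gaussian shot-noise
approximation). Peak response amplitudes are drawn from 0.1–1.0 dF/F, a
typical single-cell range for slow indicators — a simulator convention,
not a measured fact. Motion is applied with cubic-spline interpolation,
deliberately a different interpolator from the bilinear one used by the
correction step, so simulator and method do not share that code path.
All generators are pure functions of (config, seed).

Not emulated: optical PSFs and depth sectioning, dendritic morphology and
overlapping processes, neuropil dynamics (the background is temporally
constant), non-rigid deformation, bleaching, and spiking-level dynamics.
Passing closed-loop tests therefore shows the pipeline is correct under
its own assumptions, not that those assumptions hold in any particular
recording.

**Closed-loop validation sizes.** The identity check (noise and motion
off) uses a sparse 96x96 scene where rings sample pure background, so the
true contamination factor is exactly 1.0 and the pipeline must match the
simulated amplitudes to <2% RMS. The full stochastic loop uses the
study-design trial structure — the 155-type grid, 10 cycles, 1550 trials
— with 100 neurons on a spatially and temporally downscaled movie
(64 x 64 px, 10 fps, soma radius 2 px), chosen so the whole
simulate-register-extract-map loop runs in a couple of minutes; it
requires displacement RMSE < 0.3 px and >= 90% of high-SNR neurons
(peak dF/F >= 0.3) recovering BF within one 2-semitone step and BL within
one 15-dB step. At that density soma spacing is only ~2 radii, so some
ring crosstalk and argmax jitter are expected and the 90% bound is not
slack.

## Known limitations

* Paraxial, aberration-free optics; no diffraction-efficiency or PSF
  modelling; the beam-diameter default (hence the 13-us transition time)
  is an inference.
* Species profiles are placeholder fits; excitation patterns omit
  middle-ear transfer and level-dependent filter asymmetry, so absolute
  exceedance values near threshold should be read with a few dB of
  humility.
* The registration engine is strictly rigid; sessions with substantial
  non-rigid deformation need an external tool, after which the rest of
  the pipeline applies unchanged.
* WAV input supports PCM and float via scipy; exotic WAV subformats are
  not handled.
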