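# quiet2p

Design and analysis toolkit for **silent, AOD-based two-photon imaging of
auditory neuronal function**: acousto-optic raster-scan design math,
species-aware acoustic noise assessment, calibrated auditory stimulation,
and a calcium-imaging frequency-response-area (FRA) pipeline validated
against a ground-truth movie simulator.

## Why

Conventional two-photon microscopes scan with galvanometer mirrors whose
mechanical resonances (e.g. an 8-kHz resonant scanner) radiate sound right
where auditory experiments are most sensitive. A pair of orthogonal
acousto-optical deflectors (AODs) scans silently: a linear frequency chirp
of rate $r$ travelling across the crystal at acoustic velocity $v$ deflects
a beam of wavelength $\lambda$ while acting as a cylindrical lens of focal
length

$$F = \frac{v^2}{\lambda\,|r|},$$

which a fixed convex lens (the divergence compensation lens, DvCL, focal
length $f_{\mathrm{DvCL}}$) collimates at the *nominal* chirp rate. The
line time to sweep the full chirp bandwidth $B$ is then
$T = B\lambda f_{\mathrm{DvCL}}/v^2$, and detuning the chirp rate shifts
the focal plane axially without any moving part — multi-layer scanning for
free. `quiet2p.scan_optics` implements these closed-form relations plus
frame geometry, field of view, dark-periphery and ultrafast-pulse
dispersion utilities.

Whether a rig is "quiet" depends on who is listening. A noise power
spectral density $N(f)$ (dB SPL/Hz) is integrated through a bank of
rounded-exponential (roex) auditory filters
$W(g) = (1+pg)e^{-pg}$, $g = |f-f_c|/f_c$, $p = 4f_c/B_s(f_c)$, whose
equivalent rectangular bandwidth equals the species' tuning bandwidth
$B_s(f_c)$, giving an **excitation pattern**

$$E(f_c) = 10\log_{10}\sum_f W(f;f_c)\,10^{N(f)/10}\,\Delta f
\quad\text{(dB SPL)},$$

directly comparable to the species' pure-tone hearing threshold.
`quiet2p.acoustics` provides calibrated 1-Hz-bin PSDs, dual-microphone
merging, packaged marmoset/mouse profiles and the threshold-exceedance
report.

`quiet2p.stimuli` builds the corresponding experiments — semitone pip
sweeps and pseudo-randomized frequency × level grids —, and
`quiet2p.fra_pipeline` takes movies from motion correction (hierarchical
two-stage rigid registration) through ring-based neuropil subtraction,
per-trial $\Delta F/F = (F-F_0)/F_0$, and FRA matrices to best-frequency /
best-level maps. `quiet2p.synth_imaging` generates ground-truth-labelled
synthetic sessions (V/I/O-shaped tuning, GCaMP6s-like kinetics, ~4-Hz
heartbeat motion plus drift, shot-like noise) so the whole pipeline is
tested closed-loop without any recorded data.

## Worked example

```python
from quiet2p import scan_optics as so

aod = so.AODSpec()            # 650 m/s, 30 MHz bandwidth, 8.45 mm beam
relay = so.RelaySpec()        # 920 nm, f_DvCL = 1 m, 100/200 mm, 18 mm obj
program = so.chirp_program_for_dvcl(aod, relay)
geo = so.raster_frame_geometry(aod, relay, program)
print(f"line time  {program.line_time * 1e6:.1f} us")
print(f"frame      {geo.pixels_per_line} x {geo.lines_per_frame} px "
      f"at {geo.frame_rate:.1f} fps")
print(f"pixel      {geo.pixel_size * 1e6:.3f} um, "
      f"dark fraction {geo.dark_fraction:.3f}")
```

prints

```
line time  65.3 us
frame      653 x 652 px at 23.5 fps
pixel      0.585 um, dark fraction 0.199
```

i.e. collimating through the 1-m DvCL takes a 65.3-us line chirp, giving
video-rate (23.5 fps) full frames of 653 × 652 pixels at 0.585 um per
pixel, with 19.9% of each line period spent in the inter-line transition
(the dark periphery). Shorter DvCLs trade FOV margin for speed: 41.7 fps
at f = 750 mm, 93.8 fps at f = 500 mm.

The same calculators are scriptable from the shell
(`quiet2p scan design`, `quiet2p scan depth`), as are noise assessment
(`quiet2p noise assess --wav rig.wav --species marmoset`), stimulus
generation (`quiet2p stim fra`, `quiet2p stim sweep`), synthetic sessions
(`quiet2p sim session`) and the analysis (`quiet2p fra run`).

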