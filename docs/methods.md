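# Methods

## Measurement model

A cylindrical metal bar (length 14.5 cm, diameter 0.5 cm) is suspended in
the beam of a bore-type linac at gantry 0 and can be wound between two
heights separated by `B` = 20.473 cm. An ionization chamber on a lateral
stage below records current as it steps across the bar's shadow. The bar
axis lies horizontal, perpendicular to the scan direction, so each profile
shows a single rounded dip whose center is the point projection of the bar
axis through the source. For a lateral focal-spot offset `a` (mm) and the
bar laterally centered on the reference axis, the dip center at the
acquisition plane sits at

    d_up   = -a (B + C) / A          (bar upstream,   axis depth A)
    d_down = -a C / (A + B)          (bar downstream, axis depth A + B)

with `C` the bar-to-chamber clearance (3.65 cm) and `A = SAD - B`
(64.527 cm at SAD 85 cm). The inversion

    a = sign_axis * (d2 - d1) / k,   k = (B+C)/A - C/(A+B) = 0.33090...

is exact for this forward model. Two divisor modes exist: the
full-precision `k` (default) and the two-decimal convenience divisor 0.33
(`paper_rounded`), which reproduces published two-decimal results digit for
digit; on sub-millimetre offsets the two differ by well under 0.01 mm.

Axis-orientation signs map the chamber-stage frame to the IEC frame. They
are configuration, not physics: the defaults (+1 for IEC-X, -1 for IEC-Y)
are the pair consistent with published sign conventions for this setup, and
both are explicit keys (`axis_sign_x`, `axis_sign_y`) because the stage
mounting, not the method, fixes them.

## Dip-center estimation

The profile derivative is a three-point central difference,
`(c[i+1]-c[i-1])/(x[i+1]-x[i-1])`, exact for linear data on the nonuniform
stage grid; endpoints are dropped. The dip center is the derivative's
negative-to-positive zero crossing near the current minimum, located within
a window centered on the minimum-current sample (default halfwidth 1.0 mm,
matching the finely sampled central region of the default schedule) by one
of two deterministic estimators:

- `bracket_interp` — linear interpolation across the sign-changing sample
  pair nearest the minimum; the literal reading of "where the derivative
  becomes zero".
- `local_linear_fit` (default) — least-squares line through every
  derivative sample in the window, root at `-intercept/slope`; it uses all
  fine-region samples and is robust to single-sample noise. A non-positive
  fitted slope (no minimum) or a root outside the window is an error.

No smoothing is applied by default; an optional centered moving average
(`smooth_window`) exists but is off, since the estimators already average
over the window. Known bias: because the window is anchored to the
minimum-current *sample*, its sample set can be asymmetric about the true
center by up to half a sampling interval, and the derivative's cubic
component then biases the fitted root by roughly 1% of the offset (about
0.015 mm at a 1 mm offset on the default grid, noiseless). This is an
order of magnitude below the measurement's combined uncertainty and is
covered by the parameter-recovery tests; bracketing interpolation does not
share the bias but is noisier on real data.

Repeat scans aggregate to mean, sample SD (n-1) and SD of the mean.

## Simulator

The generator emulates the measurement hardware, not just its statistics:

- **Ray tracing.** Exact line/finite-cylinder intersection (any axis
  orientation), attenuated as `exp(-mu * path)` with a single effective
  coefficient (default 0.4 /cm, a generic metal at 6 MV; the central dip
  depth is then ~18%). The dip center is insensitive to `mu` by
  construction, which the tests check over mu in [0.1, 5] /cm.
- **Source and detector.** The focal spot is a 1-D Gaussian (default FWHM
  1.0 mm — invented realism, no published value; the center is first-order
  insensitive to it), integrated with 21 Gauss-Hermite nodes; the chamber
  aperture is a 2.0 mm uniform window, 11 midpoint nodes. The open field is
  flat across the scanned +/-10 mm (the analysis touches only the central
  dip, so no penumbra model).
- **Sampling.** The default stage schedule is 1 mm steps over +/-(5-10) mm,
  0.2 mm over +/-(1-5) mm, 0.1 mm over +/-1 mm — 71 positions. Each
  position is read 5 times with independent multiplicative Gaussian noise
  (default CV 0.002 per reading, chosen to put the single-scan dip-center
  repeatability at the few-hundredths-of-a-mm scale seen in practice); the
  stored value is the sample mean, with the per-point SD carried as a
  diagnostic column.
- **Sessions.** Reproducibility is modeled as a Normal(0, 0.08 mm) lateral
  bar shift per session (one realignment per session, common to both
  heights) — a modeling choice echoing the magnitude of published
  reproducibility components, not a measured value. A bar shift is almost
  exactly equivalent to a focal shift for this geometry, so it propagates
  ~1:1 into the estimate and dominates the synthetic budget. All randomness
  derives from one base seed through a fixed spawn order; sessions
  regenerate byte-identically from the manifest.

Not emulated: scatter, spectral/beam-hardening effects, penumbra, chamber
dose-rate dependence, stage backlash, or bar sag. Passing tests therefore
demonstrate the correctness of the geometry, estimator and statistics
chain under idealized noise, not the field behavior of a physical rig.

## Uncertainty budget

Type-A components: repeatability is the pooled within-session SD of the
dip centers (RMS of per-session variances), reproducibility the SD across
session means (requires >= 2 sessions). Both `sd` and `sd_of_mean` modes
exist because published budgets do not always state which is meant;
default `sd`. Type-B: the finest sampling interval enters through the
rectangular model `(interval/2)/sqrt(3)` = 0.029 mm for 0.1 mm by default;
an `as_given` mode passes through externally assigned values for
reproducing budgets whose derivation is unstated. Components combine by
root-sum-square *on the dip-center deviations* — the published convention,
which applies no 1/k sensitivity factor; dividing the combined value by
`k` to express it at focus height is offered as a clearly labeled
extension (`propagate_to_focus`), not the default. Geometry uncertainties
(A, B, C) are excluded by default as an order of magnitude smaller than
the dip-center terms. Expanded uncertainty (k=2) and effective degrees of
freedom are out of scope.

## Problem sizes and numerical choices

The test suite runs the full chain at the sizes the protocol itself uses:
single noiseless scans for recovery (71-point schedule), 50-draw Monte
Carlo for noise scaling, and a 10-repeat x 3-session study for the
end-to-end check — a few seconds in total. Dense-grid (1 um) scans verify
that both estimators agree with the continuous model's minimum to 1e-3 mm.
Ray/cylinder intersections use the standard quadratic form with a 1e-14
guard for axis-parallel rays; degenerate geometry (k = 0) and windows with
fewer than 4 derivative samples are hard errors rather than warnings.
Profile files store shortest-exact float reprs so I/O round-trips are
lossless and session regeneration is byte-identical.

## Limitations

The three-session reproducibility component rests on 2 degrees of freedom,
so synthetic budgets scatter widely around the injected value (the tests
allow 50%). The flat-field assumption restricts schedules to the central
field region (a warning fires beyond +/-50 mm). The forward model treats
the bar as laterally centered; a static bar misalignment is equivalent to
a focal offset and cannot be separated by this measurement alone — only
per-session realignment scatter is modeled.
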