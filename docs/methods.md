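# Methods

## The temperature-based aquagram

The method rests on the idea of a *structural temperature*: any perturbation
of an aqueous system changes the balance of water molecular species (free OH,
singly to multiply hydrogen-bonded clusters, hydration water), and pure water
sweeps through a continuum of such balances as it is heated from 20 to 70 °C.
A perturbation can therefore be scored, coordinate by coordinate, as the
temperature change that would have produced the same spectral response in
pure water.

The chain, per water matrix coordinate (WAMAC):

1. **Scan averaging.** Consecutive scans are averaged per reference
   temperature and per experimental group.
2. **Baseline.** A straight line is fitted by ordinary least squares to the
   points within 5 nm of both edges of the first overtone region (1300 and
   1600 nm) and subtracted. Fitting a short edge *region* rather than the
   two single edge samples suppresses the leverage that photometric noise at
   two isolated points would otherwise exert across the whole 300 nm window
   (a single noisy endpoint tilts the baseline under every coordinate). With
   `edge_halfwidth_nm=0` the fit degenerates to the exact line through the
   two endpoint samples.
3. **Relative areas.** Trapezoidal area over the coordinate's range divided
   by the area over the full 1300–1600 nm window. The ratio is exactly
   invariant under per-spectrum multiplicative scatter, and step 2 removes
   any linear additive component, so relative areas are scatter- and
   pathlength-proof. Trapezoid on the native 0.5 nm grid is used; the grid
   is dense and uniform, higher-order rules change nothing measurable.
4. **Reference curves.** Each coordinate's relative area is regressed
   against reference temperature by tricube-weighted local polynomial
   regression (LOESS-style; degree 2, span 0.5 as a fraction of the 26
   reference points, evaluated on a 0.1 °C grid). The method name is fixed;
   degree, span and grid step are free parameters and are config-exposed.
   On noiseless synthetic references the smoother reproduces the underlying
   curve to ~1e-6 relative area, so it contributes no measurable bias.
5. **Local calibration.** An OLS line r = α + βT is fitted to the smoothed
   curve inside a window of ±2 °C around the experiment temperature
   (clipped to the reference span at the edges; a window entirely outside
   the span is an error). The line is fitted to the *smoothed* curve, not
   the raw points, so the calibration inherits the smoother's noise
   suppression.
6. **Inversion.** A group's relative area r* maps to (r* − α)/β °C. A
   coordinate is *conditioned* when |β| ≥ 1e-3 × (that coordinate's full
   curve range) per °C; near-isosbestic coordinates legitimately have β ≈ 0
   and are flagged rather than reported as huge temperatures.
7. **Uncertainty.** The group's spectra are resampled with replacement
   (n_boot = 1000 by default) and pushed through steps 1–6; percentile
   2.5/97.5 bounds form the 95% interval. The reference is a fixed
   calibration and is not resampled. A group of one spectrum yields a
   zero-width interval.

Because each group's value depends only on its own spectra and the
reference, temperature-based aquagrams are invariant to which other groups
appear in the same call — the property the classic aquagram lacks.

**Experiment temperature.** For a single-temperature experiment pass
`experiment_T` explicitly (e.g. 28 °C for an incubated series). For runs
where the reference ramp itself is the experiment, `experiment_T=None`
calibrates each group in a window centered on its own nominal temperature,
so the full 20–70 °C span is representable; this per-group-window mode is
the only reading under which 26 different temperatures can share one chart.

**Delta reporting.** With a `control_group`, values are additionally
reported as group °C − control °C, with the control's point value treated
as a fixed offset for the confidence limits. Absolute values remain the
default output.

## The classic aquagram

Spectra are subset to 1300–1600 nm, corrected by multiplicative scatter
correction (MSC: each spectrum regressed on the mean spectrum of the
examined set and back-transformed; SNV available as an alternative), then
z-scored per wavelength using the mean and sample SD (n−1 throughout) over
*all* spectra in the call, and averaged per group at the twelve coordinate
center wavelengths (nearest grid point within 1e-6 nm; no range averaging
— the classic statistic is indexed by single wavelengths). The whole-set
reading of "the examined group" is deliberate: it is the only reading that
reproduces the classic aquagram's documented subset instability, and it
implies the size-weighted mean of all group values at a coordinate is
exactly zero. Per-group standardization is exposed via `scope="group"` for
comparison. Bootstrap intervals resample spectra within groups while
holding the MSC reference and standardization context fixed — the context
is a property of the examined set, not of the group.

## The WAMAC scheme

Twelve coordinates centered at 1342, 1364, 1374, 1384, 1412, 1426, 1440,
1452, 1462, 1476, 1488 and 1512 nm, each spanning center ± 6 nm, so C01
covers 1336–1348 nm. One uniform ±6 nm rule is used for all coordinates
because it reproduces C01's conventional range exactly; adjacent ranges may
overlap (C08 1446–1458 and C09 1456–1468 do). Some sources place C07 at
1432–1444 nm (center 1438); this package uses 1440 ± 6 and any coordinate
can be overridden via a YAML scheme file, which also allows entirely
different coordinate sets for other spectral regions.

## The synthetic water model

Spectra are sums of Gaussian species bands on a linear baseline, with band
amplitudes linear in temperature around 45 °C, plus per-spectrum
multiplicative/additive scatter and white photometric noise per scan.
Amplitude rates satisfy Σ σᵢ·(dAᵢ/dT) = 0 (total band area conserved), which
guarantees a temperature-invariant (isosbestic) crossing; the growing
1412 nm (weakly bonded) and shrinking 1462 nm (strongly bonded) amplitudes
produce the blue shift of the composite maximum with heating.

Two stock models:

* `two_band_model()` — 1412 nm (σ 22 nm, base 0.55, +0.0045 AU/°C) and
  1462 nm (σ 30 nm, base 0.75, −0.0033 AU/°C). The minimal mechanism that
  shows the blue shift, the isosbestic point and second-derivative minima
  at the two species bands.
* `rich_water_model()` — five components: 1342 nm (σ 16, base 0.20,
  +0.0070/°C, free OH), 1412 nm (σ 22, base 0.85, +0.0090/°C), a narrow
  bulk species at 1460 nm (σ 6, base 0.08, −0.0020/°C), the broad
  strongly-bonded band at 1462 nm (σ 30, base 0.60, rate set by area
  conservation ≈ −0.0078/°C) and a hydration/strongly-bonded wing at
  1484 nm (σ 18, base 0.10, −0.0035/°C).

The rich model's rates are deliberately strong — relative band areas sweep
a wide dynamic range over 20–70 °C — so that every one of the twelve
coordinates carries a well-conditioned calibration slope. The model is
calibrated to phenomenology, not to the absolute per-°C change of any
particular instrument's water spectra. The 1412/1462 base amplitudes are
balanced so the composite band maximum at the experiment temperature falls
*between* the species bands, as it does in real water, rather than on top
of the strongly-bonded band; this balance is what lets a solute blue-shift
the raw band maximum while still raising the far long-wavelength
coordinates (see below).

**Solute mechanism.** A structure-breaking solute is modelled as a
difference spectrum linear in effect, with effect = log10(1 + c/1 mM) so
high concentrations dominate. Per unit effect the stock coefficients are
+0.002 (1342), +0.006 (1412), −0.014 (1460), −0.007 (1462), +0.010
(1484) AU: the bulk hydrogen-bonded components are depleted and both wings
are fed — more free/weakly-bonded water on the short side (reading as a
temperature increase at C01–C08) and an ion-hydration species on the long
side that enriches C10–C12 beyond what any pure-water warming produces
(reading as a temperature *decrease* there). A structure maker is the sign
flip. Two-band variants cannot reproduce this pattern: with only two bands
every amplitude perturbation is spectrally equivalent to some temperature
change (relative areas depend only on the amplitude ratio), so all twelve
coordinates would report the same °C value. The five-component structure is
the smallest found that yields the blue shift, the sign flip at C10–C12 and
well-conditioned slopes simultaneously.

Scatter draws are per spectrum, not per wavelength, so MSC (an affine
per-spectrum model) and the relative-area normalization can remove them
exactly — making the scatter-invariance tests exact oracles rather than
statistical ones.

Defaults emulate the canonical study design: 26 temperature steps
(20–70 °C in 2 °C increments) × 3 consecutive scans = 78 reference spectra;
30 concentrations (1–1000 mM, log-spaced) × 2 repeats × 3 scans + 150
interleaved water controls = 330 experimental spectra; 1300–1600 nm at
0.5 nm steps. Default noise is 0.001 AU (≈0.1% of the band maximum,
instrument-level), multiplicative scatter SD 1%, additive scatter SD
0.002 AU.

**What the simulator does not emulate.** Real water bands are neither
Gaussian nor amplitude-only in temperature (centers and widths drift);
photometric noise is wavelength-correlated, not white; solute effects
saturate. Passing tests therefore demonstrate the *pipeline's* correctness
(recovery, stability, invariances, interval behavior) under a mechanism
with the right qualitative structure — they do not validate quantitative
°C values for any real instrument or solute.

## Numerical choices and degenerate inputs

* Sample SD (n−1) everywhere a SD appears.
* Wavelength matching: absolute tolerance 1e-6 nm; no implicit
  interpolation or regridding anywhere.
* Savitzky–Golay derivatives: derivative with respect to wavelength in nm
  (scaled by the grid step); edge points are filled from the first/last
  window's polynomial and flagged in a mask; defaults 21 points, 2nd-order
  polynomial.
* MSC with < 2 spectra and no reference, a zero-variance reference, a
  constant spectrum under SNV, zero σ at a coordinate center in the classic
  flavor, and a non-positive total area in the temperature flavor are all
  hard errors naming the offending row or coordinate.
* A temperature window that only partially overlaps the reference span is
  clipped (a group at 20 °C in per-group mode calibrates on [20, 22] °C);
  an empty overlap is an error.
* Bootstrap resamples whole spectra (rows), never wavelengths; percentile
  intervals, no bias correction; n_boot ≥ 100 enforced; fixed seeds make
  every interval reproducible.

## Known limitations

* At photometric noise far above instrument level (on the order of 1% of
  the band maximum) the temperature equivalents of weakly-responding
  coordinates carry degree-scale uncertainty with 3-scan groups; the
  relative-area noise floor divided by the calibration slope bounds the
  attainable precision, and the conditioning flag does not currently
  incorporate the noise level. Larger groups, wider edge-fit windows, or a
  precision-aware conditioning threshold are the mitigations.
* The classic flavor's bootstrap holds the standardization context fixed;
  for very small examined sets the context's own sampling variability is
  not propagated.
* Problem sizes in the test and acceptance runs match the canonical design
  (26 × 3 reference spectra, groups of 3–6 scans, 200 Monte-Carlo
  replicates at n_boot = 500 for coverage); these are the study's own
  scales and run in seconds.
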