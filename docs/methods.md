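# Methods

## Model

Each targeted compound *i* contributes one preselected target signal at
position δ_i on a uniform ppm grid (0.0002 ppm/bin at 600 MHz by default;
both are parameters). The observed height at δ_i in spectrum *n*,

y_{n,i} = x_{n,i} + Σ_{j≠i} m_{ij} · x_{n,j},

is the compound's reporter height x (proportional to concentration) plus
the tails of the other compounds' signals. The coefficients m_{ij} are read
from a spectral library with one calibration spectrum per compound, each
normalized so its reporter height is 1 and reduced to its heights at the k
target positions; organized column-wise this yields the k × k interference
matrix **m** with unit diagonal and elements in [0, 1]. Quantification is
the direct dense solve of y = m·x, followed by c_i = x_i ·
response_factor_i (μM per unit normalized reporter height, a library
input) for metabolites; non-metabolite compounds (EDTA species, internal
standard) are carried in the solve but never interpreted quantitatively.

Two modes differ only in where **m** comes from:

* **constant** — one matrix built at the nominal target positions, reused
  for the whole dataset;
* **improved** — compounds declared *variable* are located in every
  spectrum; their calibration spectra are re-synthesized as sums of
  Lorentzians, `h·(w/2)² / ((δ−δ₀)² + (w/2)²)`, at the observed positions
  and FWHMs (relative heights between a compound's signals stay fixed at
  their library values so reporter normalization remains well defined),
  and both the compound's matrix **column** and its target-position
  **row** are rebuilt; every other element is copied from the constant
  matrix unchanged. The row must move with the column because the
  optimized target position changes where every column is sampled; this
  was a genuinely open design point and the package settles it as
  row + column.

## Per-spectrum characterization of variable compounds

Measuring a drifting signal's position and width directly on the mixture
spectrum is biased by whatever lies underneath it. The adaptive mode
therefore characterizes on an **interference-subtracted residual**:

1. Bootstrap: solve the spectrum once with the constant matrix.
2. For each variable compound, subtract every *other* compound's
   normalized calibration spectrum scaled by its current reporter
   estimate (negative estimates clamp to zero), and additionally the
   compound's *own other* signals from the current model, so each signal
   is fitted essentially alone.
3. Pick each signal in a ±15-bin window (guided by the library
   positions), fit position and FWHM, adapt the matrix, re-extract y,
   re-solve.
4. Repeat from step 2 with the improved estimates until x changes by less
   than 10⁻⁹ relative (cap 25 passes; clean spectra converge in 2, the
   worst drift-onto-target geometries in ~10).

Target heights y are always read from the experimental spectrum, never
from a residual: at the *observed apex bin* for variable compounds (where
the matrix row is re-sampled) and at the *nominal target bin* for
constant-variability compounds (whose matrix row never moves). Reading a
constant target at a detected apex instead would introduce a first-order
mismatch whenever a strong interferer tail pulls the local maximum off the
nominal bin, because the model would still subtract the tail at the
nominal position; sampling y where the row is sampled keeps the linear
model self-consistent. The detected apex is still recorded for every
target — it feeds the positional-deviation indicator and the found flag —
and an undetected target falls back to the intensity at its nominal bin.

## Line-shape fitting

Two width estimators coexist:

* `estimate_fwhm` — the classical outward half-height scan with linear
  interpolation between bracketing bins; shape-agnostic (exact for
  triangular peaks), one-sided widths are doubled and flagged when a
  shoulder hides a crossing. Accurate to ~2% for Lorentzians on this grid.
* `lorentzian_fit` — the default inside peak picking: for a Lorentzian,
  1/intensity is exactly quadratic in position, so a weighted parabola fit
  through the bins around the apex (collected outward while the intensity
  decays, within a noise allowance, down to 30% of the apex) returns FWHM
  *and* sub-bin center to machine precision for an isolated noiseless
  line, and to a few percent at SNR 50. Rows are weighted by intensity²,
  the minimum-variance weighting for 1/y under additive noise. If the fit
  is not peak-like (non-positive curvature or minimum, or a center more
  than one bin off), the half-height scan takes over.

The fitted sub-bin center is used for Lorentzian re-synthesis; all matrix
*sampling* stays on the bin grid (rows are sampled at bin centers, the
optimized target position is the apex bin). Without the sub-bin center the
re-synthesized tail can be wrong by several percent of itself at a
ten-bin distance, which matters when the interferer is 25–100× taller
than the metabolite under it.

## Quality indicators

* **occurrence** — fraction of spectra with x > 3 × noise (strict
  inequality). Noise is the SD of a signal-free region after removing its
  linear trend (default region δ 10.0–11.0 ppm, ≥ 32 bins; the multiplier
  and region are configurable). The detection limit applies to the
  reporter x, not the raw target y.
* **positional deviation** — smallest integer d such that ≥ 95% of
  |position − median| ≤ d bins, the median being the lower median so bin
  counts stay integral; a warning is issued below 20 spectra.
* **MAD** — per-spectrum |position − median position| in bins.
* **degree of interference** — Δ = (y − x)/y is split exactly into the
  part from metabolite columns and the part from non-metabolite columns
  (the two parts sum to Δ up to the solve residual, ~10⁻¹⁵ in practice);
  F_q is the fraction of spectra with Δ > q, reported at q = 0.05 and
  0.50, over spectra where Δ is defined (y > 0; undefined spectra are
  counted and reported). Report categories: occurrence ≥ 90% / ≥ 5%,
  deviation ≤ 1 bin, and the interference traffic light (red F₀.₅₀ >
  0.50; yellow F₀.₅₀ ≤ 0.50 and F₀.₀₅ > 0; green F₀.₀₅ = 0).
* **mean comparison** — per-compound (μ_a − μ_b)/μ_b between two runs.

## Numerical choices

* Axis stored ascending in ppm; readers flip descending files. Bin
  indices 0-based; nearest-bin rounding is half-away-from-the-lower-index.
* Peak candidates must be strictly greater than both nearest *differing*
  neighbours; plateaus resolve to their lowest bin. Ties: highest peak,
  then nearest the nominal position, then lower ppm.
* Negative x values are preserved and flagged through the detection limit
  rather than clipped — the solve then remains literally the linear model;
  a nonnegative-least-squares variant sits behind `nonnegative=True` for
  robustness studies.
* Condition-number cap 10⁸ on the solve (configurable); above it the run
  aborts naming the most collinear compound pair. A residual check
  (‖m·x − y‖∞ ≤ 10⁻⁹·max(1, ‖y‖∞)) guards the solution.
* Negative calibration intensities clamp to 0 before vector extraction.
* Every target position must coincide with its compound's reporter
  position on the grid, which makes the matrix diagonal exactly 1.

## The simulator

`edta_plasma_preset` emulates the features that make EDTA-plasma spectra a
hard test: 10 named metabolites (approximate literature shifts, one
representative singlet each, plasma-scale concentrations drawn
log-normally with CVs of 0.2–0.35), a free-EDTA-like variable species
(singlets at δ 3.62/3.23, planted apex intensity ~25–100× the interfered
metabolites' reporters, per-signal position drift uniform ±10 bins, FWHM
uniform 1.0–2.5 Hz around the library's 1.5 Hz), stable Ca/Mg-complex-like
species (δ 3.13/2.55 and 2.69/3.21), a fixed TSP-like internal standard at
δ 0.0, metabolite jitter Gaussian with SD 0.3 bins (95% within ±0.6 bins,
i.e. the ≤1-bin scale typical of plasma metabolites), and optional i.i.d.
Gaussian bin noise. The axis is −0.2 to 4.5 ppm at 0.0002 ppm/bin with a
reserved signal-free segment (δ 4.30–4.48) for noise estimation.
`n_metabolites=54` with the internal standard excluded gives the
full-scale 57-target geometry used for throughput profiling (~55 s for
772 spectra on one CPU, ~80 ms per spectrum, dominated by the per-spectrum
characterization passes).

A single Generator keyed by the seed drives all draws, spectrum-major,
compound-minor, with a fixed per-compound draw count, so a seed pins the
dataset bit for bit. Planted reporter heights are defined as the profile
height at the grid-snapped realized reporter position — the same
convention the quantifier normalizes against — so clean, drift-free data
are recovered to ~10⁻¹² relative, limited only by float arithmetic.

What the simulator does **not** emulate, and passing tests therefore do
not demonstrate: multiplet J-structure (every signal is a singlet),
correlated/rolling baselines (noise is white), macromolecule background,
pH-dependent shift *correlations* between compounds (drifts are drawn
independently per signal), compounds absent from the model, and any
imperfection in upstream phasing, shimming or binning — spectra are
assumed to arrive baseline-corrected and binned, as the quantifier itself
assumes.

## Known limitations

* Interference from compounds not in the library is silently absorbed
  into x: the model can only subtract what it knows.
* Constant-variability compounds are subtracted at their nominal
  positions during residual characterization; sub-bin metabolite jitter
  therefore leaves a small dipole-shaped leftover under the variable
  compound's signals. Under the preset's conditions the induced
  dataset-mean concentration bias stays below ~0.1%, but heavier jitter
  would widen it.
* The iterative refinement assumes the drifting compound dominates its
  own signal region; an interferer *weaker* than what it overlaps would
  converge slowly or fall back to its library geometry.
* Concentrations refer to the NMR sample; dilution back-calculation to
  the original specimen is out of scope, as are absolute-calibration
  schemes and 2D-based quantification.
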