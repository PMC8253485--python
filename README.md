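# aquanmr

Automated targeted quantification of metabolites in binned 1D ¹H NMR
spectra, built for the situation where some signals drift between spectra.

## The problem

Targeted NMR metabolomics quantifies each compound from **one preselected
target signal**. In a crowded biofluid spectrum that signal height *y* is
not pure: it is the compound's own **reporter** contribution *x* (which is
proportional to concentration) plus interference from the tails of
neighbouring signals. With a spectral library containing one calibration
spectrum per compound — each normalized so its reporter height is 1 — the
interferences of all *k* targeted compounds are captured by a *k* × *k*
matrix **m** (column *j* = compound *j*'s normalized heights at all *k*
target positions, diagonal = 1), and the reporter heights of spectrum *n*
come from one linear solve:

```
y̅ₙ = m̿ · x̅ₙ           (constant matrix, one per dataset)
```

That works while every signal sits still. It fails for compounds such as
**free EDTA** in plasma collected with EDTA as the anticoagulant: its two
intense singlets (δ ≈ 3.62 and 3.23) are pH-sensitive, drifting by up to
~10 bins (0.002 ppm) and changing line width between spectra, right on top
of metabolite targets such as carnitine and acetylcarnitine. The adaptive
mode therefore detects each variable compound's signals in every spectrum
(apex position, height, FWHM), re-synthesizes its calibration spectrum from
Lorentzian line shapes with the observed positions and widths, and rebuilds
that compound's portion of the matrix before solving:

```
y̅ₙ = m̿ₙ · x̅ₙ          (per-spectrum matrix, variable portion rebuilt)
```

Concentrations follow as `c = x · response_factor` (μM per unit normalized
reporter height); the relative interference `Δ = (y − x)/y` and the quality
indicators *occurrence* (fraction of spectra with x > 3 × noise),
*positional deviation* (±bins covering 95% of the median-centered target
positions) and *degree of interference* `F_q` (fraction of spectra with
Δ > q, split into metabolite and non-metabolite sources) tell you which
compounds can be trusted.

The package ships a synthetic-spectrum generator with known ground truth
(EDTA-plasma-like preset: stable metabolite singlets with sub-bin jitter, a
high-intensity drifting interferer, stable complex signals, an internal
standard and optional Gaussian noise), so every claim above is testable.

## Worked example

Fifty simulated EDTA-plasma-like spectra, quantified with and without the
per-spectrum matrix adaptation:

```python
from aquanmr import quantify_dataset, compare_means, qc_report
from aquanmr.simulate import edta_plasma_preset, simulate_dataset

cfg = edta_plasma_preset(50, seed=7)
spectra, truth = simulate_dataset(cfg)
kw = dict(noise_region=cfg.noise_region)
constant = quantify_dataset(spectra, cfg.library, cfg.make_targets(), mode="constant", **kw)
improved = quantify_dataset(spectra, cfg.library, cfg.make_targets(), mode="improved", **kw)

dev = compare_means(constant, improved).dropna()
```

Printing `dev` (the per-metabolite relative deviation of mean
concentrations, (μ_constant − μ_improved)/μ_improved) gives:

```
  acetylcarnitine     +371.2%
  carnitine           +178.6%
  ornithine            +12.7%
  dimethyl_sulfone      +0.4%
  creatinine            +0.1%
  glucose               +0.0%
  ...
```

Ignoring the interferer's drift overestimates exactly the metabolites whose
targets sit in its tail — by a factor of up to ~4.7 for acetylcarnitine —
and leaves everything else untouched. The quality report flags the same
compounds (`qc_report(improved)`):

```
                 occurrence  positional_deviation_bins  F050_nonmet interference_nonmet
carnitine               1.0                          0         0.94                 red
acetylcarnitine         1.0                          0         0.98                 red
ornithine               1.0                          1         0.02              yellow
glucose                 1.0                          1         0.00               green
```

Against the simulator's ground truth, the adaptive mode keeps every
metabolite's dataset-mean concentration within 0.1% under these conditions,
while the constant matrix is off by +13% to +256% for the overlapped ones.

## Command line

```sh
aqua simulate --preset edta-plasma --n 50 --seed 7 --out data/
aqua quantify --library data/library.json --targets data/targets.tsv \
              --spectra data/spectra --mode improved \
              --noise-region 4.30:4.48 --out improved.csv
aqua qc --results improved.csv --out qc.csv
aqua compare constant.csv improved.csv
```

Spectra are plain text (two-column ppm,intensity, or a dense intensity
vector with a JSON sidecar header), the library is JSON (per-compound
Lorentzian signal lists or paths to binned calibration spectra), targets a
TSV table.

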