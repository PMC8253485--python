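"""Synthetic EDTA-plasma-like spectra with known ground truth.

Each simulated spectrum is a sum of the library compounds' normalized
Lorentzian profiles scaled by planted reporter heights, plus i.i.d.
Gaussian bin noise.  The preset emulates the features that make
EDTA-containing plasma a hard test system:

* stable metabolite singlets with sub-bin positional jitter (the ~1-bin
  scale typical of plasma metabolites),
* a high-intensity free-EDTA-like species whose two singlets drift
  independently by up to ~10 bins and vary in line width between spectra,
  overlapping several lower-intensity metabolite targets,
* stable Ca/Mg-EDTA-like complex signals, and
* a fixed internal-standard (TSP-like) singlet.

Concentrations are drawn log-normally per compound (median in uM and CV);
the planted reporter height is ``x = conc / response_factor``, defined as
the profile height at the (grid-snapped) realized reporter position so that
a noiseless, drift-free dataset is recovered exactly by the quantifier.

Randomness comes from one ``numpy`` Generator keyed by the seed, consumed
spectrum-major, compound-minor: per compound one absence uniform and one
concentration normal, then per signal one normal (constant jitter) and two
uniforms (variable shift, variable FWHM) — always drawn, used as
applicable — then the noise vector.  Same seed, same dataset, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .library import (
    CompoundEntry,
    LorentzianSignal,
    default_targets,
    lorentzian_heights,
    save_library,
)
from .spectral_data import (
    BinnedSpectrum,
    TargetSignal,
    bin_to_ppm,
    ppm_to_bin,
    write_binned_spectrum,
    write_targets,
)

__all__ = ["SimulationConfig", "simulate_dataset", "edta_plasma_preset", "write_dataset"]

#: The binning of the reference acquisition setup: 0.0002 ppm/bin at 600 MHz.
DEFAULT_BIN_WIDTH = 0.0002
DEFAULT_FREQ_MHZ = 600.0


@dataclass
class SimulationConfig:
    """Study conditions for a simulated dataset (all fields explicit)."""

    library: list[CompoundEntry]
    conc_median_uM: dict[str, float]
    conc_cv: dict[str, float]
    n_spectra: int
    seed: int
    ppm_start: float = -0.2
    n_bins: int = 23501  # -0.2 .. 4.5 ppm at 0.0002 ppm/bin
    bin_width: float = DEFAULT_BIN_WIDTH
    spectrometer_freq: float = DEFAULT_FREQ_MHZ
    jitter_sd_bins: float = 0.3
    jitter_override_bins: dict[str, float] = field(default_factory=dict)
    shift_max_bins: float = 10.0
    fwhm_range_hz: tuple[float, float] = (1.0, 2.5)
    noise_sd: float = 0.0
    absent_probability: dict[str, float] = field(default_factory=dict)
    noise_region: tuple[float, float] = (4.30, 4.48)

    def __post_init__(self) -> None:
        if self.n_spectra < 1:
            raise ConfigError("n_spectra must be >= 1")
        if self.jitter_sd_bins < 0 or self.noise_sd < 0 or self.shift_max_bins < 0:
            raise ConfigError("jitter, shift and noise scales must be >= 0")
        if self.fwhm_range_hz[0] <= 0 or self.fwhm_range_hz[1] < self.fwhm_range_hz[0]:
            raise ConfigError("fwhm_range_hz must be a positive, ordered range")
        missing = [
            e.compound_id for e in self.library if e.compound_id not in self.conc_median_uM
        ]
        if missing:
            raise ConfigError(f"no concentration distribution for: {missing}")

    def make_axis(self) -> BinnedSpectrum:
        return BinnedSpectrum(
            ppm_start=self.ppm_start,
            bin_width=self.bin_width,
            intensities=np.zeros(self.n_bins),
            spectrometer_freq=self.spectrometer_freq,
            id="axis",
        )

    def make_targets(self) -> list[TargetSignal]:
        return default_targets(self.library, bin_width=self.bin_width)


def _lognormal(rng_z: float, median: float, cv: float) -> float:
    if cv <= 0:
        return median
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return median * float(np.exp(sigma * rng_z))


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[BinnedSpectrum], pd.DataFrame]:
    """Generate spectra and the ground-truth table.

    The ground truth lists, per (spectrum, compound): planted reporter
    height ``x_true``, concentration, reporter shift (bins, signed) and
    realized reporter FWHM (Hz).
    """
    axis = config.make_axis()
    ppm_axis = axis.ppm_axis
    rng = np.random.default_rng(config.seed)
    spectra: list[BinnedSpectrum] = []
    gt_rows = []
    for n in range(config.n_spectra):
        intens = np.zeros(config.n_bins)
        sid = f"sim_{n:04d}"
        for entry in config.library:
            if entry.signals is None:
                raise ConfigError(
                    f"{entry.compound_id}: simulation needs Lorentzian signal lists"
                )
            u_absent = rng.random()
            z_conc = rng.standard_normal()
            realized: list[LorentzianSignal] = []
            for sig in entry.signals:
                z_jit = rng.standard_normal()
                u_shift, u_fwhm = rng.random(2)
                if entry.variability == "variable":
                    shift_ppm = (2 * u_shift - 1) * config.shift_max_bins * config.bin_width
                    lo, hi = config.fwhm_range_hz
                    fwhm = lo + u_fwhm * (hi - lo)
                else:
                    sd = config.jitter_override_bins.get(
                        entry.compound_id, config.jitter_sd_bins
                    )
                    shift_ppm = z_jit * sd * config.bin_width
                    fwhm = sig.fwhm_hz
                realized.append(
                    LorentzianSignal(sig.center_ppm + shift_ppm, fwhm, sig.height)
                )
            absent = u_absent < config.absent_probability.get(entry.compound_id, 0.0)
            conc = (
                0.0
                if absent
                else _lognormal(
                    z_conc,
                    config.conc_median_uM[entry.compound_id],
                    config.conc_cv.get(entry.compound_id, 0.0),
                )
            )
            rf = entry.response_factor if entry.response_factor is not None else 1.0
            x_true = conc / rf
            rep_idx = min(
                range(len(entry.signals)),
                key=lambda i: abs(entry.signals[i].center_ppm - entry.reporter_ppm),
            )
            rep_center = realized[rep_idx].center_ppm
            rep_grid_ppm = bin_to_ppm(axis, ppm_to_bin(axis, rep_center))
            apex = float(
                lorentzian_heights(rep_grid_ppm, realized, config.spectrometer_freq)
            )
            if x_true > 0:
                scale = x_true / apex
                intens += scale * np.asarray(
                    lorentzian_heights(ppm_axis, realized, config.spectrometer_freq)
                )
            gt_rows.append(
                {
                    "spectrum_id": sid,
                    "compound_id": entry.compound_id,
                    "compound_class": entry.compound_class,
                    "conc_true_uM": conc,
                    "x_true": x_true,
                    "reporter_shift_bins": (rep_center - entry.signals[rep_idx].center_ppm)
                    / config.bin_width,
                    "reporter_fwhm_hz": realized[rep_idx].fwhm_hz,
                    "absent": absent,
                }
            )
        if config.noise_sd > 0:
            intens += config.noise_sd * rng.standard_normal(config.n_bins)
        spectra.append(
            BinnedSpectrum(
                ppm_start=config.ppm_start,
                bin_width=config.bin_width,
                intensities=intens,
                spectrometer_freq=config.spectrometer_freq,
                id=sid,
            )
        )
    return spectra, pd.DataFrame(gt_rows)


# ---------------------------------------------------------------------------
# Preset

# Toy plasma library: approximate literature chemical shifts, modelled as one
# representative singlet per metabolite; response factors and concentration
# medians/CVs are plausible plasma-scale values.  Three EDTA-like species sit
# at the positions of the free acid and its Ca/Mg complexes; the free species
# is the positionally variable, high-intensity interferer.  Columns:
# (id, class, variability, signals[(ppm, fwhm_hz, rel_height)],
#  reporter_ppm, response_factor, conc_median_uM, conc_cv)
_PRESET_TABLE = [
    ("lactate", "metabolite", "constant", [(4.10, 1.4, 1.0)], 4.10, 40.0, 1200.0, 0.25),
    ("alanine", "metabolite", "constant", [(1.48, 1.3, 1.0)], 1.48, 55.0, 350.0, 0.25),
    ("glucose", "metabolite", "constant", [(3.40, 1.6, 1.0)], 3.40, 120.0, 4500.0, 0.20),
    ("creatinine", "metabolite", "constant", [(3.05, 1.4, 1.0)], 3.05, 60.0, 70.0, 0.25),
    ("citrate", "metabolite", "constant", [(2.54, 1.5, 1.0)], 2.54, 45.0, 110.0, 0.25),
    ("glutamine", "metabolite", "constant", [(2.46, 1.5, 1.0)], 2.46, 70.0, 500.0, 0.20),
    ("dimethyl_sulfone", "metabolite", "constant", [(3.142, 1.3, 1.0)], 3.142, 25.0, 20.0, 0.30),
    ("carnitine", "metabolite", "constant", [(3.226, 1.5, 1.0)], 3.226, 35.0, 40.0, 0.25),
    ("acetylcarnitine", "metabolite", "constant", [(3.614, 1.5, 1.0)], 3.614, 30.0, 8.0, 0.30),
    ("ornithine", "metabolite", "constant", [(3.634, 1.5, 1.0)], 3.634, 60.0, 60.0, 0.25),
    (
        "edta_free",
        "nonmetabolite",
        "variable",
        [(3.62, 1.5, 1.0), (3.23, 1.5, 0.95)],
        3.62,
        None,
        30.0,
        0.35,
    ),
    (
        "edta_ca",
        "nonmetabolite",
        "constant",
        [(3.13, 1.4, 1.0), (2.55, 1.4, 0.9)],
        3.13,
        None,
        20.0,
        0.25,
    ),
    (
        "edta_mg",
        "nonmetabolite",
        "constant",
        [(2.69, 1.4, 1.0), (3.21, 1.4, 0.9)],
        2.69,
        None,
        8.0,
        0.25,
    ),
]
_TSP_ROW = ("tsp", "nonmetabolite", "constant", [(0.0, 1.1, 1.0)], 0.0, None, 5.0, 0.0)

#: Free-EDTA-like signal positions of the preset (for overlap bookkeeping).
PRESET_VARIABLE_POSITIONS = (3.62, 3.23)


def _extra_metabolites(n: int) -> list[tuple]:
    """Deterministic filler metabolites for scaled-up (e.g. 54-compound) runs.

    Spread over 0.55-4.45 ppm on positions clear (>= 0.02 ppm) of the preset
    signals, with cycling line widths, response factors and concentrations.
    """
    taken = [s[0] for row in _PRESET_TABLE + [_TSP_ROW] for s in row[3]]
    out = []
    ppm = 0.55
    i = 0
    while len(out) < n:
        if ppm > 4.2:  # keep clear of the axis end and the noise region
            raise ConfigError(f"cannot place {n} filler metabolites below 4.2 ppm")
        ppm_snapped = round(ppm / DEFAULT_BIN_WIDTH) * DEFAULT_BIN_WIDTH
        if all(abs(ppm_snapped - t) >= 0.02 for t in taken):
            fwhm = (1.2, 1.4, 1.6)[i % 3]
            rf = (30.0, 60.0, 90.0, 120.0)[i % 4]
            conc = (25.0, 80.0, 250.0, 700.0)[i % 4]
            out.append(
                (
                    f"met_{i + 11:02d}",
                    "metabolite",
                    "constant",
                    [(ppm_snapped, fwhm, 1.0)],
                    ppm_snapped,
                    rf,
                    conc,
                    0.25,
                )
            )
            taken.append(ppm_snapped)
            i += 1
        ppm += 0.065
    return out


def edta_plasma_preset(
    n_spectra: int,
    seed: int,
    *,
    noise_sd: float = 0.0,
    jitter_sd_bins: float = 0.3,
    shift_max_bins: float = 10.0,
    fwhm_range_hz: tuple[float, float] = (1.0, 2.5),
    variable_enabled: bool = True,
    include_tsp: bool = True,
    n_metabolites: int = 10,
    absent_probability: dict[str, float] | None = None,
) -> SimulationConfig:
    """Ready-made EDTA-plasma-like study conditions.

    The default library has 10 metabolites, three EDTA-like species (the
    free species variable, the complexes constant) and a TSP-like internal
    standard.  ``n_metabolites=54`` with ``include_tsp=False`` gives the
    full-scale 57-target geometry.  ``variable_enabled=False`` declares the
    free species constant (no drift is simulated and no adaptation happens,
    so improved and constant modes coincide).
    """
    rows = list(_PRESET_TABLE)
    if n_metabolites < 10:
        raise ConfigError("preset needs at least the 10 named metabolites")
    if n_metabolites > 10:
        extra = _extra_metabolites(n_metabolites - 10)
        rows = rows[:10] + extra + rows[10:]
    if include_tsp:
        rows.append(_TSP_ROW)
    library = []
    conc_median, conc_cv = {}, {}
    for cid, cls, var, signals, rep, rf, med, cv in rows:
        if not variable_enabled and var == "variable":
            var = "constant"
        library.append(
            CompoundEntry(
                compound_id=cid,
                reporter_ppm=rep,
                response_factor=rf,
                signals=[LorentzianSignal(*s) for s in signals],
                variability=var,
                compound_class=cls,
            )
        )
        conc_median[cid] = med
        conc_cv[cid] = cv
    return SimulationConfig(
        library=library,
        conc_median_uM=conc_median,
        conc_cv=conc_cv,
        n_spectra=n_spectra,
        seed=seed,
        jitter_sd_bins=jitter_sd_bins,
        jitter_override_bins={"tsp": 0.0},
        shift_max_bins=shift_max_bins,
        fwhm_range_hz=fwhm_range_hz,
        noise_sd=noise_sd,
        absent_probability=dict(absent_probability or {}),
    )


def write_dataset(
    config: SimulationConfig,
    out_dir: str | Path,
    dialect: str = "dense",
) -> tuple[list[BinnedSpectrum], pd.DataFrame]:
    """Simulate and write spectra, ground truth, library and target table."""
    out = Path(out_dir)
    spectra_dir = out / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    spectra, gt = simulate_dataset(config)
    ext = ".csv" if dialect == "xy" else ".txt"
    for spec in spectra:
        write_binned_spectrum(spec, spectra_dir / f"{spec.id}{ext}", dialect=dialect)
    gt.to_csv(out / "ground_truth.csv", index=False)
    save_library(config.library, out / "library.json")
    write_targets(config.make_targets(), out / "targets.tsv")
    return spectra, gt
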