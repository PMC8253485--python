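"""Compound spectral library and the interference matrix.

Quantification rests on a k x k matrix ``m`` whose column j holds compound
j's calibration spectrum, normalized so its reporter signal height is 1 and
sampled at the k target positions; the diagonal is exactly 1 and all
elements lie in [0, 1] for a well-formed library.  Two constructions are
provided:

* :func:`build_constant_matrix` — one matrix from nominal target positions,
  reused for every spectrum (appropriate when all signals are positionally
  stable).
* :func:`adapt_matrix` — a per-spectrum matrix in which the column and the
  target-position row of each *variable* compound are rebuilt from that
  spectrum's observed signal positions and line widths (Lorentzian
  re-synthesis with library-fixed relative heights); every other element is
  copied unchanged from the constant matrix.

Calibration spectra may be given as Lorentzian signal lists (preferred:
exact re-synthesis, no grid aliasing) or as binned spectra.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LibraryError, MatrixError, RangeError
from .peak_picking import SignalObservation
from .spectral_data import (
    BinnedSpectrum,
    TargetSignal,
    bin_to_ppm,
    hz_to_ppm,
    ppm_to_bin,
)

__all__ = [
    "LorentzianSignal",
    "CompoundEntry",
    "InterferenceMatrix",
    "lorentzian_heights",
    "synthesize_spectrum",
    "normalize_calibration",
    "calibration_vector",
    "build_constant_matrix",
    "adapt_matrix",
    "load_library",
    "save_library",
    "default_targets",
]

#: Above this condition number the matrix is treated as numerically singular.
SINGULAR_COND = 1e12


@dataclass(frozen=True)
class LorentzianSignal:
    """One Lorentzian line: apex position (ppm), FWHM (Hz), apex height."""

    center_ppm: float
    fwhm_hz: float
    height: float

    def __post_init__(self) -> None:
        if self.fwhm_hz <= 0:
            raise ValueError("fwhm_hz must be positive")
        if self.height < 0:
            raise ValueError("height must be >= 0")


@dataclass
class CompoundEntry:
    """One library compound.

    Exactly one of ``signals`` (Lorentzian list) or ``spectrum`` (binned
    calibration spectrum) must be provided.  ``response_factor`` converts a
    unit normalized reporter height to a concentration in uM; it is required
    for metabolites and optional for nonmetabolites (whose reporter heights
    are not interpreted quantitatively).
    """

    compound_id: str
    reporter_ppm: float
    response_factor: float | None = None
    signals: list[LorentzianSignal] | None = None
    spectrum: BinnedSpectrum | None = None
    variability: str = "constant"
    compound_class: str = "metabolite"

    def __post_init__(self) -> None:
        if (self.signals is None) == (self.spectrum is None):
            raise LibraryError(
                f"{self.compound_id}: provide exactly one of signals or spectrum"
            )
        if self.variability not in ("constant", "variable"):
            raise LibraryError(f"{self.compound_id}: bad variability {self.variability!r}")
        if self.compound_class not in ("metabolite", "nonmetabolite"):
            raise LibraryError(f"{self.compound_id}: bad class {self.compound_class!r}")
        if self.compound_class == "metabolite":
            if self.response_factor is None or self.response_factor <= 0:
                raise LibraryError(
                    f"{self.compound_id}: metabolites need response_factor > 0"
                )

    @property
    def reporter_signal(self) -> LorentzianSignal:
        """The Lorentzian signal closest to the reporter position."""
        if self.signals is None:
            raise LibraryError(f"{self.compound_id}: no Lorentzian signal list")
        return min(self.signals, key=lambda s: abs(s.center_ppm - self.reporter_ppm))


def lorentzian_heights(
    ppm: np.ndarray | float,
    signals: list[LorentzianSignal],
    spectrometer_freq: float,
) -> np.ndarray | float:
    """Sum of Lorentzian lines evaluated at ``ppm``:
    ``sum_s h_s * (w_s/2)^2 / ((ppm - c_s)^2 + (w_s/2)^2)`` with ``w_s`` in ppm.
    """
    ppm_arr = np.asarray(ppm, dtype=float)
    out = np.zeros_like(ppm_arr)
    for s in signals:
        hw = hz_to_ppm(s.fwhm_hz, spectrometer_freq) / 2.0
        out = out + s.height * hw * hw / ((ppm_arr - s.center_ppm) ** 2 + hw * hw)
    return out if out.ndim else float(out)


def synthesize_spectrum(
    signals: list[LorentzianSignal], axis: BinnedSpectrum
) -> BinnedSpectrum:
    """Evaluate a Lorentzian signal list at the bin centers of ``axis``."""
    for s in signals:
        if not (axis.ppm_start <= s.center_ppm <= axis.ppm_end):
            raise RangeError(
                f"signal center {s.center_ppm} outside axis "
                f"[{axis.ppm_start}, {axis.ppm_end}]"
            )
    vals = (
        lorentzian_heights(axis.ppm_axis, signals, axis.spectrometer_freq)
        if signals
        else np.zeros(axis.n_bins)
    )
    return BinnedSpectrum(
        ppm_start=axis.ppm_start,
        bin_width=axis.bin_width,
        intensities=np.asarray(vals, dtype=float),
        spectrometer_freq=axis.spectrometer_freq,
        id="synthetic",
    )


def normalize_calibration(
    entry: CompoundEntry, axis: BinnedSpectrum
) -> tuple[BinnedSpectrum, float]:
    """Scale a compound's calibration spectrum so its reporter height is 1.

    Lorentzian entries are synthesized on ``axis`` first.  Returns the
    normalized spectrum and the scale (the original reporter height, read at
    the nearest bin to ``reporter_ppm``).
    """
    spec = (
        synthesize_spectrum(entry.signals, axis)
        if entry.signals is not None
        else entry.spectrum.copy()
    )
    rep_bin = ppm_to_bin(spec, entry.reporter_ppm)
    scale = float(spec.intensities[rep_bin])
    if scale <= 0:
        raise LibraryError(
            f"{entry.compound_id}: zero/negative reporter height at {entry.reporter_ppm} ppm"
        )
    spec.intensities = spec.intensities / scale
    spec.id = f"{entry.compound_id}:normalized"
    return spec, scale


def calibration_vector(
    normalized: BinnedSpectrum, target_positions: np.ndarray | list[float]
) -> np.ndarray:
    """Normalized heights at the target positions (nearest bin), clamped >= 0."""
    bins = [ppm_to_bin(normalized, p) for p in np.asarray(target_positions, dtype=float)]
    return np.maximum(normalized.intensities[bins], 0.0)


@dataclass
class InterferenceMatrix:
    """k x k matrix of normalized calibration heights at the target positions.

    ``values[i, j]`` is compound j's normalized height at target position i;
    the diagonal is 1.  ``target_ppm`` holds the (grid-snapped) positions the
    rows were sampled at; for an adapted matrix these are the per-spectrum
    optimized positions of variable compounds.  The normalized calibration
    spectra are retained privately so adaptation can resample constant
    compounds without re-synthesis.
    """

    values: np.ndarray
    compound_ids: tuple[str, ...]
    target_ppm: np.ndarray
    normalized_calibrations: dict[str, BinnedSpectrum] = field(repr=False, default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.compound_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.compound_ids)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def _check_alignment(
    library: list[CompoundEntry], targets: list[TargetSignal]
) -> None:
    if len(library) != len(targets):
        raise LibraryError(
            f"library has {len(library)} compounds but {len(targets)} targets"
        )
    for e, t in zip(library, targets):
        if e.compound_id != t.compound_id:
            raise LibraryError(
                f"library/target order mismatch: {e.compound_id} vs {t.compound_id}"
            )


def build_constant_matrix(
    library: list[CompoundEntry],
    targets: list[TargetSignal],
    axis: BinnedSpectrum,
) -> InterferenceMatrix:
    """Constant interference matrix at the nominal target positions.

    Each target must coincide (to the grid) with its compound's reporter
    position, so the diagonal is exactly 1 by normalization.
    """
    _check_alignment(library, targets)
    k = len(library)
    target_bins = [ppm_to_bin(axis, t.nominal_ppm) for t in targets]
    if len(set(target_bins)) < k:
        warnings.warn(
            "duplicate target positions produce identical matrix rows", stacklevel=2
        )
    t_ppm = np.array([bin_to_ppm(axis, b) for b in target_bins])
    values = np.empty((k, k))
    normalized: dict[str, BinnedSpectrum] = {}
    for j, entry in enumerate(library):
        if ppm_to_bin(axis, entry.reporter_ppm) != target_bins[j]:
            raise LibraryError(
                f"{entry.compound_id}: target position {targets[j].nominal_ppm} does "
                f"not coincide with reporter position {entry.reporter_ppm} on the grid"
            )
        norm, _ = normalize_calibration(entry, axis)
        normalized[entry.compound_id] = norm
        values[:, j] = calibration_vector(norm, t_ppm)
    cond = np.linalg.cond(values)
    if not np.isfinite(cond) or cond > SINGULAR_COND:
        raise MatrixError(f"interference matrix numerically singular (cond {cond:.3g})")
    return InterferenceMatrix(
        values=values,
        compound_ids=tuple(e.compound_id for e in library),
        target_ppm=t_ppm,
        normalized_calibrations=normalized,
    )


def _resynthesized_signals(
    entry: CompoundEntry, observations: list[SignalObservation]
) -> list[LorentzianSignal]:
    """Library signals with observed positions/FWHMs and library relative heights.

    Observations are matched to library signals by list order (one guide per
    signal).  A signal that was not found keeps its library position and
    width.  Relative heights always come from the library so that reporter
    normalization stays well-defined.
    """
    if entry.signals is None:
        raise LibraryError(
            f"{entry.compound_id}: variable compounds need a Lorentzian signal list"
        )
    if len(observations) != len(entry.signals):
        raise LibraryError(
            f"{entry.compound_id}: {len(observations)} observations for "
            f"{len(entry.signals)} library signals"
        )
    out = []
    for sig, obs in zip(entry.signals, observations):
        if obs.found and obs.fwhm_hz is not None:
            center = obs.apex_ppm_refined if obs.apex_ppm_refined is not None else obs.apex_ppm
            out.append(LorentzianSignal(center, obs.fwhm_hz, sig.height))
        else:
            out.append(sig)
    return out


def adapt_matrix(
    constant_m: InterferenceMatrix,
    observations: dict[str, list[SignalObservation]],
    library: list[CompoundEntry],
    targets: list[TargetSignal],
    axis: BinnedSpectrum,
) -> tuple[InterferenceMatrix, list[str]]:
    """Per-spectrum matrix: rebuild each variable compound's column and
    target-position row from its observed signals; copy everything else.

    Returns the adapted matrix and the ids of variable compounds whose
    reporter signal was not found (these fall back to their constant column
    and row, and the spectrum should be flagged).
    """
    _check_alignment(library, targets)
    ids = constant_m.compound_ids
    index = {cid: j for j, cid in enumerate(ids)}
    variable = [e for e in library if e.variability == "variable"]
    missing = [e.compound_id for e in variable if e.compound_id not in observations]
    if missing:
        raise LibraryError(f"no observations for variable compounds: {missing}")

    values = constant_m.values.copy()
    t_ppm = constant_m.target_ppm.copy()
    normalized = dict(constant_m.normalized_calibrations)
    fallback: list[str] = []
    adapted: list[CompoundEntry] = []

    # pass 1: optimized target positions and re-synthesized calibrations
    for entry in variable:
        obs = observations[entry.compound_id]
        rep_idx = min(
            range(len(entry.signals)),
            key=lambda i: abs(entry.signals[i].center_ppm - entry.reporter_ppm),
        )
        rep_obs = obs[rep_idx]
        if not rep_obs.found:
            fallback.append(entry.compound_id)
            continue
        j = index[entry.compound_id]
        new_pos = bin_to_ppm(axis, ppm_to_bin(axis, rep_obs.apex_ppm))
        t_ppm[j] = new_pos
        new_entry = CompoundEntry(
            compound_id=entry.compound_id,
            reporter_ppm=new_pos,
            response_factor=entry.response_factor,
            signals=_resynthesized_signals(entry, obs),
            variability=entry.variability,
            compound_class=entry.compound_class,
        )
        norm, _ = normalize_calibration(new_entry, axis)
        normalized[entry.compound_id] = norm
        adapted.append(new_entry)

    # pass 2: variable columns at the current target positions
    for entry in adapted:
        j = index[entry.compound_id]
        values[:, j] = calibration_vector(normalized[entry.compound_id], t_ppm)
    # pass 3: variable compounds' rows, all columns, at the optimized positions
    for entry in adapted:
        i = index[entry.compound_id]
        for cid, j in index.items():
            values[i, j] = calibration_vector(normalized[cid], [t_ppm[i]])[0]

    cond = np.linalg.cond(values)
    if not np.isfinite(cond) or cond > SINGULAR_COND:
        raise MatrixError(f"adapted matrix numerically singular (cond {cond:.3g})")
    return (
        InterferenceMatrix(
            values=values,
            compound_ids=ids,
            target_ppm=t_ppm,
            normalized_calibrations=normalized,
        ),
        fallback,
    )


# ---------------------------------------------------------------------------
# Library file I/O and target derivation


def load_library(path: str | Path) -> list[CompoundEntry]:
    """Load a JSON library.

    Each record: ``{compound_id, class, variability, reporter_ppm,
    response_factor_uM_per_unit, signals: [{center_ppm, fwhm_hz, rel_height}]}``
    or ``spectrum_path`` (resolved relative to the JSON file) instead of
    ``signals``.
    """
    from .spectral_data import read_binned_spectrum

    path = Path(path)
    records = json.loads(path.read_text())
    entries = []
    for rec in records:
        signals = None
        spectrum = None
        if "signals" in rec and rec["signals"] is not None:
            signals = [
                LorentzianSignal(
                    center_ppm=float(s["center_ppm"]),
                    fwhm_hz=float(s["fwhm_hz"]),
                    height=float(s.get("rel_height", 1.0)),
                )
                for s in rec["signals"]
            ]
        elif "spectrum_path" in rec:
            spectrum = read_binned_spectrum(path.parent / rec["spectrum_path"])
        rf = rec.get("response_factor_uM_per_unit")
        entries.append(
            CompoundEntry(
                compound_id=str(rec["compound_id"]),
                reporter_ppm=float(rec["reporter_ppm"]),
                response_factor=float(rf) if rf is not None else None,
                signals=signals,
                spectrum=spectrum,
                variability=str(rec.get("variability", "constant")),
                compound_class=str(rec.get("class", "metabolite")),
            )
        )
    return entries


def save_library(library: list[CompoundEntry], path: str | Path) -> None:
    records = []
    for e in library:
        if e.signals is None:
            raise LibraryError(
                f"{e.compound_id}: only Lorentzian-list entries can be saved to JSON"
            )
        records.append(
            {
                "compound_id": e.compound_id,
                "class": e.compound_class,
                "variability": e.variability,
                "reporter_ppm": e.reporter_ppm,
                "response_factor_uM_per_unit": e.response_factor,
                "signals": [
                    {"center_ppm": s.center_ppm, "fwhm_hz": s.fwhm_hz, "rel_height": s.height}
                    for s in e.signals
                ],
            }
        )
    Path(path).write_text(json.dumps(records, indent=1))


def default_targets(
    library: list[CompoundEntry],
    bin_width: float = 0.0002,
    constant_window_bins: int = 1,
    variable_window_bins: int = 15,
) -> list[TargetSignal]:
    """One target per compound at its reporter position.

    Constant compounds get a narrow window (default +/-1 bin, the typical
    positional-deviation scale of plasma metabolites); variable compounds a
    wide one (default +/-15 bins, covering drifts of ~10 bins).
    """
    return [
        TargetSignal(
            compound_id=e.compound_id,
            nominal_ppm=e.reporter_ppm,
            window_ppm=(
                variable_window_bins if e.variability == "variable" else constant_window_bins
            )
            * bin_width,
            variability=e.variability,
        )
        for e in library
    ]
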