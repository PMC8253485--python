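"""Core quantification: target extraction, the linear solve, concentrations.

For spectrum ``n`` the target-signal vector ``y_n`` (one intensity per
targeted compound) relates to the reporter-signal vector ``x_n`` through the
interference matrix: ``y_n = m @ x_n`` (constant mode, one matrix for the
whole dataset) or ``y_n = m_n @ x_n`` (improved mode, the variable portion
of ``m_n`` rebuilt per spectrum from observed signal positions and line
widths).  The solve is a direct dense solve; reporter heights convert to
concentrations through each metabolite's response factor, the relative
interference is ``delta = (y - x)/y``, and detection is judged as
``x > detection_multiplier x noise``.

Target heights are read at the position the matrix row is sampled at:
the fixed nominal bin for constant-variability targets (whose row never
moves) and the observed apex for variable compounds (whose row is
re-sampled at that apex).  The detected apex of every target is recorded
regardless, feeding the positional-deviation quality indicator.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AquaError, LibraryError, MatrixError
from .library import (
    CompoundEntry,
    InterferenceMatrix,
    adapt_matrix,
    build_constant_matrix,
)
from .peak_picking import (
    DEFAULT_DETECTION_MULTIPLIER,
    DEFAULT_NOISE_REGION,
    SignalObservation,
    characterize_compound,
    estimate_noise,
    pick_target_signal,
)
from .quality import decompose_interference
from .spectral_data import BinnedSpectrum, TargetSignal, ppm_to_bin

__all__ = [
    "QuantRecord",
    "extract_targets",
    "solve_reporters",
    "relative_interference",
    "to_concentrations",
    "quantify_dataset",
    "records_to_frame",
]

logger = logging.getLogger("aquanmr.quantify")

#: Condition-number cap for the interference matrix; above it the solve aborts.
DEFAULT_COND_CAP = 1e8
#: Half-width (bins) of the guide windows used to characterize variable compounds.
VARIABLE_GUIDE_WINDOW_BINS = 15
#: Improved-mode refinement stops when x changes by less than this (relative).
REFINE_TOL = 1e-9


@dataclass
class QuantRecord:
    """Per-spectrum quantification result (arrays aligned with compound_ids)."""

    spectrum_id: str
    compound_ids: tuple[str, ...]
    y: np.ndarray
    position_ppm: np.ndarray
    position_bins: np.ndarray
    found: np.ndarray
    x: np.ndarray
    delta: np.ndarray
    delta_met: np.ndarray
    delta_nonmet: np.ndarray
    conc_uM: np.ndarray
    below_detection: np.ndarray
    mode: str
    noise_level: float
    compound_classes: tuple[str, ...]
    matrix_values: np.ndarray = field(repr=False, default=None)
    fallback_compounds: tuple[str, ...] = ()


def extract_targets(
    spectrum: BinnedSpectrum,
    targets: list[TargetSignal],
    noise: float = 0.0,
    variable_observations: dict[str, object] | None = None,
    detection_multiplier: float = DEFAULT_DETECTION_MULTIPLIER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Reduce a spectrum to its target vector.

    Returns ``(y, position_ppm, position_bins, found)``.  Constant targets:
    ``y`` is the intensity at the nominal target bin and the position is the
    detected apex within the narrow window (nominal if none found).  Variable
    targets: when a reporter observation is supplied (improved mode) its apex
    height and position are used; otherwise the target's own window is
    searched and the apex height taken, falling back to the nominal-bin
    intensity when nothing is found.
    """
    k = len(targets)
    y = np.empty(k)
    pos_ppm = np.empty(k)
    pos_bins = np.empty(k, dtype=int)
    found = np.zeros(k, dtype=bool)
    for i, t in enumerate(targets):
        nominal_bin = ppm_to_bin(spectrum, t.nominal_ppm)
        obs = None
        if variable_observations is not None and t.compound_id in variable_observations:
            obs = variable_observations[t.compound_id]
        else:
            obs = pick_target_signal(
                spectrum, t, noise=noise, detection_multiplier=detection_multiplier
            )
        found[i] = obs.found
        pos_ppm[i] = obs.apex_ppm
        pos_bins[i] = obs.apex_bin
        if t.variability == "variable" and obs.found:
            # read from THIS spectrum at the observed apex: the observation may
            # come from an interference-subtracted residual, but y is defined
            # on the experimental spectrum
            y[i] = float(spectrum.intensities[obs.apex_bin])
        else:
            y[i] = float(spectrum.intensities[nominal_bin])
    return y, pos_ppm, pos_bins, found


def _most_collinear_pair(m: InterferenceMatrix | np.ndarray) -> str:
    values = m.values if isinstance(m, InterferenceMatrix) else np.asarray(m)
    ids = (
        m.compound_ids
        if isinstance(m, InterferenceMatrix)
        else tuple(str(j) for j in range(values.shape[1]))
    )
    norms = np.linalg.norm(values, axis=0)
    norms[norms == 0] = 1.0
    unit = values / norms
    cos = np.abs(unit.T @ unit)
    np.fill_diagonal(cos, 0.0)
    i, j = np.unravel_index(np.argmax(cos), cos.shape)
    return f"{ids[i]} / {ids[j]} (|cos| {cos[i, j]:.4f})"


def solve_reporters(
    m: InterferenceMatrix | np.ndarray,
    y: np.ndarray,
    cond_cap: float = DEFAULT_COND_CAP,
    nonnegative: bool = False,
) -> np.ndarray:
    """Solve ``m @ x = y`` for the reporter heights by direct dense solve.

    Negative entries of ``x`` are preserved (the model is linear; they are
    flagged downstream via the detection limit).  ``nonnegative=True``
    switches to a nonnegative least-squares solve for robustness studies.
    Raises :class:`MatrixError` when the condition number exceeds
    ``cond_cap``, naming the most collinear compound pair.
    """
    values = m.values if isinstance(m, InterferenceMatrix) else np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise MatrixError(f"matrix must be square, got {values.shape}")
    if y.shape != (values.shape[0],):
        raise MatrixError(f"y length {y.shape} does not match k={values.shape[0]}")
    cond = np.linalg.cond(values)
    if not np.isfinite(cond) or cond > cond_cap:
        raise MatrixError(
            f"interference matrix too ill-conditioned (cond {cond:.3g} > {cond_cap:.3g}); "
            f"most collinear columns: {_most_collinear_pair(m)}"
        )
    if nonnegative:
        from scipy.optimize import nnls

        x, _ = nnls(values, y)
        return x
    x = np.linalg.solve(values, y)
    resid = np.max(np.abs(values @ x - y))
    if resid > 1e-9 * max(1.0, np.max(np.abs(y))):
        raise MatrixError(f"solve residual {resid:.3g} exceeds tolerance")
    return x


def relative_interference(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """``delta = (y - x)/y`` elementwise; NaN marks the undefined case y <= 0."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x must have the same length")
    out = np.full(y.shape, np.nan)
    ok = y > 0
    out[ok] = (y[ok] - x[ok]) / y[ok]
    return out


def to_concentrations(x: np.ndarray, library: list[CompoundEntry]) -> np.ndarray:
    """Metabolite concentrations (uM): ``conc = x * response_factor``.

    Nonmetabolite entries (e.g. EDTA species) are not interpreted
    quantitatively and come back as NaN.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(library),):
        raise ValueError("x length must match library")
    conc = np.full(x.shape, np.nan)
    for i, e in enumerate(library):
        if e.compound_class == "metabolite":
            if e.response_factor is None:
                raise LibraryError(f"{e.compound_id}: missing response factor")
            conc[i] = x[i] * e.response_factor
    return conc


def _variable_guides(entry: CompoundEntry, bin_width: float) -> list[TargetSignal]:
    window = VARIABLE_GUIDE_WINDOW_BINS * bin_width
    return [
        TargetSignal(
            compound_id=entry.compound_id,
            nominal_ppm=s.center_ppm,
            window_ppm=window,
            variability="variable",
        )
        for s in entry.signals
    ]


def _improved_solve(
    spec: BinnedSpectrum,
    library: list[CompoundEntry],
    targets: list[TargetSignal],
    constant_m: InterferenceMatrix,
    variable_entries: list[CompoundEntry],
    noise: float,
    detection_multiplier: float,
    cond_cap: float,
    nonnegative: bool,
    refine_passes: int,
):
    """Adapt-and-solve for one spectrum.

    Variable compounds are characterized on an interference-subtracted
    residual: the current reporter estimates scale every *other* compound's
    normalized calibration spectrum, the sum is subtracted, and the variable
    compound's signal positions and line widths are measured on what
    remains.  The first pass bootstraps from a constant-matrix solve; each
    refinement pass re-subtracts with the improved estimates, so errors in
    the cleaned spectrum shrink geometrically.  Target heights y are always
    read from the experimental spectrum (at the observed apex for variable
    compounds), never from the residual.
    """
    from .library import LorentzianSignal, lorentzian_heights

    index = {cid: j for j, cid in enumerate(constant_m.compound_ids)}
    # bootstrap: constant-matrix estimate of the reporter heights
    y0, _, _, _ = extract_targets(
        spec, targets, noise=noise, detection_multiplier=detection_multiplier
    )
    x_est = solve_reporters(constant_m, y0, cond_cap=cond_cap, nonnegative=nonnegative)
    m_n = constant_m
    fallback: tuple[str, ...] = ()
    var_obs_full: dict[str, list] = {}
    reporter_obs: dict[str, SignalObservation] = {}

    def normalized_signals(entry: CompoundEntry, signals) -> list[LorentzianSignal]:
        """Signal list scaled so the compound's reporter height is 1."""
        rep_bin = ppm_to_bin(spec, entry.reporter_ppm)
        rep_ppm = spec.ppm_start + rep_bin * spec.bin_width
        scale = float(lorentzian_heights(rep_ppm, signals, spec.spectrometer_freq))
        return [
            LorentzianSignal(s.center_ppm, s.fwhm_hz, s.height / scale) for s in signals
        ]

    # current per-signal model of each variable compound (library prior,
    # replaced by the adapted model after the first pass)
    model: dict[str, list[LorentzianSignal]] = {
        e.compound_id: normalized_signals(e, e.signals) for e in variable_entries
    }

    x_prev = None
    for _ in range(max(1, refine_passes)):
        calibs = m_n.normalized_calibrations
        for entry in variable_entries:
            base = spec.intensities.copy()
            for cid, j in index.items():
                if cid == entry.compound_id:
                    continue
                xj = max(float(x_est[j]), 0.0)
                if xj > 0:
                    base = base - xj * calibs[cid].intensities
            xv = max(float(x_est[index[entry.compound_id]]), 0.0)
            guides = _variable_guides(entry, spec.bin_width)
            obs = []
            for i, guide in enumerate(guides):
                # also remove the compound's *other* modeled signals so the
                # line-shape fit sees this signal alone
                others = [s for k, s in enumerate(model[entry.compound_id]) if k != i]
                residual = base
                if xv > 0 and others:
                    residual = base - xv * np.asarray(
                        lorentzian_heights(spec.ppm_axis, others, spec.spectrometer_freq)
                    )
                res_spec = BinnedSpectrum(
                    ppm_start=spec.ppm_start,
                    bin_width=spec.bin_width,
                    intensities=residual,
                    spectrometer_freq=spec.spectrometer_freq,
                    id=f"{spec.id}:residual:{guide.compound_id}",
                )
                obs.append(
                    pick_target_signal(
                        res_spec, guide, noise=noise, detection_multiplier=detection_multiplier
                    )
                )
            var_obs_full[entry.compound_id] = obs
            rep_idx = min(
                range(len(entry.signals)),
                key=lambda i: abs(entry.signals[i].center_ppm - entry.reporter_ppm),
            )
            reporter_obs[entry.compound_id] = obs[rep_idx]
        m_n, fb = adapt_matrix(constant_m, var_obs_full, library, targets, spec)
        fallback = tuple(fb)
        for entry in variable_entries:  # refresh the per-signal model
            if entry.compound_id not in fb:
                adapted = [
                    LorentzianSignal(
                        (
                            o.apex_ppm_refined
                            if (o.found and o.apex_ppm_refined is not None)
                            else (o.apex_ppm if o.found else s.center_ppm)
                        ),
                        o.fwhm_hz if (o.found and o.fwhm_hz) else s.fwhm_hz,
                        s.height,
                    )
                    for s, o in zip(entry.signals, var_obs_full[entry.compound_id])
                ]
                model[entry.compound_id] = normalized_signals(entry, adapted)
        y, pos_ppm, pos_bins, found = extract_targets(
            spec,
            targets,
            noise=noise,
            variable_observations=reporter_obs,
            detection_multiplier=detection_multiplier,
        )
        x_est = solve_reporters(m_n, y, cond_cap=cond_cap, nonnegative=nonnegative)
        if x_prev is not None:
            scale = max(float(np.max(np.abs(x_est))), 1e-300)
            if float(np.max(np.abs(x_est - x_prev))) <= REFINE_TOL * scale:
                break
        x_prev = x_est
    return m_n, fallback, y, pos_ppm, pos_bins, found, x_est


def quantify_dataset(
    spectra,
    library: list[CompoundEntry],
    targets: list[TargetSignal],
    mode: str = "improved",
    noise_region: tuple[float, float] | None = DEFAULT_NOISE_REGION,
    detection_multiplier: float = DEFAULT_DETECTION_MULTIPLIER,
    cond_cap: float = DEFAULT_COND_CAP,
    nonnegative: bool = False,
    refine_passes: int = 25,
    strict: bool = False,
) -> list[QuantRecord]:
    """Quantify a dataset of spectra sharing one axis.

    ``mode="constant"`` builds one interference matrix from nominal target
    positions and reuses it; ``mode="improved"`` characterizes each variable
    compound's signals in every spectrum, adapts the matrix, then solves.
    With an empty variable set the improved mode reduces identically to the
    constant mode.  Per-spectrum failures are logged and skipped unless
    ``strict``.
    """
    if mode not in ("constant", "improved"):
        raise ValueError(f"mode must be 'constant' or 'improved', got {mode!r}")
    spectra = list(spectra)
    if not spectra:
        return []
    axis = spectra[0]
    constant_m = build_constant_matrix(library, targets, axis)
    classes = tuple(e.compound_class for e in library)
    variable_entries = [e for e in library if e.variability == "variable"]
    records: list[QuantRecord] = []
    t_total = 0.0
    for spec in spectra:
        t0 = time.perf_counter()
        try:
            if (
                abs(spec.ppm_start - axis.ppm_start) > 1e-9
                or abs(spec.bin_width - axis.bin_width) > 1e-12
                or spec.n_bins != axis.n_bins
            ):
                raise AquaError(f"{spec.id}: axis differs from dataset axis")
            noise = (
                estimate_noise(spec, noise_region).level if noise_region is not None else 0.0
            )
            fallback: tuple[str, ...] = ()
            if mode == "improved" and variable_entries:
                m_n, fallback, y, pos_ppm, pos_bins, found, x = _improved_solve(
                    spec,
                    library,
                    targets,
                    constant_m,
                    variable_entries,
                    noise,
                    detection_multiplier,
                    cond_cap,
                    nonnegative,
                    refine_passes,
                )
            else:
                m_n = constant_m
                y, pos_ppm, pos_bins, found = extract_targets(
                    spec, targets, noise=noise, detection_multiplier=detection_multiplier
                )
                x = solve_reporters(m_n, y, cond_cap=cond_cap, nonnegative=nonnegative)
            delta = relative_interference(y, x)
            d_met, d_nonmet = decompose_interference(m_n.values, x, y, classes)
            conc = to_concentrations(x, library)
            below = x <= detection_multiplier * noise
            records.append(
                QuantRecord(
                    spectrum_id=spec.id,
                    compound_ids=m_n.compound_ids,
                    y=y,
                    position_ppm=pos_ppm,
                    position_bins=pos_bins,
                    found=found,
                    x=x,
                    delta=delta,
                    delta_met=d_met,
                    delta_nonmet=d_nonmet,
                    conc_uM=conc,
                    below_detection=below,
                    mode=mode,
                    noise_level=noise,
                    compound_classes=classes,
                    matrix_values=m_n.values,
                    fallback_compounds=fallback,
                )
            )
            dt = time.perf_counter() - t0
            t_total += dt
            logger.info(
                "%s: mode=%s k=%d solve ok%s (%.1f ms, cumulative %.2f s)",
                spec.id,
                mode,
                len(targets),
                f" fallback={list(fallback)}" if fallback else "",
                1e3 * dt,
                t_total,
            )
        except AquaError:
            if strict:
                raise
            logger.exception("%s: quantification failed; skipped", spec.id)
    return records


def records_to_frame(records: list[QuantRecord]) -> pd.DataFrame:
    """Long-format results table, one row per (spectrum, compound)."""
    rows = []
    for r in records:
        for i, cid in enumerate(r.compound_ids):
            rows.append(
                {
                    "spectrum_id": r.spectrum_id,
                    "compound_id": cid,
                    "compound_class": r.compound_classes[i],
                    "y": r.y[i],
                    "delta_y_ppm": r.position_ppm[i],
                    "position_bins": int(r.position_bins[i]),
                    "found": bool(r.found[i]),
                    "x": r.x[i],
                    "delta": r.delta[i],
                    "delta_met": r.delta_met[i],
                    "delta_nonmet": r.delta_nonmet[i],
                    "conc_uM": r.conc_uM[i],
                    "below_detection": bool(r.below_detection[i]),
                    "mode": r.mode,
                    "noise_level": r.noise_level,
                    "fallback": cid in r.fallback_compounds,
                }
            )
    return pd.DataFrame(rows)
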