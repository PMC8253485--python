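"""Dataset-level quality indicators for quantification results.

* **occurrence** — fraction of spectra in which a compound's reporter height
  exceeds the detection limit (x > 3 x noise, strict inequality).
* **positional deviation** — the symmetric radius (+/- bins) that accounts
  for 95% of the median-centered distribution of a target's observed
  positions; implemented as the smallest integer-bin radius covering >= 95%
  (ceiling quantile, lower median for even-length series so bin counts stay
  integral).
* **MAD** — per-spectrum absolute distance (bins) between the observed and
  the dataset-median position of a signal.
* **degree of interference F_q** — fraction of spectra where the relative
  interference delta of a compound exceeds q (reported at q = 0.05 and
  0.50), computable separately for the metabolite and nonmetabolite parts of
  the interference.
* **mean-concentration comparison** — per-compound relative deviation
  (mean_a - mean_b)/mean_b between two runs of the pipeline.

The report classifies each compound with the conventional thresholds:
occurrence >= 90% / >= 5%, positional deviation <= 1 bin, and a
traffic-light on interference (red: F_0.50 > 0.50; yellow: F_0.50 <= 0.50
and F_0.05 > 0; green: F_0.05 = 0).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "occurrence",
    "occurrence_table",
    "positional_deviation",
    "mad_positions",
    "decompose_interference",
    "degree_of_interference",
    "compare_means",
    "qc_report",
    "REPORT_QS",
    "OCCURRENCE_HIGH",
    "OCCURRENCE_LOW",
    "DEVIATION_BINS",
]

REPORT_QS = (0.05, 0.50)
OCCURRENCE_HIGH = 0.90
OCCURRENCE_LOW = 0.05
DEVIATION_BINS = 1
_POSITION_WARN_N = 20


def _compound_index(record, compound_id: str) -> int:
    try:
        return record.compound_ids.index(compound_id)
    except ValueError:
        raise KeyError(f"compound {compound_id!r} not in records")


def occurrence(records, compound_id: str) -> float:
    """Fraction of spectra with the compound's reporter above the detection
    limit (uses the below_detection flags set at solve time)."""
    if not records:
        raise ValueError("need at least one record")
    i = _compound_index(records[0], compound_id)
    above = [not r.below_detection[i] for r in records]
    return float(np.mean(above))


def occurrence_table(records) -> pd.Series:
    if not records:
        raise ValueError("need at least one record")
    ids = records[0].compound_ids
    return pd.Series({cid: occurrence(records, cid) for cid in ids}, name="occurrence")


def _lower_median(values: np.ndarray) -> float:
    s = np.sort(np.asarray(values))
    return float(s[(s.size - 1) // 2])


def positional_deviation(positions_bins) -> int:
    """Smallest integer d with >= 95% of |position - median| <= d bins."""
    pos = np.asarray(positions_bins, dtype=float)
    if pos.size == 0:
        raise ValueError("need at least one position")
    if pos.size < _POSITION_WARN_N:
        warnings.warn(
            f"positional deviation from only {pos.size} spectra is unreliable",
            stacklevel=2,
        )
    dev = np.sort(np.abs(pos - _lower_median(pos)))
    idx = int(np.ceil(0.95 * dev.size)) - 1
    return int(np.ceil(dev[idx]))


def mad_positions(positions_bins) -> np.ndarray:
    """Per-spectrum |position - median(position)| in bins (lower median)."""
    pos = np.asarray(positions_bins, dtype=float)
    if pos.size == 0:
        raise ValueError("need at least one position")
    return np.abs(pos - _lower_median(pos))


def decompose_interference(
    matrix_values: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    classes,
) -> tuple[np.ndarray, np.ndarray]:
    """Split each compound's relative interference by interferer class.

    ``interference_i = sum_{j != i} m[i, j] * x_j`` is divided into the part
    from metabolite columns and the part from nonmetabolite columns; each is
    divided by ``y_i`` (NaN where y <= 0).  On solver output the two parts
    sum to ``(y_i - x_i)/y_i`` exactly, up to the solve residual.
    """
    values = np.asarray(matrix_values, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    contrib = values * x[None, :]
    np.fill_diagonal(contrib, 0.0)
    met_mask = np.array([c == "metabolite" for c in classes])
    met = contrib[:, met_mask].sum(axis=1)
    nonmet = contrib[:, ~met_mask].sum(axis=1)
    d_met = np.full(y.shape, np.nan)
    d_nonmet = np.full(y.shape, np.nan)
    ok = y > 0
    d_met[ok] = met[ok] / y[ok]
    d_nonmet[ok] = nonmet[ok] / y[ok]
    return d_met, d_nonmet


def degree_of_interference(deltas, q: float) -> float:
    """F_q: fraction of spectra where delta exceeds q, over spectra where
    delta is defined (NaN entries, from y = 0, are excluded)."""
    if not 0 <= q < 1:
        raise ValueError("q must be in [0, 1)")
    d = np.asarray(deltas, dtype=float)
    defined = d[~np.isnan(d)]
    if defined.size == 0:
        return float("nan")
    return float(np.count_nonzero(defined > q) / defined.size)


def compare_means(records_a, records_b) -> pd.Series:
    """Per-compound relative deviation of mean concentrations:
    (mean_a - mean_b)/mean_b.  NaN where mean_b is 0 or undefined."""
    if not records_a or not records_b:
        raise ValueError("need records on both sides")
    ids = records_a[0].compound_ids
    if records_b[0].compound_ids != ids:
        raise ValueError("compound sets differ between the two runs")
    out = {}
    for i, cid in enumerate(ids):
        a = np.array([r.conc_uM[i] for r in records_a])
        b = np.array([r.conc_uM[i] for r in records_b])
        mean_a = np.nanmean(a) if not np.all(np.isnan(a)) else np.nan
        mean_b = np.nanmean(b) if not np.all(np.isnan(b)) else np.nan
        if np.isnan(mean_b) or mean_b == 0:
            out[cid] = np.nan
        else:
            out[cid] = (mean_a - mean_b) / mean_b
    return pd.Series(out, name="relative_mean_deviation")


def _traffic_light(f050: float, f005: float) -> str:
    if np.isnan(f050) or np.isnan(f005):
        return "undefined"
    if f050 > 0.50:
        return "red"
    if f005 > 0.0:
        return "yellow"
    return "green"


def qc_report(records, qs=REPORT_QS) -> pd.DataFrame:
    """Per-compound quality-indicator table over a dataset of records."""
    if not records:
        raise ValueError("need at least one record")
    ids = records[0].compound_ids
    q_lo, q_hi = sorted(qs)
    rows = []
    for i, cid in enumerate(ids):
        occ = occurrence(records, cid)
        positions = np.array([r.position_bins[i] for r in records])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pdev = positional_deviation(positions)
        d_met = np.array([r.delta_met[i] for r in records])
        d_nonmet = np.array([r.delta_nonmet[i] for r in records])
        f_lo_met = degree_of_interference(d_met, q_lo)
        f_hi_met = degree_of_interference(d_met, q_hi)
        f_lo_non = degree_of_interference(d_nonmet, q_lo)
        f_hi_non = degree_of_interference(d_nonmet, q_hi)
        n_undefined = int(np.count_nonzero(np.isnan([r.delta[i] for r in records])))
        rows.append(
            {
                "compound_id": cid,
                "compound_class": records[0].compound_classes[i],
                "occurrence": occ,
                "positional_deviation_bins": pdev,
                f"F{q_lo:.2f}_met".replace("0.", "0"): f_lo_met,
                f"F{q_hi:.2f}_met".replace("0.", "0"): f_hi_met,
                f"F{q_lo:.2f}_nonmet".replace("0.", "0"): f_lo_non,
                f"F{q_hi:.2f}_nonmet".replace("0.", "0"): f_hi_non,
                "occurrence_ge_90pct": occ >= OCCURRENCE_HIGH,
                "occurrence_ge_5pct": occ >= OCCURRENCE_LOW,
                "deviation_le_1_bin": pdev <= DEVIATION_BINS,
                "interference_met": _traffic_light(f_hi_met, f_lo_met),
                "interference_nonmet": _traffic_light(f_hi_non, f_lo_non),
                "n_delta_undefined": n_undefined,
            }
        )
    return pd.DataFrame(rows)
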