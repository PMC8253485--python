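"""Binned 1D NMR spectra: container, ppm/bin coordinate conventions, text I/O.

A spectrum is a vector of relative intensities on a uniform ppm grid.  The
internal convention is ASCENDING ppm regardless of file order (NMR software
conventionally writes descending axes; readers normalize), with 0-based bin
indices and "nearest bin" rounding half away from the lower index, so that
positional statistics counted in bins are reproducible.

Supported dialects:

* ``xy`` — two numeric columns (ppm, intensity), comma/tab/whitespace
  separated, optional single header line.
* ``dense`` — one intensity per line plus a JSON or YAML sidecar header
  ``{ppm_start, bin_width, spectrometer_freq_mhz, id}`` next to the file.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import GridError, ParseError, RangeError

__all__ = [
    "BinnedSpectrum",
    "TargetSignal",
    "read_binned_spectrum",
    "write_binned_spectrum",
    "read_targets",
    "write_targets",
    "ppm_to_bin",
    "bin_to_ppm",
    "slice_region",
    "hz_to_ppm",
    "ppm_to_hz",
]

#: Tolerance (ppm) for accepting a file's ppm column as an arithmetic progression.
GRID_TOLERANCE_PPM = 1e-9

_SPLIT = re.compile(r"[,\t ;]+")


def hz_to_ppm(width_hz: float, spectrometer_freq_mhz: float) -> float:
    """Convert a width in Hz to ppm (at 600 MHz, 1.2 Hz = 0.002 ppm)."""
    return width_hz / spectrometer_freq_mhz


def ppm_to_hz(width_ppm: float, spectrometer_freq_mhz: float) -> float:
    """Convert a width in ppm to Hz."""
    return width_ppm * spectrometer_freq_mhz


@dataclass
class BinnedSpectrum:
    """A 1D NMR spectrum on a uniform ppm grid (ascending ppm).

    Parameters
    ----------
    ppm_start : float
        ppm of bin 0 (the lowest-ppm bin).
    bin_width : float
        ppm per bin, strictly positive.
    intensities : numpy.ndarray
        Relative intensities, one per bin, length >= 2.
    spectrometer_freq : float, default 600.0
        Spectrometer frequency in MHz, used for Hz <-> ppm conversion.
    id : str
        Spectrum label.
    """

    ppm_start: float
    bin_width: float
    intensities: np.ndarray
    spectrometer_freq: float = 600.0
    id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.intensities.ndim != 1 or self.intensities.size < 2:
            raise ValueError("intensities must be a 1D vector of length >= 2")
        if self.spectrometer_freq <= 0:
            raise ValueError("spectrometer_freq must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.intensities.size)

    @property
    def ppm_end(self) -> float:
        """ppm of the last bin."""
        return self.ppm_start + (self.n_bins - 1) * self.bin_width

    @property
    def ppm_axis(self) -> np.ndarray:
        """Bin-center ppm values, ascending."""
        return self.ppm_start + np.arange(self.n_bins) * self.bin_width

    def copy(self) -> "BinnedSpectrum":
        return replace(self, intensities=self.intensities.copy())


@dataclass(frozen=True)
class TargetSignal:
    """A compound's preselected target signal.

    ``variability`` distinguishes compounds whose signal position is stable
    between spectra ("constant", searched within a narrow window) from those
    that drift ("variable", searched within a wide window and re-modelled per
    spectrum).
    """

    compound_id: str
    nominal_ppm: float
    window_ppm: float
    variability: str = "constant"

    def __post_init__(self) -> None:
        if self.window_ppm <= 0:
            raise ValueError("window_ppm must be positive")
        if self.variability not in ("constant", "variable"):
            raise ValueError("variability must be 'constant' or 'variable'")


def ppm_to_bin(spectrum: BinnedSpectrum, ppm: float) -> int:
    """Nearest bin index for a ppm position.

    Rounds half away from the lower index (deterministic tie-break).  Raises
    :class:`RangeError` if ``ppm`` lies more than half a bin outside the axis.
    """
    pos = (ppm - spectrum.ppm_start) / spectrum.bin_width
    if pos < -0.5 or pos > spectrum.n_bins - 0.5:
        raise RangeError(
            f"ppm {ppm} outside axis [{spectrum.ppm_start}, {spectrum.ppm_end}]"
        )
    b = int(np.floor(pos + 0.5))
    return min(max(b, 0), spectrum.n_bins - 1)


def bin_to_ppm(spectrum: BinnedSpectrum, bin_index: int) -> float:
    """ppm of a bin center."""
    if bin_index < 0 or bin_index >= spectrum.n_bins:
        raise RangeError(f"bin {bin_index} outside [0, {spectrum.n_bins - 1}]")
    return spectrum.ppm_start + bin_index * spectrum.bin_width


def slice_region(spectrum: BinnedSpectrum, lo_ppm: float, hi_ppm: float) -> BinnedSpectrum:
    """Sub-spectrum covering [lo_ppm, hi_ppm], inclusive of the enclosing bins."""
    if lo_ppm >= hi_ppm:
        raise RangeError(f"empty region: lo {lo_ppm} >= hi {hi_ppm}")
    if hi_ppm < spectrum.ppm_start or lo_ppm > spectrum.ppm_end:
        raise RangeError(
            f"region [{lo_ppm}, {hi_ppm}] does not overlap axis "
            f"[{spectrum.ppm_start}, {spectrum.ppm_end}]"
        )
    eps = GRID_TOLERANCE_PPM / spectrum.bin_width
    lo_bin = int(np.floor((lo_ppm - spectrum.ppm_start) / spectrum.bin_width + eps))
    hi_bin = int(np.ceil((hi_ppm - spectrum.ppm_start) / spectrum.bin_width - eps))
    lo_bin = max(lo_bin, 0)
    hi_bin = min(hi_bin, spectrum.n_bins - 1)
    if hi_bin - lo_bin + 1 < 2:
        # keep the length-2 container invariant for degenerate 1-bin overlaps
        hi_bin = min(lo_bin + 1, spectrum.n_bins - 1)
        lo_bin = hi_bin - 1
    return BinnedSpectrum(
        ppm_start=bin_to_ppm(spectrum, lo_bin),
        bin_width=spectrum.bin_width,
        intensities=spectrum.intensities[lo_bin : hi_bin + 1].copy(),
        spectrometer_freq=spectrum.spectrometer_freq,
        id=spectrum.id,
    )


# ---------------------------------------------------------------------------
# I/O


def _parse_xy_lines(lines: list[str], path: str) -> tuple[np.ndarray, np.ndarray]:
    ppm, inten = [], []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in _SPLIT.split(line) if p]
        if len(parts) < 2:
            raise ParseError(f"{path}: line {lineno}: expected two columns, got {line!r}")
        try:
            ppm.append(float(parts[0]))
            inten.append(float(parts[1]))
        except ValueError:
            if lineno == 1 and not ppm:
                continue  # single header line
            raise ParseError(f"{path}: line {lineno}: non-numeric value in {line!r}")
    if len(ppm) < 2:
        raise ParseError(f"{path}: fewer than 2 data rows")
    return np.asarray(ppm), np.asarray(inten)


def _find_sidecar(path: Path) -> Path:
    for ext in (".json", ".yaml", ".yml"):
        cand = path.with_suffix(path.suffix + ext)
        if cand.exists():
            return cand
        cand = path.with_suffix(ext)
        if cand.exists():
            return cand
    raise ParseError(f"no JSON/YAML sidecar header found for {path}")


def read_binned_spectrum(
    path: str | Path,
    dialect: str = "auto",
    spectrometer_freq: float = 600.0,
    id: str | None = None,
) -> BinnedSpectrum:
    """Read a spectrum from a two-column (ppm, intensity) file or a dense
    intensity vector with a sidecar header.

    ``dialect`` is ``"xy"``, ``"dense"`` or ``"auto"`` (xy if the first data
    line has two columns).  A ppm column must be an arithmetic progression
    within ``GRID_TOLERANCE_PPM``; descending files are flipped to the
    ascending internal convention.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    lines = path.read_text().splitlines()
    if dialect == "auto":
        first_data = next((l for l in lines if l.strip() and not l.startswith("#")), "")
        dialect = "xy" if len([p for p in _SPLIT.split(first_data.strip()) if p]) >= 2 else "dense"

    if dialect == "dense":
        sidecar = _find_sidecar(path)
        text = sidecar.read_text()
        meta = json.loads(text) if sidecar.suffix == ".json" else yaml.safe_load(text)
        try:
            vals = np.array(
                [float(l) for l in lines if l.strip() and not l.startswith("#")]
            )
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric intensity line ({exc})")
        return BinnedSpectrum(
            ppm_start=float(meta["ppm_start"]),
            bin_width=float(meta["bin_width"]),
            intensities=vals,
            spectrometer_freq=float(meta.get("spectrometer_freq_mhz", spectrometer_freq)),
            id=str(meta.get("id", id if id is not None else path.stem)),
        )

    ppm, inten = _parse_xy_lines(lines, str(path))
    diffs = np.diff(ppm)
    if diffs[0] == 0:
        raise GridError(f"{path}: zero ppm step at row 2")
    # the first step defines the grid; the first row deviating from it is named
    bad = np.nonzero(np.abs(diffs - diffs[0]) > GRID_TOLERANCE_PPM)[0]
    if bad.size:
        raise GridError(
            f"{path}: non-uniform ppm grid at data row {int(bad[0]) + 2} "
            f"(step {diffs[bad[0]]:.6g} vs {diffs[0]:.6g})"
        )
    step = (ppm[-1] - ppm[0]) / (ppm.size - 1)
    if step < 0:  # descending file -> ascending internal convention
        ppm, inten, step = ppm[::-1], inten[::-1], -step
    return BinnedSpectrum(
        ppm_start=float(ppm[0]),
        bin_width=float(step),
        intensities=inten.copy(),
        spectrometer_freq=spectrometer_freq,
        id=id if id is not None else path.stem,
    )


def write_binned_spectrum(
    spectrum: BinnedSpectrum, path: str | Path, dialect: str = "xy"
) -> None:
    """Write a spectrum; round-trips intensities bit-exactly (float repr)."""
    path = Path(path)
    if dialect == "xy":
        axis = spectrum.ppm_axis
        with path.open("w") as fh:
            for p, v in zip(axis, spectrum.intensities):
                fh.write(f"{float(p)!r},{float(v)!r}\n")
    elif dialect == "dense":
        with path.open("w") as fh:
            for v in spectrum.intensities:
                fh.write(f"{float(v)!r}\n")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "ppm_start": spectrum.ppm_start,
                    "bin_width": spectrum.bin_width,
                    "spectrometer_freq_mhz": spectrum.spectrometer_freq,
                    "id": spectrum.id,
                },
                indent=1,
            )
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_targets(path: str | Path) -> list[TargetSignal]:
    """Read a target table (CSV/TSV with columns compound_id, nominal_ppm,
    window_ppm, variability)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"compound_id", "nominal_ppm", "window_ppm", "variability"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing target columns {sorted(missing)}")
    return [
        TargetSignal(
            compound_id=str(r.compound_id),
            nominal_ppm=float(r.nominal_ppm),
            window_ppm=float(r.window_ppm),
            variability=str(r.variability),
        )
        for r in df.itertuples()
    ]


def write_targets(targets: list[TargetSignal], path: str | Path) -> None:
    pd.DataFrame(
        {
            "compound_id": [t.compound_id for t in targets],
            "nominal_ppm": [t.nominal_ppm for t in targets],
            "window_ppm": [t.window_ppm for t in targets],
            "variability": [t.variability for t in targets],
        }
    ).to_csv(path, sep="\t", index=False)
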