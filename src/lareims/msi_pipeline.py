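"""MSI preprocessing and image reconstruction.

Raster-scanned REIMS spectra are turned into analysis-ready image grids:
lock-mass drift correction against leucine enkephalin (negative mode m/z
554.2615), 0.1 Da binning over a shared axis, TIC normalization, unidirectional
row-major image assembly, ion-image / RGB-composite / correlation-map
extraction, and accurate-mass annotation against a small built-in table of
species observed in laser-ablation REIMS of tissue.

Notes on conventions
--------------------
* Bins are half-open ``[lo, lo + width)`` and identified by their lower edge.
* Lock-mass correction is single-point multiplicative: the m/z axis is scaled
  by reference/observed using the most intense peak within +-0.5 Da of the
  reference; if no peak is found the last valid factor is carried forward.
* The lock-mass reference 554.2615 is used verbatim as the calibration
  constant.  The isotope-mass computation for C28H37N5O7 [M-H]- gives
  554.2620; the discrepancy is documented and deliberate -- the constant is
  an instrument calibration value, not a derived mass.  Similarly the table
  keeps computed masses for species whose commonly printed values differ in
  the last decimal (e.g. TG 52:2 [M+Cl]- computes to ~893.74).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "ScanStream",
    "ImageGrid",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "compute_mz",
    "default_annotation_table",
    "LOCK_MASS_MZ",
    "LockMassCorrector",
    "lockmass_correct",
    "bin_spectrum",
    "tic_normalize",
    "reconstruct_image",
    "extract_ion_image",
    "composite_rgb",
    "region_correlation_map",
    "annotate_peaks",
    "write_imzml",
    "read_imzml",
]

#: leucine enkephalin lock mass, negative mode (instrument calibration value)
LOCK_MASS_MZ = 554.2615
DEFAULT_BIN_WIDTH = 0.1
DEFAULT_MZ_RANGE = (50.0, 1200.0)

#: monoisotopic atomic masses (Da), CODATA/AME2020
MONOISOTOPIC_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Na": 22.9897692809,
    "K": 38.96370668,
}
ELECTRON_MASS = 5.48579909065e-4  # Da

_ADDUCTS = {
    "[M-H]-": (-MONOISOTOPIC_MASS["H"] + ELECTRON_MASS, -1),
    "[M+Cl]-": (MONOISOTOPIC_MASS["Cl"] + ELECTRON_MASS, -1),
    "[M+H]+": (MONOISOTOPIC_MASS["H"] - ELECTRON_MASS, +1),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class Spectrum:
    """A centroided spectrum: strictly increasing m/z, same-length intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have identical length")
        if self.mz.size and (np.any(np.diff(self.mz) <= 0) or self.mz[0] <= 0):
            raise ValueError("mz must be strictly increasing and positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class ScanStream:
    """Ordered spectra plus the raster geometry that produced them."""

    spectra: list
    rows: int
    cols: int
    pixel_size_um: float = 5.0
    scan_order: str = "row-major"

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass
class ImageGrid:
    """rows x cols grid of binned, normalized spectra on a shared bin axis."""

    data: np.ndarray          # (rows, cols, n_bins)
    bin_lo: float
    bin_width: float
    pixel_size_um: float = 5.0

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]

    @property
    def bin_edges(self) -> np.ndarray:
        """Lower edges of the half-open bins."""
        return self.bin_lo + self.bin_width * np.arange(self.n_bins)

    def flatten(self) -> np.ndarray:
        """(rows*cols, n_bins) view in row-major pixel order."""
        return self.data.reshape(-1, self.n_bins)


# ---------------------------------------------------------------------------
# accurate mass
# ---------------------------------------------------------------------------

def parse_formula(formula: str) -> dict:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        if not m.group(1):
            break
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def compute_mz(formula: str, adduct: str = "[M-H]-") -> float:
    """Theoretical monoisotopic m/z of ``formula`` for the given adduct.

    [M-H]- removes a proton (the electron stays, charge -1); [M+Cl]- adds a
    chloride (Cl atom plus an electron); [M+H]+ adds a proton.  The result
    carries full precision; rounding for display is the caller's business.
    """
    if adduct not in _ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}; know {sorted(_ADDUCTS)}")
    mass = 0.0
    for element, count in parse_formula(formula).items():
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        mass += MONOISOTOPIC_MASS[element] * count
    delta, charge = _ADDUCTS[adduct]
    return (mass + delta) / abs(charge)


_DEFAULT_SPECIES = [
    # (name, formula, adduct) -- species repeatedly observed in negative-mode
    # REIMS of brain and breast tissue
    ("adenine", "C5H5N5", "[M-H]-"),
    ("guanine", "C5H5N5O", "[M-H]-"),
    ("glutamine", "C5H10N2O3", "[M-H]-"),
    ("glutamate", "C5H9NO4", "[M-H]-"),
    ("PE(36:1)", "C41H80NO8P", "[M-H]-"),
    ("PE(36:2)", "C41H78NO8P", "[M-H]-"),
    ("PE(38:4)", "C43H78NO8P", "[M-H]-"),
    ("TG(52:2)", "C55H102O6", "[M+Cl]-"),
    ("leucine enkephalin", "C28H37N5O7", "[M-H]-"),
]


def default_annotation_table() -> pd.DataFrame:
    """Built-in annotation table; theoretical m/z recomputed from formulas."""
    rows = [{"name": n, "formula": f, "adduct": a,
             "theoretical_mz": compute_mz(f, a)}
            for n, f, a in _DEFAULT_SPECIES]
    return pd.DataFrame(rows)


def annotate_peaks(peaks, table: pd.DataFrame | None = None,
                   tol_ppm: float = 10.0) -> pd.DataFrame:
    """Match peaks to the annotation table by smallest |ppm| within tolerance.

    Unmatched peaks are labeled ``unknown``.
    """
    if table is None:
        table = default_annotation_table()
    theo = table["theoretical_mz"].to_numpy()
    out = []
    for mz in np.atleast_1d(np.asarray(peaks, dtype=float)):
        ppm = (mz - theo) / theo * 1e6
        j = int(np.argmin(np.abs(ppm)))
        if abs(ppm[j]) <= tol_ppm:
            out.append({"mz": mz, "name": table["name"].iloc[j],
                        "formula": table["formula"].iloc[j],
                        "adduct": table["adduct"].iloc[j],
                        "theoretical_mz": theo[j], "ppm": float(ppm[j])})
        else:
            out.append({"mz": mz, "name": "unknown", "formula": None,
                        "adduct": None, "theoretical_mz": np.nan,
                        "ppm": np.nan})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class LockMassCorrector:
    """Stateful single-point recalibration against a lock-mass compound.

    Scans without a detectable lock peak reuse the factor from the last scan
    that had one (identity if none yet); this carry-forward is the only
    cross-scan state in preprocessing.
    """

    def __init__(self, reference: float = LOCK_MASS_MZ,
                 window: float = 0.5) -> None:
        self.reference = reference
        self.window = window
        self.last_factor = 1.0

    def factor_for(self, spectrum: Spectrum) -> float:
        lo, hi = self.reference - self.window, self.reference + self.window
        mask = (spectrum.mz >= lo) & (spectrum.mz <= hi)
        if not mask.any():
            logger.warning("no lock-mass peak within +-%.2f of %.4f; "
                           "reusing factor %.6f", self.window, self.reference,
                           self.last_factor)
            return self.last_factor
        idx = np.flatnonzero(mask)
        observed = spectrum.mz[idx[np.argmax(spectrum.intensity[idx])]]
        self.last_factor = self.reference / observed
        return self.last_factor

    def correct(self, spectrum: Spectrum) -> Spectrum:
        f = self.factor_for(spectrum)
        return Spectrum(mz=spectrum.mz * f, intensity=spectrum.intensity,
                        metadata=dict(spectrum.metadata))


def lockmass_correct(spectrum: Spectrum, reference: float = LOCK_MASS_MZ,
                     window: float = 0.5,
                     corrector: LockMassCorrector | None = None) -> Spectrum:
    """One-shot lock-mass correction (stateless unless a corrector is passed)."""
    if corrector is None:
        corrector = LockMassCorrector(reference=reference, window=window)
    return corrector.correct(spectrum)


def bin_spectrum(spectrum: Spectrum, width: float = DEFAULT_BIN_WIDTH,
                 mz_range: tuple = DEFAULT_MZ_RANGE) -> np.ndarray:
    """Sum intensities into half-open bins [lo, lo+width) over ``mz_range``.

    Total in-range intensity is conserved exactly.  Peaks landing within a
    relative 1e-6 of an upper bin boundary are snapped up so that the
    half-open convention survives floating-point representation of decimal
    m/z values (e.g. a peak written as 100.1 belongs to [100.1, 100.2)).
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = mz_range
    n_bins = int(round((hi - lo) / width))
    q = (spectrum.mz - lo) / width
    idx = np.floor(q).astype(int)
    frac = q - idx
    idx = np.where(frac > 1.0 - 1e-6, idx + 1, idx)
    ok = (idx >= 0) & (idx < n_bins)
    return np.bincount(idx[ok], weights=spectrum.intensity[ok],
                       minlength=n_bins).astype(float)


def tic_normalize(vector: np.ndarray) -> np.ndarray:
    """Scale to unit total ion current; raises on an empty (all-zero) spectrum."""
    vector = np.asarray(vector, dtype=float)
    total = vector.sum()
    if total <= 0:
        raise ValueError("empty spectrum: total ion current is zero")
    return vector / total


# ---------------------------------------------------------------------------
# image reconstruction and extraction
# ---------------------------------------------------------------------------

def reconstruct_image(stream: ScanStream, width: float = DEFAULT_BIN_WIDTH,
                      mz_range: tuple = DEFAULT_MZ_RANGE,
                      lockmass: bool = True,
                      reference: float = LOCK_MASS_MZ,
                      serpentine: bool = False,
                      normalize: bool = True) -> ImageGrid:
    """Assemble a complete raster stream into an image grid.

    Spectra are assigned to pixels in unidirectional row-major raster order
    (row flyback); ``serpentine=True`` reverses every odd row instead.  Each
    pixel holds the lock-mass-corrected, binned and (by default) TIC
    normalized vector.
    """
    expected = stream.rows * stream.cols
    if len(stream) != expected:
        raise ValueError(
            f"incomplete stream: expected {expected} spectra "
            f"({stream.rows} x {stream.cols}), got {len(stream)}")
    corrector = LockMassCorrector(reference=reference)
    lo, hi = mz_range
    n_bins = int(round((hi - lo) / width))
    data = np.zeros((stream.rows, stream.cols, n_bins))
    for i, spec in enumerate(stream.spectra):
        if lockmass:
            spec = corrector.correct(spec)
        v = bin_spectrum(spec, width=width, mz_range=mz_range)
        if normalize:
            v = tic_normalize(v)
        row, col = divmod(i, stream.cols)
        if serpentine and row % 2 == 1:
            col = stream.cols - 1 - col
        data[row, col] = v
    return ImageGrid(data=data, bin_lo=lo, bin_width=width,
                     pixel_size_um=stream.pixel_size_um)


def extract_ion_image(grid: ImageGrid, mz_window: tuple) -> np.ndarray:
    """Per-pixel sum of bins overlapping the half-open window [lo, hi)."""
    lo, hi = mz_window
    if hi <= lo:
        return np.zeros((grid.rows, grid.cols))
    edges = grid.bin_edges
    sel = (edges < hi) & (edges + grid.bin_width > lo)
    return grid.data[:, :, sel].sum(axis=2)


def composite_rgb(red: np.ndarray, green: np.ndarray,
                  blue: np.ndarray) -> np.ndarray:
    """Stack three ion images into RGB, scaling each channel independently
    to [0, 1] by its own 99th percentile (clipped)."""
    channels = [np.asarray(c, dtype=float) for c in (red, green, blue)]
    shape = channels[0].shape
    if any(c.shape != shape for c in channels):
        raise ValueError("channel shapes must match")
    out = np.zeros(shape + (3,))
    for k, c in enumerate(channels):
        p99 = np.percentile(c, 99)
        if p99 > 0:
            out[..., k] = np.clip(c / p99, 0.0, 1.0)
    return out


def region_correlation_map(grid: ImageGrid, mask: np.ndarray) -> np.ndarray:
    """Pearson correlation of each pixel spectrum with the mean spectrum of a
    reference region (hyperspectral correlation image)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (grid.rows, grid.cols):
        raise ValueError("mask shape must match the grid")
    if not mask.any():
        raise ValueError("reference mask is empty")
    ref = grid.data[mask].mean(axis=0)
    ref_c = ref - ref.mean()
    ref_norm = np.linalg.norm(ref_c)
    flat = grid.flatten()
    flat_c = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat_c, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = flat_c @ ref_c / (norms * ref_norm)
    corr = np.where((norms > 0) & (ref_norm > 0), corr, 0.0)
    return corr.reshape(grid.rows, grid.cols)


# ---------------------------------------------------------------------------
# imzML IO (continuous mode)
# ---------------------------------------------------------------------------

def write_imzml(grid: ImageGrid, path: str) -> None:
    """Write an image grid as continuous-mode imzML (shared bin-center axis)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    centers = grid.bin_edges + grid.bin_width / 2.0
    with ImzMLWriter(path, mode="continuous") as writer:
        for row in range(grid.rows):
            for col in range(grid.cols):
                writer.addSpectrum(centers, grid.data[row, col],
                                   (col + 1, row + 1, 1))


def read_imzml(path: str, pixel_size_um: float = 5.0) -> ImageGrid:
    """Read continuous-mode imzML written by :func:`write_imzml`."""
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(path)
    coords = np.array(parser.coordinates)
    rows = int(coords[:, 1].max())
    cols = int(coords[:, 0].max())
    mz0, _ = parser.getspectrum(0)
    width = float(np.median(np.diff(mz0)))
    data = np.zeros((rows, cols, len(mz0)))
    for i, (x, y, _z) in enumerate(parser.coordinates):
        _, intensity = parser.getspectrum(i)
        data[y - 1, x - 1] = intensity
    return ImageGrid(data=data, bin_lo=float(mz0[0]) - width / 2.0,
                     bin_width=width, pixel_size_um=pixel_size_um)
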