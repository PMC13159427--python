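"""Reading MS²I runs and reconstructing ion images.

A tandem-MSI run is a flat sequence of spectra: per pixel one full-scan FT
spectrum followed by the targeted ion-trap MS² spectra of that pixel's
inclusion list.  This module reads such runs from mzML, partitions the
spectra by scan filter (analyzer + MS level + isolation window), lays them
out on the pixel grid, and turns any (filter, target m/z, tolerance) triple
into a 2-D ion image — the atomic object that spatial similarity networking
compares.

The mzML reader is deliberately minimal: centroided spectra, MS level, scan
start time, precursor isolation window, activation type, and 32/64-bit
float peak arrays (plain or zlib-compressed).  Profile-mode spectra are
rejected; centroiding is out of scope.
"""

from __future__ import annotations

import base64
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "PeakList",
    "ScanFilter",
    "SpectrumRecord",
    "PixelGrid",
    "MSIDataset",
    "IonImage",
    "MzmlFormatError",
    "GridMismatchError",
    "read_mzml",
    "assign_pixels",
    "uniform_line_breaks",
    "extract_ion_image",
    "detect_product_ions",
]

_NS = "{http://psi.hupo.org/ms/mzml}"

# PSI-MS controlled-vocabulary accessions the reader understands.
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LOWER = "MS:1000828"
_ACC_ISO_UPPER = "MS:1000829"
_ACC_HCD = "MS:1000422"
_ACC_CID = "MS:1000133"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


class MzmlFormatError(ValueError):
    """Raised when an mzML file violates what this reader supports."""


class GridMismatchError(ValueError):
    """Raised when a spectrum sequence does not fit the declared pixel grid."""


class IncompatibleImageError(ValueError):
    """Raised when two ion images do not share shape and valid mask."""


@dataclass(frozen=True)
class PeakList:
    """A centroided spectrum: ascending m/z values with nonnegative counts."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("m/z values must be strictly increasing")
        if inten.size and np.min(inten) < 0:
            raise ValueError("intensities must be nonnegative")

    def __len__(self) -> int:
        return int(self.mz.size)

    @staticmethod
    def empty() -> "PeakList":
        return PeakList(np.empty(0), np.empty(0))

    @staticmethod
    def from_pairs(pairs: Iterable[tuple[float, float]]) -> "PeakList":
        """Build from (m/z, intensity) pairs; coincident m/z are summed."""
        acc: dict[float, float] = {}
        for mz, i in pairs:
            acc[float(mz)] = acc.get(float(mz), 0.0) + float(i)
        if not acc:
            return PeakList.empty()
        mzs = np.array(sorted(acc))
        return PeakList(mzs, np.array([acc[m] for m in mzs]))

    def window_sum(self, target_mz: float, tolerance: float) -> float:
        """Summed intensity of peaks with |m/z − target| ≤ tolerance."""
        lo = np.searchsorted(self.mz, target_mz - tolerance, side="left")
        hi = np.searchsorted(self.mz, target_mz + tolerance, side="right")
        return float(self.intensity[lo:hi].sum())


@dataclass(frozen=True)
class ScanFilter:
    """Identity of an acquisition channel.

    MS1 channels carry no isolation metadata; MS² channels are identified by
    their isolation window (center, full width) and activation.  The
    inclusion-list index is unknown at read time and filled in by
    :func:`assign_pixels` from the column phase of the window.
    """

    analyzer: str  # "FT" | "IT"
    ms_level: int
    isolation_center: Optional[float] = None
    isolation_width: Optional[float] = None
    activation: str = "none"  # "HCD" | "CID" | "none"
    list_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.analyzer not in ("FT", "IT"):
            raise ValueError(f"unknown analyzer {self.analyzer!r}")
        if self.activation not in ("HCD", "CID", "none"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.ms_level < 1:
            raise ValueError("ms_level must be >= 1")
        if self.ms_level == 1:
            if self.isolation_center is not None or self.isolation_width is not None:
                raise ValueError("MS1 filters carry no isolation window")
        else:
            if not (self.isolation_center and self.isolation_center > 0):
                raise ValueError("MS² filters need isolation_center > 0")
            if not (self.isolation_width and self.isolation_width > 0):
                raise ValueError("MS² filters need isolation_width > 0")

    def with_list_index(self, k: int) -> "ScanFilter":
        return replace(self, list_index=k)

    def describe(self) -> str:
        if self.ms_level == 1:
            return f"{self.analyzer} MS1"
        return (
            f"{self.analyzer} MS{self.ms_level} {self.isolation_center:.4f}"
            f"±{self.isolation_width / 2:.3f} {self.activation}"
            + (f" list={self.list_index}" if self.list_index is not None else "")
        )


@dataclass(frozen=True)
class SpectrumRecord:
    """One acquired spectrum with its position in the run."""

    index: int
    filter: ScanFilter
    peaks: PeakList
    retention_time: float = 0.0


@dataclass(frozen=True)
class PixelGrid:
    """Raster geometry shared by all channels of one run.

    Row 0 is the first scan line, column 0 the first pixel in a line,
    row-major acquisition order.  MS² channels are downsampled N-fold in x:
    list k occupies FT columns k, k+N, k+2N, ...  Channel arrays are
    ceil(pixels/N) wide, with trailing columns a list never visits masked
    invalid.
    """

    n_lines: int
    pixels_per_line_ms1: int
    n_lists: int = 1
    ft_pixel_x_um: float = 20.0
    ft_pixel_y_um: float = 50.0

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.pixels_per_line_ms1 < 1 or self.n_lists < 1:
            raise ValueError("grid counts must be >= 1")

    @property
    def ms2_pixels_per_line(self) -> int:
        return math.ceil(self.pixels_per_line_ms1 / self.n_lists)

    @property
    def ms2_pixel_x_um(self) -> float:
        return self.ft_pixel_x_um * self.n_lists


@dataclass
class MSIDataset:
    """Spectra of one run arranged per channel on the pixel grid.

    ``channels`` maps each ScanFilter to a 2-D object array of
    SpectrumRecord (``None`` where the channel never acquired a pixel).
    """

    grid: PixelGrid
    channels: dict[ScanFilter, np.ndarray]
    provenance: str = ""

    def ft_filter(self) -> ScanFilter:
        for f in self.channels:
            if f.ms_level == 1:
                return f
        raise KeyError("dataset has no MS1 channel")

    def ms2_filters(self) -> list[ScanFilter]:
        out = [f for f in self.channels if f.ms_level >= 2]
        return sorted(out, key=lambda f: (f.list_index or 0, f.isolation_center))

    def find_ms2_filter(self, center: float, tol: float = 0.01) -> ScanFilter:
        """The MS² channel whose isolation center is nearest ``center``."""
        cands = [f for f in self.ms2_filters() if abs(f.isolation_center - center) <= tol]
        if not cands:
            raise KeyError(
                f"no MS² channel near m/z {center}; available: "
                + ", ".join(f.describe() for f in self.ms2_filters())
            )
        return min(cands, key=lambda f: abs(f.isolation_center - center))


@dataclass
class IonImage:
    """2-D intensity map of one target m/z under one scan filter.

    ``valid_mask`` marks pixels the channel actually acquired; values are
    zero outside it, and the pixel count P counts only valid pixels.
    A pixel acquired without the peak scores 0 and stays valid.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    target_mz: float
    tolerance: float
    filter: Optional[ScanFilter] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape or self.values.ndim != 2:
            raise ValueError("values and valid_mask must be 2-D arrays of equal shape")
        if self.values.size and np.min(self.values) < 0:
            raise ValueError("ion-image intensities must be nonnegative")
        if np.any(self.values[~self.valid_mask] != 0):
            raise ValueError("intensities outside the valid mask must be zero")

    @property
    def P(self) -> int:
        """Number of valid (acquired) pixels."""
        return int(self.valid_mask.sum())

    def compatible_with(self, other: "IonImage") -> bool:
        return (
            self.values.shape == other.values.shape
            and bool(np.array_equal(self.valid_mask, other.valid_mask))
        )


# ---------------------------------------------------------------------------
# mzML reading
# ---------------------------------------------------------------------------

def _cv_params(element) -> dict[str, str]:
    """accession -> value for all cvParams directly under ``element``."""
    out = {}
    for cv in element.findall(f"{_NS}cvParam"):
        out[cv.get("accession")] = cv.get("value", "")
    return out


def _decode_binary(bda, index: int) -> np.ndarray:
    params = _cv_params(bda)
    text = bda.findtext(f"{_NS}binary") or ""
    raw = base64.b64decode(text)
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    elif _ACC_NOCOMP not in params:
        raise MzmlFormatError(
            f"spectrum {index}: unsupported binary compression scheme"
        )
    if _ACC_F64 in params:
        dtype = "<f8"
    elif _ACC_F32 in params:
        dtype = "<f4"
    else:
        raise MzmlFormatError(f"spectrum {index}: unsupported binary data type")
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(elem, position: int) -> SpectrumRecord:
    params = _cv_params(elem)
    if _ACC_PROFILE in params:
        raise MzmlFormatError(
            f"spectrum {position} is profile-mode; only centroided data are supported"
        )
    try:
        ms_level = int(params[_ACC_MS_LEVEL])
    except KeyError:
        raise MzmlFormatError(f"spectrum {position} lacks an ms level cvParam")

    rt = 0.0
    scan_list = elem.find(f"{_NS}scanList")
    if scan_list is not None:
        for scan in scan_list.findall(f"{_NS}scan"):
            for cv in scan.findall(f"{_NS}cvParam"):
                if cv.get("accession") == _ACC_SCAN_START:
                    rt = float(cv.get("value"))
                    if cv.get("unitName", "second").startswith("minute"):
                        rt *= 60.0

    center = width = None
    activation = "none"
    if ms_level >= 2:
        prec_list = elem.find(f"{_NS}precursorList")
        prec = prec_list.find(f"{_NS}precursor") if prec_list is not None else None
        iso = prec.find(f"{_NS}isolationWindow") if prec is not None else None
        if iso is None:
            raise MzmlFormatError(
                f"MS{ms_level} spectrum {position} lacks precursor isolation metadata"
            )
        iso_params = _cv_params(iso)
        try:
            center = float(iso_params[_ACC_ISO_TARGET])
        except KeyError:
            raise MzmlFormatError(
                f"MS{ms_level} spectrum {position} lacks an isolation window target m/z"
            )
        lower = float(iso_params.get(_ACC_ISO_LOWER, 0.35))
        upper = float(iso_params.get(_ACC_ISO_UPPER, 0.35))
        width = lower + upper
        act = prec.find(f"{_NS}activation")
        if act is not None:
            act_params = _cv_params(act)
            if _ACC_HCD in act_params:
                activation = "HCD"
            elif _ACC_CID in act_params:
                activation = "CID"

    mz = np.empty(0)
    inten = np.empty(0)
    bda_list = elem.find(f"{_NS}binaryDataArrayList")
    if bda_list is not None:
        for bda in bda_list.findall(f"{_NS}binaryDataArray"):
            params_b = _cv_params(bda)
            if _ACC_MZ_ARRAY in params_b:
                mz = _decode_binary(bda, position)
            elif _ACC_INT_ARRAY in params_b:
                inten = _decode_binary(bda, position)

    # PIA convention: the survey scan is the high-resolution FT channel and
    # all fragmentation scans run in the ion trap.
    analyzer = "FT" if ms_level == 1 else "IT"
    filt = ScanFilter(
        analyzer=analyzer,
        ms_level=ms_level,
        isolation_center=center,
        isolation_width=width,
        activation=activation,
    )
    return SpectrumRecord(
        index=position, filter=filt, peaks=PeakList(mz, inten), retention_time=rt
    )


def read_mzml(path: str) -> list[SpectrumRecord]:
    """Read an mzML run into SpectrumRecords, in acquisition order.

    MS² spectra must carry their precursor isolation window; profile-mode
    spectra are rejected.
    """
    records = []
    position = 0
    for _, elem in etree.iterparse(str(path), tag=f"{_NS}spectrum"):
        records.append(_parse_spectrum(elem, position))
        position += 1
        elem.clear()
        while elem.getprevious() is not None:
            del elem.getparent()[0]
    return records


# ---------------------------------------------------------------------------
# Pixel assignment
# ---------------------------------------------------------------------------

def uniform_line_breaks(grid: PixelGrid, n_ms2_per_ft: int) -> list[int]:
    """Record indices starting each line, for uniform lines of full pixels."""
    per_line = grid.pixels_per_line_ms1 * (1 + n_ms2_per_ft)
    return [line * per_line for line in range(grid.n_lines)]


def _split_blocks(records: Sequence[SpectrumRecord], line_no: int):
    """Split one line's records into per-pixel blocks of 1 FT + k MS² scans."""
    blocks: list[list[SpectrumRecord]] = []
    for rec in records:
        if rec.filter.ms_level == 1:
            blocks.append([rec])
        else:
            if not blocks:
                raise GridMismatchError(
                    f"line {line_no} starts with an MS{rec.filter.ms_level} scan; "
                    "each pixel block must open with an FT survey scan"
                )
            blocks[-1].append(rec)
    return blocks


def assign_pixels(
    records: Sequence[SpectrumRecord],
    grid: PixelGrid,
    line_breaks: Sequence[int],
) -> MSIDataset:
    """Lay a flat spectrum sequence out on the pixel grid, per channel.

    ``line_breaks`` lists the record index starting each scan line.  Within a
    line, each pixel contributes one FT scan followed by its MS² scans; the
    MS² windows of a pixel at FT column c belong to inclusion list c mod N
    and land at column c // N of their (N-fold coarser) channel.
    """
    if len(line_breaks) != grid.n_lines:
        raise GridMismatchError(
            f"{len(line_breaks)} line breaks for a grid of {grid.n_lines} lines"
        )
    if list(line_breaks) != sorted(set(int(b) for b in line_breaks)):
        raise GridMismatchError("line_breaks must be strictly increasing")

    n = grid.n_lists
    ms2_cols = grid.ms2_pixels_per_line
    ft_channel = np.full((grid.n_lines, grid.pixels_per_line_ms1), None, dtype=object)
    ft_filter: Optional[ScanFilter] = None
    ms2_channels: dict[ScanFilter, np.ndarray] = {}
    window_list: dict[tuple, int] = {}  # base MS² filter -> list index

    bounds = list(line_breaks) + [len(records)]
    for line_no in range(grid.n_lines):
        line_records = records[bounds[line_no] : bounds[line_no + 1]]
        blocks = _split_blocks(line_records, line_no)
        if len(blocks) != grid.pixels_per_line_ms1:
            raise GridMismatchError(
                f"line {line_no}: expected {grid.pixels_per_line_ms1} pixel "
                f"blocks, found {len(blocks)}"
            )
        for col, block in enumerate(blocks):
            ft_rec = block[0]
            if ft_filter is None:
                ft_filter = ft_rec.filter
            ft_channel[line_no, col] = ft_rec
            k = col % n
            for rec in block[1:]:
                base = replace(rec.filter, list_index=None)
                key = (base.isolation_center, base.isolation_width, base.activation,
                       base.ms_level)
                if key in window_list and window_list[key] != k:
                    raise GridMismatchError(
                        f"isolation window {base.isolation_center} appears on "
                        f"inclusion lists {window_list[key]} and {k}; a window "
                        "must belong to exactly one list"
                    )
                window_list[key] = k
                filt = base.with_list_index(k)
                if filt not in ms2_channels:
                    ms2_channels[filt] = np.full(
                        (grid.n_lines, ms2_cols), None, dtype=object
                    )
                ms2_channels[filt][line_no, col // n] = rec

    if ft_filter is None:
        raise GridMismatchError("run contains no FT survey scans")
    channels: dict[ScanFilter, np.ndarray] = {ft_filter: ft_channel}
    channels.update(ms2_channels)
    return MSIDataset(grid=grid, channels=channels)


# ---------------------------------------------------------------------------
# Ion images
# ---------------------------------------------------------------------------

def extract_ion_image(
    dataset: MSIDataset,
    filt: ScanFilter,
    target_mz: float,
    tolerance: float,
) -> IonImage:
    """Reconstruct the image of one target m/z under one scan filter.

    Each valid pixel's value is the summed intensity of peaks within
    ±tolerance of the target; pixels the channel never acquired are masked
    invalid and set to zero.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    try:
        channel = dataset.channels[filt]
    except KeyError:
        available = ", ".join(f.describe() for f in dataset.channels)
        raise KeyError(f"unknown scan filter {filt.describe()}; available: {available}")
    values = np.zeros(channel.shape)
    mask = np.zeros(channel.shape, dtype=bool)
    for (r, c), rec in np.ndenumerate(channel):
        if rec is None:
            continue
        mask[r, c] = True
        values[r, c] = rec.peaks.window_sum(target_mz, tolerance)
    return IonImage(
        values=values, valid_mask=mask, target_mz=target_mz,
        tolerance=tolerance, filter=filt,
    )


def detect_product_ions(
    dataset: MSIDataset,
    filt: ScanFilter,
    bin_width: float = 0.5,
    min_pixel_fraction: float = 0.05,
    min_rel_intensity: float = 0.01,
) -> list[float]:
    """Find candidate product-ion m/z centers in one MS² channel.

    Pools all valid pixels of the channel into a mean spectrum binned at
    ``bin_width`` and keeps intensity-weighted bin centroids that reach
    ``min_rel_intensity`` of the strongest bin and occur in at least
    ``min_pixel_fraction`` of the pixels.  Returns centers sorted by m/z.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    channel = dataset.channels[filt]
    total: dict[int, float] = {}
    weighted_mz: dict[int, float] = {}
    occupancy: dict[int, int] = {}
    n_pixels = 0
    for (_, _), rec in np.ndenumerate(channel):
        if rec is None:
            continue
        n_pixels += 1
        if not len(rec.peaks):
            continue
        bins = np.floor(rec.peaks.mz / bin_width).astype(int)
        for b in np.unique(bins):
            sel = bins == b
            inten = float(rec.peaks.intensity[sel].sum())
            if inten <= 0:
                continue
            total[b] = total.get(b, 0.0) + inten
            weighted_mz[b] = weighted_mz.get(b, 0.0) + float(
                (rec.peaks.mz[sel] * rec.peaks.intensity[sel]).sum()
            )
            occupancy[b] = occupancy.get(b, 0) + 1
    if not total or n_pixels == 0:
        return []
    base = max(total.values())
    centers = []
    for b, inten in total.items():
        if inten < min_rel_intensity * base:
            continue
        if occupancy[b] / n_pixels < min_pixel_fraction:
            continue
        centers.append(weighted_mz[b] / inten)
    return sorted(centers)
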