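"""Parallel image acquisition (PIA) arithmetic.

PIA couples one long, high-resolution Fourier-transform (FT) survey scan per
pixel with *n* targeted ion-trap MS² scans acquired in parallel during the FT
transient.  Because the FT analyzer accumulates ions for only a few
milliseconds of a transient lasting about a second, the vast majority of the
continuously arriving ion flux would otherwise be discarded; the parallel MS²
scans recover it.  Cycling through *N* inclusion lists along the fast (x)
scan axis multiplies the number of precursor isolation windows covered per
experiment at the cost of an N-fold coarser MS² pixel in x.

This module holds the bookkeeping for that scheme: duty-cycle / ion
utilization, total window coverage, FT vs MS² pixel geometry, and the
per-pixel scan schedule that the synthetic-data writer consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "AcquisitionConfig",
    "DutyCycleReport",
    "ScheduleEntry",
    "ion_utilization",
    "coverage",
    "ms2_geometry",
    "duty_cycle_report",
    "build_schedule",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing, multiplexing and stage geometry of one PIA experiment.

    Parameters
    ----------
    ft_scan_time_ms:
        Duration of one FT transient in milliseconds (1024 ms for a
        500 000 resolving-power scan at m/z 200).
    ft_accumulation_ms:
        Ion accumulation (injection) time feeding one FT scan, ms.
    n_lists:
        Number of inclusion lists N cycled along the x axis.
    windows_per_list:
        Number of precursor isolation windows targeted by each list; equals
        the number n of MS² scans acquired per pixel, since a pixel runs its
        list once.
    isolation_width_da:
        Full width of each precursor isolation window, Da.
    ft_pixel_x_um, ft_pixel_y_um:
        FT pixel pitch along the scan direction (x) and between lines (y).
    inclusion_lists:
        Optional explicit window centers (Th), one sequence per list, each of
        length ``windows_per_list``.  Required by the synthetic writer;
        the duty-cycle arithmetic does not need them.
    """

    ft_scan_time_ms: float = 1024.0
    ft_accumulation_ms: float = 5.0
    n_lists: int = 4
    windows_per_list: int = 27
    isolation_width_da: float = 0.7
    ft_pixel_x_um: float = 20.0
    ft_pixel_y_um: float = 50.0
    inclusion_lists: Optional[tuple[tuple[float, ...], ...]] = None

    def __post_init__(self) -> None:
        if self.ft_scan_time_ms <= 0 or self.ft_accumulation_ms <= 0:
            raise ValueError("FT scan and accumulation times must be positive")
        if self.n_lists < 1 or self.windows_per_list < 1:
            raise ValueError("n_lists and windows_per_list must be >= 1")
        if self.isolation_width_da <= 0:
            raise ValueError("isolation_width_da must be positive")
        if self.ft_pixel_x_um <= 0 or self.ft_pixel_y_um <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.inclusion_lists is not None:
            lists = tuple(tuple(float(w) for w in lst) for lst in self.inclusion_lists)
            object.__setattr__(self, "inclusion_lists", lists)
            if len(lists) != self.n_lists:
                raise ValueError(
                    f"expected {self.n_lists} inclusion lists, got {len(lists)}"
                )
            for k, lst in enumerate(lists):
                if len(lst) != self.windows_per_list:
                    raise ValueError(
                        f"inclusion list {k} has {len(lst)} windows, "
                        f"expected {self.windows_per_list}"
                    )

    @property
    def n_ms2_per_ft(self) -> int:
        """MS² scans per pixel (one pass through that pixel's list)."""
        return self.windows_per_list


@dataclass(frozen=True)
class DutyCycleReport:
    """Summary of ion usage and geometry for one configuration."""

    ft_ion_utilization: float
    ft_ion_unused: float
    total_windows: int
    ms2_pixel_x_um: float
    ms2_pixel_y_um: float
    ms2_spectra_per_pixel_cycle: int

    def as_dict(self) -> dict:
        return {
            "ft_ion_utilization": self.ft_ion_utilization,
            "ft_ion_unused": self.ft_ion_unused,
            "total_windows": self.total_windows,
            "ms2_pixel_x_um": self.ms2_pixel_x_um,
            "ms2_pixel_y_um": self.ms2_pixel_y_um,
            "ms2_spectra_per_pixel_cycle": self.ms2_spectra_per_pixel_cycle,
        }


@dataclass(frozen=True)
class ScheduleEntry:
    """One pixel of the acquisition schedule.

    ``window_centers`` holds the isolation-window centers (Th) of the list
    assigned to this pixel, in scan order, or ``None`` placeholders when the
    configuration carries no explicit inclusion lists.
    """

    row: int
    col: int
    list_index: int
    window_centers: tuple[Optional[float], ...]


def ion_utilization(config: AcquisitionConfig) -> tuple[float, float]:
    """Fraction of the incoming ion flux used / left unused by the FT channel.

    The FT analyzer accumulates ions for ``ft_accumulation_ms`` out of every
    ``ft_scan_time_ms`` transient; everything arriving outside that window is
    lost unless captured by parallel MS² scans.
    """
    if config.ft_accumulation_ms > config.ft_scan_time_ms:
        raise ValueError(
            "ion accumulation time cannot exceed the FT scan time "
            f"({config.ft_accumulation_ms} > {config.ft_scan_time_ms} ms)"
        )
    used = config.ft_accumulation_ms / config.ft_scan_time_ms
    return used, 1.0 - used


def coverage(config: AcquisitionConfig) -> int:
    """Total number of precursor isolation windows covered per experiment."""
    return config.n_lists * config.windows_per_list


def ms2_geometry(config: AcquisitionConfig) -> tuple[float, float]:
    """MS² pixel size (x, y) in µm.

    Cycling N lists means each list revisits only every Nth x position, so
    the MS² pixel grows N-fold along x; the y pitch (line spacing) is shared
    with the FT channel.
    """
    return config.ft_pixel_x_um * config.n_lists, config.ft_pixel_y_um


def duty_cycle_report(config: AcquisitionConfig) -> DutyCycleReport:
    used, unused = ion_utilization(config)
    ms2_x, ms2_y = ms2_geometry(config)
    return DutyCycleReport(
        ft_ion_utilization=used,
        ft_ion_unused=unused,
        total_windows=coverage(config),
        ms2_pixel_x_um=ms2_x,
        ms2_pixel_y_um=ms2_y,
        ms2_spectra_per_pixel_cycle=config.n_ms2_per_ft,
    )


def build_schedule(config: AcquisitionConfig, grid) -> list[ScheduleEntry]:
    """Per-pixel scan schedule for a row-major raster over ``grid``.

    ``grid`` is an :class:`ssnmsi.msi_io.PixelGrid` (or anything exposing
    ``n_lines``, ``pixels_per_line_ms1`` and ``n_lists``).  Pixel (r, c) is
    assigned inclusion list ``c mod N``; over any N consecutive x positions
    every window of every list is scheduled exactly once.
    """
    if grid.n_lists != config.n_lists:
        raise ValueError(
            f"grid expects {grid.n_lists} inclusion lists but the acquisition "
            f"config defines {config.n_lists}"
        )
    if config.inclusion_lists is not None:
        lists: Sequence[tuple[Optional[float], ...]] = config.inclusion_lists
    else:
        lists = [
            tuple(None for _ in range(config.windows_per_list))
            for _ in range(config.n_lists)
        ]
    schedule = []
    for row in range(grid.n_lines):
        for col in range(grid.pixels_per_line_ms1):
            k = col % config.n_lists
            schedule.append(
                ScheduleEntry(row=row, col=col, list_index=k, window_centers=tuple(lists[k]))
            )
    return schedule
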