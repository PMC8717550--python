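"""DIA acquisition geometry.

Small-window DIA schedules the same ordered set of isolation windows every
cycle, so the (cycle, window) pair of an MS/MS scan is determined by the
acquisition method alone, never by the sample.  This module models that
prescheduled window scheme and provides the window-index half of the dual
index (dID) used downstream.

The default scheme tiles the densely populated 400–800 m/z precursor range
with 6-Th windows overlapping by 1 Th (5-Th step), which yields exactly 80
windows per cycle; with an 8-s cycle time and ~8-s chromatographic peak
widths (FWHM) every eluting peptide is sampled in its window at least twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InvalidSchemeError",
    "WindowScheme",
    "build_window_scheme",
    "window_index_of",
    "windows_containing",
    "scheme_from_config",
    "DEFAULT_SCHEME_PARAMS",
]

#: Default acquisition parameters (m/z range in Th, times in seconds).
DEFAULT_SCHEME_PARAMS = {
    "range_low": 400.0,
    "range_high": 800.0,
    "width": 6.0,
    "overlap": 1.0,
    "cycle_time": 8.0,
}


class InvalidSchemeError(ValueError):
    """Raised when the requested window tiling is geometrically impossible."""


@dataclass(frozen=True)
class WindowScheme:
    """Ordered isolation windows of one DIA acquisition cycle.

    Attributes
    ----------
    windows : tuple of (lower m/z, upper m/z)
        Sorted by lower edge, strictly increasing, equal width.
    width, overlap : float
        Isolation width and inter-window overlap in Th.
    precursor_range : (float, float)
        Scheduled precursor m/z range; the union of windows covers it (the
        last window may extend past the upper bound, keeping widths equal).
    cycle_time : float
        Duration of one full window cycle in seconds.
    """

    windows: tuple[tuple[float, float], ...]
    width: float
    overlap: float
    precursor_range: tuple[float, float]
    cycle_time: float = 8.0

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def step(self) -> float:
        """Spacing between consecutive window lower edges (width − overlap)."""
        return self.width - self.overlap

    @property
    def centers(self) -> np.ndarray:
        return np.array([(lo + hi) / 2.0 for lo, hi in self.windows])

    def to_table(self) -> pd.DataFrame:
        """Tab-friendly scheme table (1-based index, edges, centers)."""
        lo = np.array([w[0] for w in self.windows])
        hi = np.array([w[1] for w in self.windows])
        return pd.DataFrame(
            {
                "index": np.arange(1, self.n_windows + 1),
                "lower_mz": lo,
                "upper_mz": hi,
                "center_mz": (lo + hi) / 2.0,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def build_window_scheme(
    range_low: float,
    range_high: float,
    width: float,
    overlap: float = 0.0,
    cycle_time: float = 8.0,
) -> WindowScheme:
    """Construct the minimal ordered tiling of ``[range_low, range_high]``.

    Window ``k`` (0-based) starts at ``range_low + k * (width - overlap)``;
    windows are emitted until the first one whose upper edge reaches
    ``range_high``.  All windows keep the full width, so the last window may
    extend beyond ``range_high``.

    Raises
    ------
    InvalidSchemeError
        If ``width <= overlap``, ``width <= 0``, ``overlap < 0`` or the m/z
        range is empty.
    """
    if width <= 0:
        raise InvalidSchemeError(f"window width must be positive, got {width}")
    if overlap < 0:
        raise InvalidSchemeError(f"overlap must be non-negative, got {overlap}")
    if width <= overlap:
        raise InvalidSchemeError(
            f"width ({width}) must exceed overlap ({overlap}); "
            "the tiling would never advance"
        )
    if range_high <= range_low:
        raise InvalidSchemeError(
            f"empty precursor range [{range_low}, {range_high}]"
        )
    step = width - overlap
    windows: list[tuple[float, float]] = []
    k = 0
    while True:
        lo = range_low + k * step
        hi = lo + width
        windows.append((lo, hi))
        if hi >= range_high - 1e-9:
            break
        k += 1
    return WindowScheme(
        windows=tuple(windows),
        width=float(width),
        overlap=float(overlap),
        precursor_range=(float(range_low), float(range_high)),
        cycle_time=float(cycle_time),
    )


def window_index_of(isolation_center: float, scheme: WindowScheme) -> int | None:
    """1-based index of the scheme window nearest an isolation center.

    The match must fall within half a window step of the nearest center
    (i.e. the scan's isolation center is closer to this window than to any
    neighbour); otherwise the scan is unassignable and ``None`` is returned.
    """
    if scheme.n_windows == 0:
        raise InvalidSchemeError("empty window scheme")
    centers = scheme.centers
    k = int(np.clip(round((isolation_center - centers[0]) / scheme.step), 0,
                    scheme.n_windows - 1))
    if abs(isolation_center - centers[k]) <= scheme.step / 2.0 + 1e-9:
        return k + 1
    return None


def windows_containing(mz: float, scheme: WindowScheme) -> list[int]:
    """All 1-based window indices whose [lower, upper] interval contains mz.

    With a positive overlap an interior m/z at a window junction belongs to
    exactly two windows — the intentional co-isolation of small-window DIA.
    """
    return [
        k + 1
        for k, (lo, hi) in enumerate(scheme.windows)
        if lo <= mz <= hi
    ]


def scheme_from_config(source: str | Path | dict) -> WindowScheme:
    """Build a scheme from a YAML file or dict with an ``acquisition:`` block.

    Recognised keys (all optional, defaults are the 80-window production
    scheme): range_low, range_high, width, overlap, cycle_time.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(source)
    params = dict(DEFAULT_SCHEME_PARAMS)
    params.update(cfg.get("acquisition", cfg) or {})
    return build_window_scheme(
        params["range_low"],
        params["range_high"],
        params["width"],
        params["overlap"],
        params["cycle_time"],
    )
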