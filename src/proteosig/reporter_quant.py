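"""TMT reporter-ion extraction.

Every TMT label releases a channel-specific low-mass reporter ion on HCD
fragmentation; its intensity quantifies the multiplexed sample in that
channel.  Extraction is identification-free: for each channel the most
intense peak within a ppm tolerance of the theoretical reporter m/z is
taken, and an unmatched channel records 0 (not missing) so that downstream
signature matrices stay complete.

Theoretical reporter m/z values are singly-protonated monoisotopic masses
computed from the published reagent compositions (C8H16N+ for channel 126,
plus 13C/15N isotope substitutions for the heavier channels).  The N/C
isotopologue pairs sit ~6.3 mDa apart, well outside a 10-ppm window at
m/z ≈ 127 (±1.27 mDa), so adjacent channels never cross-assign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra_io import MsmsScan

__all__ = [
    "TMT_REPORTER_MZ",
    "ReporterChannelSet",
    "ReporterVector",
    "extract_reporters",
    "reporters_to_table",
]

# Monoisotopic m/z of the singly charged TMT reporter ions (Th).
# 126 = C8H16N+; each step adds one 13C (+1.0033548) or swaps 14N -> 15N
# (+0.9970349).  131 (TMT10) and 131N (TMT11) are the same ion.
TMT_REPORTER_MZ: dict[str, float] = {
    "126": 126.127726,
    "127N": 127.124761,
    "127C": 127.131081,
    "128N": 128.128116,
    "128C": 128.134436,
    "129N": 129.131471,
    "129C": 129.137790,
    "130N": 130.134825,
    "130C": 130.141145,
    "131": 131.138180,
    "131N": 131.138180,
    "131C": 131.144500,
}

_TMT10_LABELS = ("126", "127N", "127C", "128N", "128C",
                 "129N", "129C", "130N", "130C", "131")
_TMT11_LABELS = ("126", "127N", "127C", "128N", "128C",
                 "129N", "129C", "130N", "130C", "131N", "131C")


@dataclass(frozen=True)
class ReporterChannelSet:
    """Ordered reporter channels of one TMT plex."""

    name: str
    labels: tuple[str, ...]
    mz: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.mz):
            raise ValueError("labels and m/z lists differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        if list(self.mz) != sorted(self.mz):
            raise ValueError("channels must be ordered by theoretical m/z")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def tmt10(cls) -> "ReporterChannelSet":
        return cls("TMT10", _TMT10_LABELS,
                   tuple(TMT_REPORTER_MZ[c] for c in _TMT10_LABELS))

    @classmethod
    def tmt11(cls) -> "ReporterChannelSet":
        return cls("TMT11", _TMT11_LABELS,
                   tuple(TMT_REPORTER_MZ[c] for c in _TMT11_LABELS))

    @classmethod
    def from_name(cls, name: str) -> "ReporterChannelSet":
        key = name.lower().replace("-", "").replace("plex", "")
        if key in ("tmt10", "10"):
            return cls.tmt10()
        if key in ("tmt11", "11"):
            return cls.tmt11()
        raise ValueError(f"unknown plex {name!r} (expected TMT10 or TMT11)")


@dataclass
class ReporterVector:
    """Per-scan reporter intensities, one non-negative value per channel."""

    run_id: str
    scan_number: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)


def extract_reporters(
    scan: MsmsScan,
    channels: ReporterChannelSet,
    tol_ppm: float = 10.0,
) -> ReporterVector:
    """Extract raw reporter intensities from one MS/MS scan.

    For each channel, peaks satisfying |m/z − m/z_theor| / m/z_theor ≤
    tol_ppm × 1e-6 are candidates and the most intense one is selected;
    channels with no candidate record 0.
    """
    if scan.ms_level != 2:
        raise ValueError(f"scan {scan.scan_number} is not an MS/MS scan")
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be positive, got {tol_ppm}")
    out = np.zeros(len(channels))
    mz = scan.mz_array
    inten = scan.intensity_array
    for i, target in enumerate(channels.mz):
        delta = target * tol_ppm * 1e-6
        lo = np.searchsorted(mz, target - delta, side="left")
        hi = np.searchsorted(mz, target + delta, side="right")
        if hi > lo:
            out[i] = inten[lo:hi].max()
    return ReporterVector(scan.run_id, scan.scan_number, out)


def reporters_to_table(
    vectors: list[ReporterVector],
    channels: ReporterChannelSet,
    wide: bool = False,
) -> pd.DataFrame:
    """Long-form (run_id, scan_number, channel, intensity) or wide per-scan table."""
    wide_df = pd.DataFrame(
        [v.intensities for v in vectors],
        columns=list(channels.labels),
    )
    wide_df.insert(0, "run_id", [v.run_id for v in vectors])
    wide_df.insert(1, "scan_number", [v.scan_number for v in vectors])
    if wide:
        return wide_df
    return wide_df.melt(
        id_vars=["run_id", "scan_number"],
        var_name="channel",
        value_name="intensity",
    )
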