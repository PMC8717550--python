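"""Spectral-library augmentation with TMT reporter ions.

Search engines that match DIA runs against a spectral library only export
quantification for fragments present in the library.  Adding the fixed
reporter masses of the TMT reagents as extra fragment rows to every
library entry therefore makes the reporter region visible to the library
search and lets it export multiplexed quantification.

The library dialect is a minimal tab-separated fragment-level table with
the columns below; unknown columns are passed through untouched.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .reporter_quant import ReporterChannelSet

__all__ = [
    "LIBRARY_COLUMNS",
    "REPORTER_ANNOTATION_PREFIX",
    "read_library",
    "write_library",
    "augment_with_reporters",
]

#: Required columns of the fragment-level library table.
LIBRARY_COLUMNS = (
    "modified_peptide",
    "precursor_charge",
    "precursor_mz",
    "fragment_mz",
    "relative_intensity",
    "fragment_annotation",
    "normalized_rt",
)

REPORTER_ANNOTATION_PREFIX = "reporter_"

#: Cross-assignment guard when checking pre-existing reporter rows (Th).
_REPORTER_MZ_TOL = 0.002


def read_library(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spectral library {path} missing columns: {missing}")
    if (df["fragment_mz"] <= 0).any():
        raise ValueError(f"spectral library {path} has non-positive fragment m/z")
    return df


def write_library(library: pd.DataFrame, path: str | Path) -> None:
    library.to_csv(path, sep="\t", index=False)


def augment_with_reporters(
    library: pd.DataFrame,
    channels: ReporterChannelSet,
    reporter_intensity: float = 1.0,
) -> pd.DataFrame:
    """Add one reporter fragment row per channel to every library entry.

    Entries are keyed by (modified_peptide, precursor_charge).  Reporter
    rows are annotated ``reporter_<channel>`` and inherit the entry's
    precursor fields; non-reporter rows are returned untouched.  The
    operation is idempotent: entries already carrying a reporter
    annotation for a channel are skipped, but a pre-existing reporter row
    whose m/z disagrees with the channel's theoretical value is an error.
    """
    if len(library) == 0:
        return library.copy()
    is_reporter = library["fragment_annotation"].astype(str).str.startswith(
        REPORTER_ANNOTATION_PREFIX
    )
    new_rows = []
    for (pep, charge), entry in library.groupby(
        ["modified_peptide", "precursor_charge"], sort=False
    ):
        existing = entry[is_reporter.loc[entry.index]]
        have = {}
        for _, row in existing.iterrows():
            label = str(row["fragment_annotation"])[len(REPORTER_ANNOTATION_PREFIX):]
            have[label] = float(row["fragment_mz"])
        template = entry.iloc[0]
        for label, mz in zip(channels.labels, channels.mz):
            if label in have:
                if abs(have[label] - mz) > _REPORTER_MZ_TOL:
                    raise ValueError(
                        f"entry {pep}/{charge}: existing reporter_{label} at "
                        f"{have[label]:.5f} conflicts with theoretical {mz:.5f}"
                    )
                continue
            row = {c: template[c] for c in library.columns}
            row.update(
                fragment_mz=mz,
                relative_intensity=reporter_intensity,
                fragment_annotation=f"{REPORTER_ANNOTATION_PREFIX}{label}",
            )
            new_rows.append(row)
    if not new_rows:
        return library.copy()
    return pd.concat(
        [library, pd.DataFrame(new_rows)], ignore_index=True
    )
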