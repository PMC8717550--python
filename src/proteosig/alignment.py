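"""Anchor-based RT alignment, dual indexing and run aggregation.

The identification-free aggregation rests on two observations: (i) in DIA
the isolation-window sequence is prescheduled, so the window index of an
MS/MS scan is sample-independent; (ii) after aligning runs in retention
time on a handful of ubiquitous anchor precursors, the acquisition-cycle
number of a scan is comparable across runs.  Binning aligned RT at the
cycle time and pairing the bin with the window index yields a dual index
dID = (rt_bin, window_index) that names the "same" MS/MS event in every
run.  Filling the full scheduled (rt_bin × window) grid with per-channel
reporter intensities gives one complete quantitative matrix per TMT
channel — a proteome signature — and stacking the per-channel rows of many
runs gives a samples × features matrix with zero missing entries by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .acquisition import WindowScheme, window_index_of
from .reporter_quant import ReporterChannelSet, ReporterVector
from .spectra_io import MsmsScan, RunManifest

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentError",
    "AggregationError",
    "DEFAULT_ANCHOR_MZ",
    "RtMap",
    "DualIndex",
    "ProteomeSignature",
    "AggregatedMatrix",
    "detect_anchor_elution",
    "fit_rt_map",
    "assign_did",
    "build_signature",
    "aggregate_runs",
    "feature_names",
]


class AlignmentError(RuntimeError):
    """RT alignment is impossible (too few anchors, non-monotone order...)."""


class AggregationError(ValueError):
    """Signatures cannot be aggregated (mismatched schemes or grids)."""


#: Doubly charged precursors observed in essentially every run of this
#: acquisition scheme; their elution apexes are the alignment landmarks.
DEFAULT_ANCHOR_MZ: tuple[float, ...] = (
    466.7743,
    660.3674,
    464.779,
    437.2732,
    587.3539,
    587.864,
    706.4723,
)


class DualIndex(NamedTuple):
    rt_bin: int  # 1-based
    window_index: int  # 1-based


# ---------------------------------------------------------------------------
# anchors


def detect_anchor_elution(
    scans: Sequence[MsmsScan],
    anchors: Sequence[float] = DEFAULT_ANCHOR_MZ,
    scheme: WindowScheme | None = None,
    *,
    tol_ppm: float = 10.0,
    min_snr: float = 5.0,
) -> dict[float, float]:
    """Locate the elution apex of each anchor precursor within its window.

    For every anchor m/z the trace of summed intensity within ±``tol_ppm``
    of that m/z is built across the scans of the anchor's isolation window,
    lightly smoothed (3-point moving average) and its apex located with
    3-point parabolic interpolation — sub-cycle accuracy from a trace
    sampled once per cycle.  Anchors whose apex does not rise ``min_snr``-
    fold above the trace median are reported as NaN (missing).

    Raises
    ------
    AlignmentError
        If fewer than two anchors are detected.
    """
    if scheme is None:
        raise ValueError("a WindowScheme is required to group scans by window")
    by_window: dict[int, list[MsmsScan]] = {}
    for s in scans:
        w = window_index_of(s.isolation_center, scheme)
        if w is not None:
            by_window.setdefault(w, []).append(s)

    apexes: dict[float, float] = {}
    n_found = 0
    for mz in anchors:
        w = window_index_of(mz, scheme)
        window_scans = by_window.get(w, []) if w is not None else []
        if not window_scans:
            apexes[mz] = float("nan")
            continue
        times = np.array([s.rt for s in window_scans])
        delta = mz * tol_ppm * 1e-6
        trace = np.empty(len(window_scans))
        for i, s in enumerate(window_scans):
            lo = np.searchsorted(s.mz_array, mz - delta, side="left")
            hi = np.searchsorted(s.mz_array, mz + delta, side="right")
            trace[i] = s.intensity_array[lo:hi].sum()
        order = np.argsort(times)
        times, trace = times[order], trace[order]
        if len(trace) >= 3:
            smooth = np.convolve(trace, np.ones(3) / 3.0, mode="same")
        else:
            smooth = trace
        peak = float(smooth.max())
        baseline = float(np.median(smooth))
        if peak <= 0 or (baseline > 0 and peak < min_snr * baseline):
            apexes[mz] = float("nan")
            logger.warning("anchor %.4f m/z: no signal above noise floor", mz)
            continue
        i = int(np.argmax(smooth))
        apex = times[i]
        if 0 < i < len(smooth) - 1:
            y0, y1, y2 = smooth[i - 1], smooth[i], smooth[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                shift = 0.5 * (y0 - y2) / denom
                shift = float(np.clip(shift, -0.5, 0.5))
                apex = apex + shift * (times[i + 1] - times[i - 1]) / 2.0
        apexes[mz] = float(apex)
        n_found += 1
    if n_found < 2:
        raise AlignmentError(
            f"only {n_found} anchor(s) detected; at least 2 are required "
            "for RT alignment"
        )
    return apexes


# ---------------------------------------------------------------------------
# RT mapping


@dataclass(frozen=True)
class RtMap:
    """Monotone piecewise-linear map from a run's RT to the reference RT.

    Linear extrapolation with the terminal segment slopes beyond the first
    and last anchors.  ``identity()`` maps every RT to itself (the
    reference run's own map).
    """

    run_times: np.ndarray
    ref_times: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "run_times", np.asarray(self.run_times, float))
        object.__setattr__(self, "ref_times", np.asarray(self.ref_times, float))
        if self.run_times.size != self.ref_times.size or self.run_times.size < 2:
            raise AlignmentError("an RT map needs >= 2 matched anchor pairs")
        if not (np.all(np.diff(self.run_times) > 0) and np.all(np.diff(self.ref_times) > 0)):
            raise AlignmentError(
                "anchor elution order is not strictly increasing in both runs"
            )

    @classmethod
    def identity(cls) -> "RtMap":
        return cls(np.array([0.0, 1.0]), np.array([0.0, 1.0]))

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.run_times, self.ref_times)

    def __call__(self, rt):
        rt = np.asarray(rt, dtype=float)
        x, y = self.run_times, self.ref_times
        out = np.interp(rt, x, y)
        lo_slope = (y[1] - y[0]) / (x[1] - x[0])
        hi_slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
        out = np.where(rt < x[0], y[0] + (rt - x[0]) * lo_slope, out)
        out = np.where(rt > x[-1], y[-1] + (rt - x[-1]) * hi_slope, out)
        return float(out) if out.ndim == 0 else out


def fit_rt_map(
    run_anchor_times: Mapping[float, float] | Sequence[float],
    reference_anchor_times: Mapping[float, float] | Sequence[float],
) -> RtMap:
    """Fit the piecewise-linear RT map through matched anchor pairs.

    Accepts either parallel sequences of times or two ``{anchor m/z:
    apex}`` dicts (anchors missing — NaN — in either run are dropped).
    Returns the identity map when the matched sequences are equal.
    """
    if isinstance(run_anchor_times, Mapping):
        keys = [
            k
            for k in run_anchor_times
            if k in reference_anchor_times
            and np.isfinite(run_anchor_times[k])
            and np.isfinite(reference_anchor_times[k])
        ]
        run_t = np.array([run_anchor_times[k] for k in keys])
        ref_t = np.array([reference_anchor_times[k] for k in keys])
    else:
        run_t = np.asarray(run_anchor_times, float)
        ref_t = np.asarray(reference_anchor_times, float)
        ok = np.isfinite(run_t) & np.isfinite(ref_t)
        run_t, ref_t = run_t[ok], ref_t[ok]
    if run_t.size < 2:
        raise AlignmentError(
            f"only {run_t.size} matched anchors; >= 2 required"
        )
    order = np.argsort(ref_t)
    run_t, ref_t = run_t[order], ref_t[order]
    if not np.all(np.diff(run_t) > 0):
        raise AlignmentError(
            "anchors elute in a different order in the two runs; "
            "monotone alignment impossible"
        )
    return RtMap(run_t, ref_t)


# ---------------------------------------------------------------------------
# dual indexing


def assign_did(
    scan: MsmsScan,
    rt_map: RtMap,
    scheme: WindowScheme,
    rt_bin_width: float | None = None,
) -> DualIndex | None:
    """Dual index of one scan in the reference frame, or None if unassignable.

    rt_bin = floor(mapped_rt / rt_bin_width) + 1 (1-based; bin width
    defaults to the cycle time so one bin spans one acquisition cycle);
    window_index comes from the scheme.  Scans outside the scheme or
    mapping to a negative reference RT are unassignable.
    """
    bw = scheme.cycle_time if rt_bin_width is None else rt_bin_width
    if bw <= 0:
        raise ValueError(f"rt_bin_width must be positive, got {bw}")
    w = window_index_of(scan.isolation_center, scheme)
    if w is None:
        return None
    mapped = rt_map(scan.rt)
    rt_bin = int(np.floor(mapped / bw)) + 1
    if rt_bin < 1:
        return None
    return DualIndex(rt_bin, w)


def feature_names(n_windows: int, n_rt_bins: int) -> list[str]:
    """Window-major dID feature names ``w<window>_t<bin>`` (both 1-based)."""
    return [f"w{w}_t{t}" for w in range(1, n_windows + 1) for t in range(1, n_rt_bins + 1)]


@dataclass
class ProteomeSignature:
    """Complete per-run grid of reporter intensities indexed by dID.

    ``values`` has shape (n_channels, n_rt_bins, n_windows); every scheduled
    grid cell exists and unobserved cells hold 0, so one TMT10 run yields
    exactly ten complete per-channel matrices.
    """

    run_id: str
    channels: tuple[str, ...]
    values: np.ndarray
    scheme: WindowScheme
    rt_bin_width: float
    observed: np.ndarray | None = None  # (n_rt_bins, n_windows) scan-received mask
    n_dropped_window: int = 0
    n_dropped_rt: int = 0
    n_collisions: int = 0

    @property
    def n_rt_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def channel_matrix(self, label: str) -> np.ndarray:
        """The (rt_bin × window) matrix of one channel."""
        return self.values[self.channels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        """Channels × dID-features table (window-major feature order)."""
        n_ch, n_t, n_w = self.values.shape
        flat = self.values.transpose(0, 2, 1).reshape(n_ch, n_w * n_t)
        return pd.DataFrame(
            flat,
            index=list(self.channels),
            columns=feature_names(n_w, n_t),
        )


def build_signature(
    scans: Sequence[MsmsScan],
    reporter_vectors: Sequence[ReporterVector],
    rt_map: RtMap,
    scheme: WindowScheme,
    *,
    rt_bin_width: float | None = None,
    n_rt_bins: int | None = None,
    collision: str = "keep_max",
    channels: ReporterChannelSet | None = None,
    phase_correct: bool = True,
) -> ProteomeSignature:
    """Classify every scan into the scheduled dID grid.

    ``n_rt_bins`` fixes the grid extent (normally derived from the
    reference run's aligned gradient span); scans mapping beyond it are
    dropped with a count.  When two scans collide on one dID the scan with
    the larger summed reporter intensity wins (``collision="keep_max"``) or
    their vectors are summed (``collision="sum"``).  ``phase_correct``
    anchors each scan at its acquisition-cycle midpoint before binning
    (see the inline note), which is what makes the RT bin behave as a
    cycle index.
    """
    if len(scans) != len(reporter_vectors):
        raise ValueError("scans and reporter vectors must be parallel sequences")
    if collision not in ("keep_max", "sum"):
        raise ValueError(f"unknown collision rule {collision!r}")
    bw = scheme.cycle_time if rt_bin_width is None else float(rt_bin_width)

    # The RT component of the dID is the acquisition cycle, but the scans of
    # one cycle carry staggered timestamps (each window is acquired at its
    # own dwell offset).  Floor-binning raw timestamps would place the
    # late-cycle windows right at bin boundaries, where sub-second alignment
    # residuals flip a whole window by one bin.  Reducing every scan to its
    # cycle midpoint — subtracting the per-window timestamp phase, constant
    # within a run — makes bins cut between cycles for every window alike,
    # tolerating residuals up to half a cycle.
    if phase_correct:
        phases: dict[int, float] = {}
        by_w: dict[int, list[float]] = {}
        for scan in scans:
            w = window_index_of(scan.isolation_center, scheme)
            if w is not None:
                by_w.setdefault(w, []).append(scan.rt % bw)
        for w, offs in by_w.items():
            phases[w] = float(np.median(offs))

    assigned: list[tuple[DualIndex, np.ndarray]] = []
    dropped_w = dropped_rt = 0
    for scan, vec in zip(scans, reporter_vectors):
        w = window_index_of(scan.isolation_center, scheme)
        if w is None:
            dropped_w += 1
            continue
        rt = scan.rt
        if phase_correct:
            rt = rt - phases[w] + bw / 2.0
        mapped = rt_map(rt)
        rt_bin = int(np.floor(mapped / bw)) + 1
        if rt_bin < 1:
            dropped_w += 1
            continue
        assigned.append((DualIndex(rt_bin, w), vec.intensities))

    if n_rt_bins is None:
        n_rt_bins = max((d.rt_bin for d, _ in assigned), default=1)

    n_ch = len(channels) if channels is not None else (
        len(assigned[0][1]) if assigned else 0
    )
    if n_ch == 0:
        raise ValueError("cannot infer channel count from zero admitted scans; "
                         "pass channels=")
    labels = tuple(channels.labels) if channels is not None else tuple(
        str(i) for i in range(1, n_ch + 1)
    )

    values = np.zeros((n_ch, n_rt_bins, scheme.n_windows))
    observed = np.zeros((n_rt_bins, scheme.n_windows), dtype=bool)
    best_total = np.full((n_rt_bins, scheme.n_windows), -1.0)
    collisions = 0
    for did, inten in assigned:
        t, w = did.rt_bin - 1, did.window_index - 1
        if t >= n_rt_bins:
            dropped_rt += 1
            continue
        total = float(inten.sum())
        observed[t, w] = True
        if best_total[t, w] >= 0:
            collisions += 1
            if collision == "sum":
                values[:, t, w] += inten
                best_total[t, w] += total
                continue
            if total <= best_total[t, w]:
                continue
        values[:, t, w] = inten
        best_total[t, w] = total

    run_id = scans[0].run_id if scans else ""
    if dropped_w or dropped_rt:
        logger.info(
            "run %s: %d scans unassignable to a window, %d beyond the "
            "reference gradient span",
            run_id, dropped_w, dropped_rt,
        )
    return ProteomeSignature(
        run_id=run_id,
        channels=labels,
        values=values,
        scheme=scheme,
        rt_bin_width=bw,
        observed=observed,
        n_dropped_window=dropped_w,
        n_dropped_rt=dropped_rt,
        n_collisions=collisions,
    )


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class AggregatedMatrix:
    """Samples × dID-features matrix from many runs; no missing entries.

    Rows are ``run_id:channel`` samples; ``meta`` carries per-sample
    metadata (run, channel, mix, input amount, batch, population) on the
    same index.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def missing_fraction(self) -> float:
        return float(self.data.isna().to_numpy().mean())

    def write_tsv(self, data_path, meta_path=None) -> None:
        self.data.to_csv(data_path, sep="\t", index_label="sample")
        if meta_path is not None:
            self.meta.to_csv(meta_path, sep="\t", index_label="sample")


def aggregate_runs(
    signatures: Sequence[ProteomeSignature],
    manifests: Mapping[str, RunManifest] | None = None,
    populations: Mapping[str, Mapping[str, str]] | None = None,
    *,
    features: str = "intersection",
) -> AggregatedMatrix:
    """Stack per-channel signature rows from many runs on a common dID grid.

    All signatures must share the window scheme, RT bin width and grid
    extent; the result then has Σ(plex sizes) sample rows, an identical
    feature column set for every row and zero missing entries.  With
    ``features="intersection"`` (default) only the dID cells that received
    an MS/MS scan in *every* run are kept — the near-complete overlap that
    prescheduled acquisition guarantees, minus the handful of cells a
    run's residual RT drift displaced; ``features="all"`` keeps the full
    scheduled grid (unobserved cells stay 0).
    ``populations`` optionally maps run_id → (channel → population label).
    Output row order is canonical (sorted by run_id, then channel order),
    so aggregation is invariant to the input order of the signatures.
    """
    if not signatures:
        raise AggregationError("no signatures to aggregate")
    if features not in ("intersection", "all"):
        raise ValueError(f"unknown feature rule {features!r}")
    ref = signatures[0]
    for sig in signatures[1:]:
        if sig.scheme.windows != ref.scheme.windows:
            raise AggregationError(
                f"run {sig.run_id}: window scheme differs from run {ref.run_id}"
            )
        if sig.rt_bin_width != ref.rt_bin_width or sig.n_rt_bins != ref.n_rt_bins:
            raise AggregationError(
                f"run {sig.run_id}: RT grid differs from run {ref.run_id}"
            )
    keep_cols: list[str] | None = None
    if features == "intersection" and all(s.observed is not None for s in signatures):
        mask = np.logical_and.reduce([s.observed for s in signatures])
        names = np.array(
            feature_names(ref.scheme.n_windows, ref.n_rt_bins)
        )
        flat = mask.T.reshape(-1)  # window-major, matching feature_names
        keep_cols = list(names[flat])
        if not keep_cols:
            raise AggregationError("no dID observed in every run")
    rows = []
    meta_rows = []
    for sig in sorted(signatures, key=lambda s: s.run_id):
        frame = sig.to_frame()
        if keep_cols is not None:
            frame = frame[keep_cols]
        man = manifests.get(sig.run_id) if manifests else None
        pops = populations.get(sig.run_id, {}) if populations else {}
        for ch in sig.channels:
            sample = f"{sig.run_id}:{ch}"
            rows.append(pd.Series(frame.loc[ch], name=sample))
            meta_rows.append(
                {
                    "sample": sample,
                    "run_id": sig.run_id,
                    "channel": ch,
                    "mix": man.mix if man else "",
                    "input_ng": man.input_ng if man else float("nan"),
                    "batch": man.batch if man else sig.run_id,
                    "plex": man.plex if man else len(sig.channels),
                    "population": pops.get(ch, ""),
                }
            )
    data = pd.DataFrame(rows)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return AggregatedMatrix(data=data, meta=meta)
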