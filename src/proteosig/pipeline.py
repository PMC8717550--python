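"""End-to-end convenience pipeline: scans → signatures → aggregated matrix.

Glue over the stage modules: reporter extraction, anchor detection,
RT-map fitting against the first run (the reference), dual indexing on the
reference grid and aggregation with design metadata attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .acquisition import WindowScheme
from .alignment import (
    DEFAULT_ANCHOR_MZ,
    AggregatedMatrix,
    ProteomeSignature,
    RtMap,
    aggregate_runs,
    build_signature,
    detect_anchor_elution,
    fit_rt_map,
)
from .reporter_quant import ReporterChannelSet, extract_reporters
from .spectra_io import MsmsScan, RunManifest
from .synthetic import Experiment, MixDesign

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "process_runs", "process_experiment"]


@dataclass
class PipelineResult:
    """Aggregated matrix plus per-run alignment diagnostics."""

    aggregated: AggregatedMatrix
    signatures: dict[str, ProteomeSignature]
    rt_maps: dict[str, RtMap]
    anchor_times: dict[str, dict[float, float]]
    reference_run_id: str


def process_runs(
    runs: Sequence[tuple[RunManifest, Sequence[MsmsScan]]],
    scheme: WindowScheme,
    designs: Mapping[str, MixDesign] | None = None,
    *,
    anchors: Sequence[float] = DEFAULT_ANCHOR_MZ,
    rt_bin_width: float | None = None,
    collision: str = "keep_max",
    tol_ppm: float = 10.0,
) -> PipelineResult:
    """Run the signature pipeline over a set of runs.

    The first run is the alignment reference: its detected anchor apexes
    define the reference RT frame, and its aligned gradient span fixes the
    RT-bin extent of the common dID grid.
    """
    if not runs:
        raise ValueError("no runs to process")
    ref_id = runs[0][0].run_id
    bw = scheme.cycle_time if rt_bin_width is None else rt_bin_width

    anchor_times: dict[str, dict[float, float]] = {}
    vectors = {}
    ms2_scans = {}
    for manifest, scans in runs:
        ms2 = [s for s in scans if s.ms_level == 2]
        channels = ReporterChannelSet.from_name(f"tmt{manifest.plex}")
        vectors[manifest.run_id] = (
            channels,
            [extract_reporters(s, channels, tol_ppm) for s in ms2],
        )
        ms2_scans[manifest.run_id] = ms2
        anchor_times[manifest.run_id] = detect_anchor_elution(
            ms2, anchors, scheme, tol_ppm=tol_ppm
        )

    ref_anchor = anchor_times[ref_id]
    rt_maps = {
        rid: (RtMap.identity() if rid == ref_id else fit_rt_map(times, ref_anchor))
        for rid, times in anchor_times.items()
    }

    # reference grid extent from the reference run's own gradient span
    channels, ref_vecs = vectors[ref_id]
    ref_sig = build_signature(
        ms2_scans[ref_id], ref_vecs, rt_maps[ref_id], scheme,
        rt_bin_width=bw, collision=collision, channels=channels,
    )
    n_bins = ref_sig.n_rt_bins

    signatures: dict[str, ProteomeSignature] = {ref_id: ref_sig}
    for manifest, _ in runs:
        rid = manifest.run_id
        if rid == ref_id:
            continue
        channels, vecs = vectors[rid]
        signatures[rid] = build_signature(
            ms2_scans[rid], vecs, rt_maps[rid], scheme,
            rt_bin_width=bw, n_rt_bins=n_bins,
            collision=collision, channels=channels,
        )

    manifest_map = {m.run_id: m for m, _ in runs}
    populations = (
        {rid: d.assignment for rid, d in designs.items()} if designs else None
    )
    aggregated = aggregate_runs(
        list(signatures.values()), manifest_map, populations
    )
    return PipelineResult(
        aggregated=aggregated,
        signatures=signatures,
        rt_maps=rt_maps,
        anchor_times=anchor_times,
        reference_run_id=ref_id,
    )


def process_experiment(exp: Experiment, **kwargs) -> PipelineResult:
    """Apply :func:`process_runs` to a simulated experiment."""
    runs = [(m, exp.scans[m.run_id]) for m in exp.manifests]
    return process_runs(runs, exp.scheme, exp.designs, **kwargs)


def signature_pca(
    aggregated: AggregatedMatrix,
    *,
    batch_correct: bool = True,
    pseudocount: float = 1.0,
):
    """Standard clustering flow for an aggregated signature matrix.

    Scale samples to equal total signal, log10(x + 1), remove per-run
    (batch) effects with the empirical-Bayes model, then exact PCA.  Every
    multiplexed run carries all populations, so removing per-batch feature
    means leaves the biological contrast intact while stripping the
    run-to-run axis.  Returns the :class:`~proteosig.analysis.PcaResult`.
    """
    from .analysis import pca
    from .normalize import eb_batch_correct, log10_transform, scale_equal_channel_signal

    scaled, _ = scale_equal_channel_signal(aggregated)
    log_matrix = log10_transform(scaled, pseudocount)
    if batch_correct:
        log_matrix = eb_batch_correct(log_matrix, aggregated.meta["batch"])
    return pca(log_matrix, log_transform=False)
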