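"""RT alignment, dual indexing, signature grids and aggregation."""

import numpy as np
import pytest

from proteosig import (
    AggregationError,
    AlignmentError,
    DEFAULT_ANCHOR_MZ,
    MixDesign,
    MsmsScan,
    ReporterChannelSet,
    ReporterVector,
    RtMap,
    RtWarp,
    aggregate_runs,
    assign_did,
    build_signature,
    detect_anchor_elution,
    extract_reporters,
    fit_rt_map,
    simulate_run,
    window_index_of,
)


# --------------------------------------------------------------------------
# RT maps


def test_identity_map():
    m = fit_rt_map([10.0, 50.0], [10.0, 50.0])
    assert m(33.3) == pytest.approx(33.3)
    assert RtMap.identity()(123.4) == pytest.approx(123.4)


def test_linear_interpolation_example():
    m = fit_rt_map([100.0, 200.0], [50.0, 100.0])
    assert m(150.0) == pytest.approx(75.0)


def test_constant_offset_recovered_exactly():
    ref = np.array([50.0, 120.0, 260.0])
    m = fit_rt_map(ref + 30.0, ref)
    for rt in (60.0, 140.0, 250.0, 10.0, 320.0):  # incl. extrapolation
        assert m(rt) == pytest.approx(rt - 30.0, abs=1e-9)


def test_map_matches_direct_piecewise_evaluation():
    """Oracle: manual segment-by-segment linear evaluation."""
    run_t = np.array([40.0, 90.0, 160.0, 300.0])
    ref_t = np.array([35.0, 95.0, 150.0, 310.0])
    m = fit_rt_map(run_t, ref_t)
    rng = np.random.default_rng(3)
    for rt in rng.uniform(0.0, 340.0, size=40):
        if rt <= run_t[0]:
            k = 0
        elif rt >= run_t[-1]:
            k = len(run_t) - 2
        else:
            k = int(np.searchsorted(run_t, rt) - 1)
        slope = (ref_t[k + 1] - ref_t[k]) / (run_t[k + 1] - run_t[k])
        expected = ref_t[k] + (rt - run_t[k]) * slope
        assert m(rt) == pytest.approx(expected, abs=1e-9)


def test_map_drops_missing_anchors_and_validates():
    run = {1.0: 10.0, 2.0: float("nan"), 3.0: 30.0}
    ref = {1.0: 12.0, 2.0: 20.0, 3.0: 33.0}
    m = fit_rt_map(run, ref)
    assert m.run_times.size == 2
    with pytest.raises(AlignmentError, match="matched anchors"):
        fit_rt_map({1.0: 10.0}, {1.0: 10.0})
    with pytest.raises(AlignmentError, match="different order"):
        fit_rt_map([10.0, 5.0], [10.0, 20.0])


# --------------------------------------------------------------------------
# anchors


def _trace_scans(scheme, anchor_mz, apexes, n_cycles=50, height=1e5):
    """Per-window scans carrying Gaussian traces at the given apexes."""
    by_window = {}
    for amz, apex in zip(anchor_mz, apexes):
        w = window_index_of(amz, scheme)
        by_window.setdefault(w, []).append((amz, apex))
    scans = []
    number = 0
    for c in range(n_cycles):
        rt = c * scheme.cycle_time
        for w, members in sorted(by_window.items()):
            number += 1
            lo, hi = scheme.windows[w - 1]
            mz = np.array([m for m, _ in members])
            inten = np.array(
                [height * np.exp(-0.5 * ((rt - apex) / 3.4) ** 2) + 1.0
                 for _, apex in members]
            )
            order = np.argsort(mz)
            scans.append(
                MsmsScan("r", number, rt, (lo + hi) / 2, scheme.width,
                         mz[order], inten[order])
            )
    return scans


def test_anchor_apex_recovered_within_half_cycle(scheme):
    scans = _trace_scans(scheme, [466.7743, 660.3674], [300.0, 150.0])
    times = detect_anchor_elution(scans, [466.7743, 660.3674, 706.4723], scheme)
    assert times[466.7743] == pytest.approx(300.0, abs=scheme.cycle_time / 2)
    assert times[660.3674] == pytest.approx(150.0, abs=scheme.cycle_time / 2)
    assert np.isnan(times[706.4723])  # no signal: flagged missing


def test_two_anchors_sharing_a_window(scheme):
    """587.3539 and 587.864 co-isolate in one window but trace separately."""
    assert window_index_of(587.3539, scheme) == window_index_of(587.864, scheme)
    scans = _trace_scans(scheme, [587.3539, 587.864], [120.0, 250.0])
    times = detect_anchor_elution(scans, [587.3539, 587.864], scheme)
    assert times[587.3539] == pytest.approx(120.0, abs=scheme.cycle_time / 2)
    assert times[587.864] == pytest.approx(250.0, abs=scheme.cycle_time / 2)


def test_no_anchor_signal_is_alignment_impossible(scheme, small_truth):
    scans = simulate_run(
        small_truth, MixDesign.mix1(), scheme, gradient=80.0, seed=5,
        run_id="r", include_anchors=False,
    )
    ms2 = [s for s in scans if s.ms_level == 2]
    with pytest.raises(AlignmentError, match="at least 2"):
        detect_anchor_elution(ms2, DEFAULT_ANCHOR_MZ, scheme)


def test_warp_recovery_on_simulated_run(scheme, small_truth):
    """Post-alignment anchor residuals stay below half an RT bin."""
    rng = np.random.default_rng(21)
    warp = RtWarp.random(rng)
    run = simulate_run(
        small_truth, MixDesign.mix1(), scheme, gradient=80.0,
        rt_warp=warp, seed=6, run_id="warped",
    )
    ref = simulate_run(
        small_truth, MixDesign.mix1(), scheme, gradient=80.0, seed=7, run_id="ref"
    )
    anchors = [mz for mz in DEFAULT_ANCHOR_MZ]
    t_run = detect_anchor_elution([s for s in run if s.ms_level == 2], anchors, scheme)
    t_ref = detect_anchor_elution([s for s in ref if s.ms_level == 2], anchors, scheme)
    m = fit_rt_map(t_run, t_ref)
    for mz in anchors:
        if np.isfinite(t_run[mz]) and np.isfinite(t_ref[mz]):
            assert abs(m(t_run[mz]) - t_ref[mz]) < scheme.cycle_time / 2


# --------------------------------------------------------------------------
# dual indexing


def _ms2(rt, center, scheme):
    return MsmsScan("r", 1, rt, center, scheme.width, np.array([]), np.array([]))


def test_assign_did_examples(scheme):
    ident = RtMap.identity()
    assert assign_did(_ms2(0.0, 403.0, scheme), ident, scheme) == (1, 1)
    assert assign_did(_ms2(83.0, 403.0, scheme), ident, scheme, 8.0).rt_bin == 11
    assert assign_did(_ms2(10.0, 250.0, scheme), ident, scheme) is None
    with pytest.raises(ValueError, match="rt_bin_width"):
        assign_did(_ms2(0.0, 403.0, scheme), ident, scheme, 0.0)


def test_all_window_indices_in_range(scheme, small_run):
    ident = RtMap.identity()
    for s in small_run:
        if s.ms_level != 2:
            continue
        did = assign_did(s, ident, scheme)
        assert did is not None and 1 <= did.window_index <= 80


# --------------------------------------------------------------------------
# signatures


def _vec(intensities):
    return ReporterVector("r", 1, np.asarray(intensities, dtype=float))


def test_tmt10_run_yields_ten_complete_matrices(scheme, small_run, tmt10):
    ms2 = [s for s in small_run if s.ms_level == 2]
    vecs = [extract_reporters(s, tmt10) for s in ms2]
    sig = build_signature(ms2, vecs, RtMap.identity(), scheme, channels=tmt10)
    assert sig.n_channels == 10
    assert sig.values.shape == (10, sig.n_rt_bins, 80)
    assert np.isfinite(sig.values).all()
    # dID uniqueness: the grid itself is the index, one cell per dID
    frame = sig.to_frame()
    assert not frame.columns.duplicated().any()
    assert frame.shape == (10, sig.n_rt_bins * 80)


def test_zero_admitted_scans_gives_all_zero_grid(scheme, tmt10):
    scans = [_ms2(5.0, 250.0, scheme)]  # unassignable
    sig = build_signature(
        scans, [_vec(np.ones(10))], RtMap.identity(), scheme,
        n_rt_bins=4, channels=tmt10,
    )
    assert sig.values.shape == (10, 4, 80)
    assert not sig.values.any()
    assert sig.n_dropped_window == 1


def test_collision_keeps_higher_signal_scan(scheme, tmt10):
    s1 = _ms2(1.0, 403.0, scheme)
    s2 = _ms2(2.0, 403.0, scheme)  # same bin (width 8 s), same window
    weak, strong = _vec([1.0] * 10), _vec([50.0] * 10)
    sig = build_signature(
        [s1, s2], [weak, strong], RtMap.identity(), scheme,
        n_rt_bins=1, channels=tmt10, phase_correct=False,
    )
    np.testing.assert_allclose(sig.values[:, 0, 0], 50.0)
    assert sig.n_collisions == 1
    summed = build_signature(
        [s1, s2], [weak, strong], RtMap.identity(), scheme,
        n_rt_bins=1, channels=tmt10, collision="sum", phase_correct=False,
    )
    np.testing.assert_allclose(summed.values[:, 0, 0], 51.0)


# --------------------------------------------------------------------------
# aggregation


def _small_signatures(scheme, tmt10, n_runs, seed=31):
    from proteosig import generate_truth

    truth = generate_truth(n_peptides=40, n_proteins=8, seed=seed, gradient=80.0)
    sigs = []
    n_bins = None
    for i in range(n_runs):
        scans = simulate_run(
            truth, MixDesign.mix1(), scheme, gradient=80.0, seed=seed + i,
            run_id=f"run{i:02d}",
        )
        ms2 = [s for s in scans if s.ms_level == 2]
        vecs = [extract_reporters(s, tmt10) for s in ms2]
        sig = build_signature(
            ms2, vecs, RtMap.identity(), scheme, n_rt_bins=n_bins, channels=tmt10
        )
        n_bins = sig.n_rt_bins
        sigs.append(sig)
    return sigs


def test_aggregate_row_counts_and_completeness(scheme, tmt10):
    sigs = _small_signatures(scheme, tmt10, 3)
    agg = aggregate_runs(sigs)
    assert agg.n_samples == 30
    assert agg.missing_fraction == 0.0
    assert not agg.data.isna().any().any()


def test_single_run_aggregation_is_identity(scheme, tmt10):
    sigs = _small_signatures(scheme, tmt10, 1)
    agg = aggregate_runs(sigs, features="all")
    frame = sigs[0].to_frame()
    assert agg.data.shape == (10, frame.shape[1])
    np.testing.assert_allclose(agg.data.to_numpy(), frame.to_numpy())


def test_aggregation_is_permutation_invariant(scheme, tmt10):
    sigs = _small_signatures(scheme, tmt10, 3)
    a = aggregate_runs(sigs)
    b = aggregate_runs(list(reversed(sigs)))
    assert list(a.data.index) == list(b.data.index)
    np.testing.assert_allclose(a.data.to_numpy(), b.data.to_numpy())


def test_mismatched_grids_refuse_to_aggregate(scheme, tmt10):
    from proteosig import build_window_scheme

    sigs = _small_signatures(scheme, tmt10, 2)
    other_scheme = build_window_scheme(400.0, 800.0, 5.0, 0.0, 8.0)
    sigs2 = _small_signatures(other_scheme, tmt10, 1)
    with pytest.raises(AggregationError, match="scheme differs"):
        aggregate_runs([sigs[0], sigs2[0]])
    with pytest.raises(AggregationError, match="no signatures"):
        aggregate_runs([])
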