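"""Ground-truthed DIA-TMT run simulator.

Generates multiplexed small-window DIA runs with known composition so that
every pipeline stage can be tested end to end: Gaussian elution peaks
(FWHM ≈ 8 s), an 80-window 400–800 m/z cycle, TMT10/11 reporter patterns
under the benchmark mix designs, monotone inter-run RT warps, dilution
scaling (0.5–10 ng) and multiplicative plus background noise.  Anchor
precursors at the seven standard m/z values are always included so runs
stay alignable.  Co-isolation is emergent — any peptides sharing a window
and an elution time contribute to the same scans — not scripted.

The noise model is deliberately simple (per-peak log-normal with a
configurable CV plus an additive reporter noise floor); it reproduces the
qualitative behaviour of diluted reporter data without modelling ion
statistics, isotope envelopes or FAIMS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import WindowScheme, build_window_scheme, windows_containing, window_index_of
from .alignment import DEFAULT_ANCHOR_MZ
from .reporter_quant import ReporterChannelSet
from .spectra_io import MsmsScan, RunManifest, write_manifest, write_mzml

__all__ = [
    "MixDesign",
    "GroundTruth",
    "RtWarp",
    "NoiseParams",
    "generate_truth",
    "simulate_run",
    "emit_experiment",
    "Experiment",
    "PRESETS",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# designs


@dataclass(frozen=True)
class MixDesign:
    """Channel → biological-population assignment of one multiplexed run."""

    name: str
    plex: str  # "tmt10" | "tmt11"
    assignment: dict[str, str]
    input_ng: float

    def __post_init__(self) -> None:
        channels = ReporterChannelSet.from_name(self.plex)
        missing = [c for c in channels.labels if c not in self.assignment]
        if missing:
            raise ValueError(f"design {self.name}: unassigned channels {missing}")

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.assignment.values()))

    @classmethod
    def mix1(cls, input_ng: float = 10.0) -> "MixDesign":
        a = {c: "K562" for c in ("126", "127N", "127C", "128N", "128C")}
        a.update({c: "HeLa" for c in ("129N", "129C", "130N", "130C", "131")})
        return cls("mix1", "tmt10", a, input_ng)

    @classmethod
    def mix2(cls, input_ng: float = 10.0) -> "MixDesign":
        inv = {
            ch: ("HeLa" if pop == "K562" else "K562")
            for ch, pop in cls.mix1().assignment.items()
        }
        return cls("mix2", "tmt10", inv, input_ng)

    @classmethod
    def mix3(cls, input_ng: float = 10.0) -> "MixDesign":
        a = {c: "K562" for c in ("126", "127C", "128C", "129C", "130C")}
        a.update({c: "HeLa" for c in ("127N", "128N", "129N", "130N", "131")})
        return cls("mix3", "tmt10", a, input_ng)

    @classmethod
    def tko11(cls, input_ng: float = 10.0) -> "MixDesign":
        """TMT11 yeast knockout standard layout (WT + met6/his4/ura2)."""
        a = {c: "his4" for c in ("126", "127N", "127C")}
        a.update({c: "met6" for c in ("128N", "128C", "129N")})
        a.update({c: "ura2" for c in ("129C", "130N", "130C")})
        a.update({c: "WT" for c in ("131N", "131C")})
        return cls("tko11", "tmt11", a, input_ng)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Known composition of a simulated sample set.

    ``peptides`` columns: peptide, protein, mz (2+ precursor), rt_apex
    (reference-frame seconds), fwhm (s), is_anchor.  ``abundance`` holds
    the linear per-population abundance of every peptide at the nominal
    10-ng input.
    """

    peptides: pd.DataFrame
    abundance: pd.DataFrame  # index: peptide, columns: populations
    populations: tuple[str, ...]
    knockouts: dict[str, str]  # protein -> population with abundance 0
    gradient: float
    seed: int

    def knockout_features(
        self,
        protein: str,
        scheme: WindowScheme,
        rt_bin_width: float | None = None,
        bin_slack: int = 1,
    ) -> set[str]:
        """dID feature names where the protein's peptides land (±bin_slack)."""
        bw = scheme.cycle_time if rt_bin_width is None else rt_bin_width
        rows = self.peptides[self.peptides["protein"] == protein]
        feats: set[str] = set()
        for row in rows.itertuples():
            wins = set(windows_containing(row.mz, scheme))
            w0 = window_index_of(row.mz, scheme)
            if w0 is not None:
                wins.add(w0)
            t0 = int(np.floor(row.rt_apex / bw)) + 1
            for w in wins:
                for dt in range(-bin_slack, bin_slack + 1):
                    if t0 + dt >= 1:
                        feats.add(f"w{w}_t{t0 + dt}")
        return feats

    def write_tsv(self, peptide_path, abundance_path) -> None:
        self.peptides.to_csv(peptide_path, sep="\t", index=False)
        self.abundance.to_csv(abundance_path, sep="\t", index_label="peptide")


def generate_truth(
    n_peptides: int = 300,
    n_proteins: int = 60,
    populations: tuple[str, ...] = ("K562", "HeLa"),
    knockout_spec: dict[str, str] | None = None,
    fc_sigma: float = 1.0,
    seed: int = 0,
    *,
    gradient: float = 320.0,
    fwhm: float = 8.0,
    mz_range: tuple[float, float] = (400.0, 800.0),
    base_log10_mean: float = 4.5,
    base_log10_sd: float = 0.5,
    anchor_mz: tuple[float, ...] = DEFAULT_ANCHOR_MZ,
    anchor_log10: float = 5.5,
) -> GroundTruth:
    """Draw a ground-truth proteome for a set of populations.

    Base abundances are log-normal; per-protein population fold changes
    are 2**N(0, fc_sigma) relative to the first population; knockout
    proteins are zeroed in their strain.  Precursor m/z is uniform over
    the scheduled range (notional charge 2), apexes are spread over the
    central 90% of the gradient, and the anchor precursors are appended
    with population-independent abundance.
    """
    if n_peptides < len(populations):
        raise ValueError("need at least one peptide per population")
    knockout_spec = dict(knockout_spec or {})
    rng = np.random.default_rng(seed)

    protein_names = [f"prot_{i:03d}" for i in range(n_proteins)]
    for i, ko in enumerate(knockout_spec):
        if i >= n_proteins:
            raise ValueError("more knockout proteins than proteins")
        protein_names[i] = ko
    unknown = [p for p in knockout_spec if p not in protein_names]
    if unknown:
        raise ValueError(f"knockout protein(s) not in proteome: {unknown}")
    bad_pop = {p: q for p, q in knockout_spec.items() if q not in populations}
    if bad_pop:
        raise ValueError(f"knockout population(s) unknown: {bad_pop}")

    peptides = [f"pep_{i:04d}" for i in range(n_peptides)]
    proteins = [protein_names[i % n_proteins] for i in range(n_peptides)]
    mz = rng.uniform(*mz_range, size=n_peptides)
    apex = rng.uniform(0.05 * gradient, 0.95 * gradient, size=n_peptides)
    base = 10.0 ** rng.normal(base_log10_mean, base_log10_sd, size=n_peptides)

    # per-protein log2 fold change of each non-reference population
    fc = {populations[0]: {p: 0.0 for p in protein_names}}
    for pop in populations[1:]:
        fc[pop] = {
            p: float(rng.normal(0.0, fc_sigma)) if fc_sigma > 0 else 0.0
            for p in protein_names
        }

    ab = {}
    for pop in populations:
        col = base * np.array([2.0 ** fc[pop][p] for p in proteins])
        for ko_protein, ko_pop in knockout_spec.items():
            if ko_pop == pop:
                col = np.where(np.array(proteins) == ko_protein, 0.0, col)
        ab[pop] = col

    pep_df = pd.DataFrame(
        {
            "peptide": peptides,
            "protein": proteins,
            "mz": mz,
            "rt_apex": apex,
            "fwhm": fwhm,
            "is_anchor": False,
        }
    )
    ab_df = pd.DataFrame(ab, index=peptides)

    # anchors: ubiquitous, equal across populations, evenly spread apexes
    n_anchor = len(anchor_mz)
    anchor_rows = pd.DataFrame(
        {
            "peptide": [f"anchor_{i+1}" for i in range(n_anchor)],
            "protein": "ANCHOR",
            "mz": list(anchor_mz),
            "rt_apex": np.linspace(0.08, 0.92, n_anchor) * gradient,
            "fwhm": fwhm,
            "is_anchor": True,
        }
    )
    anchor_ab = pd.DataFrame(
        {pop: 10.0 ** anchor_log10 for pop in populations},
        index=anchor_rows["peptide"],
    )
    return GroundTruth(
        peptides=pd.concat([pep_df, anchor_rows], ignore_index=True),
        abundance=pd.concat([ab_df, anchor_ab]),
        populations=tuple(populations),
        knockouts=knockout_spec,
        gradient=float(gradient),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# run simulation


@dataclass(frozen=True)
class RtWarp:
    """Monotone RT distortion: offset + slope·t + amp·sin(2πt/period)."""

    slope: float = 1.0
    offset: float = 0.0
    amp: float = 0.0
    period: float = 120.0

    def __post_init__(self) -> None:
        if self.slope <= self.amp * 2.0 * math.pi / self.period:
            raise ValueError("warp parameters violate monotonicity")

    def __call__(self, t):
        return self.offset + self.slope * np.asarray(t) + self.amp * np.sin(
            2.0 * math.pi * np.asarray(t) / self.period
        )

    @classmethod
    def random(cls, rng: np.random.Generator) -> "RtWarp":
        """Replicate-series drift, scaled to the short test gradient.

        Back-to-back technical replicates on one column drift by a small
        fraction of an acquisition cycle per cycle; on this gradient that
        means sub-percent slope deviations, a couple of seconds of offset
        and a sub-second nonlinear residual.  Keeping the drift *in cycle
        units* comparable to a well-behaved replicate series matters: a
        short gradient with percent-level slope error would skip whole RT
        bins, an artifact of the scale-down rather than of the method.
        """
        return cls(
            slope=float(rng.uniform(0.995, 1.005)),
            offset=float(rng.uniform(-2.0, 2.0)),
            amp=float(rng.uniform(0.0, 0.2)),
            period=float(rng.uniform(90.0, 150.0)),
        )


@dataclass(frozen=True)
class NoiseParams:
    """Simulator noise: multiplicative CV, additive reporter floor, clutter."""

    cv: float = 0.15
    floor: float = 30.0
    background_peaks: int = 3
    mz_jitter_ppm: float = 3.0
    residual_precursor_fraction: float = 0.3


def _merge_peaks(mz: np.ndarray, inten: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if mz.size == 0:
        return mz, inten
    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]
    uniq, inverse = np.unique(mz, return_inverse=True)
    if uniq.size == mz.size:
        return mz, inten
    return uniq, np.bincount(inverse, weights=inten)


def simulate_run(
    truth: GroundTruth,
    design: MixDesign,
    scheme: WindowScheme,
    *,
    gradient: float | None = None,
    rt_warp: RtWarp | None = None,
    noise: NoiseParams = NoiseParams(),
    dilution_ng: float = 10.0,
    seed: int = 0,
    run_id: str = "run",
    include_anchors: bool = True,
    include_ms1: bool = True,
    out_path: str | Path | None = None,
) -> list[MsmsScan]:
    """Simulate one multiplexed DIA run as an ordered scan list.

    Every cycle emits one MS/MS scan per scheme window (plus an optional
    MS1 at the cycle start); a scan's reporter intensities sum the
    contributions of all co-isolated peptides (channel abundance ×
    Gaussian elution factor × dilution scale × log-normal noise) on top of
    a background reporter floor, and each contributing peptide leaves a
    residual precursor peak that alignment can trace.  ``rt_warp`` maps
    reference-frame apex times into this run's clock.
    """
    if dilution_ng <= 0:
        raise ValueError(f"dilution_ng must be positive, got {dilution_ng}")
    warp = rt_warp or RtWarp()
    rng = np.random.default_rng(seed)
    channels = ReporterChannelSet.from_name(design.plex)
    n_ch = len(channels)
    gradient = truth.gradient if gradient is None else gradient
    ct = scheme.cycle_time
    n_w = scheme.n_windows
    dwell = ct / (n_w + 1)
    n_cycles = int(round(gradient / ct))
    scale = dilution_ng / 10.0
    s_ln = math.sqrt(math.log(1.0 + noise.cv**2)) if noise.cv > 0 else 0.0

    pop_of = [design.assignment[c] for c in channels.labels]
    rep = np.zeros((n_cycles, n_w, n_ch))
    prec_peaks: dict[tuple[int, int], list[tuple[float, float]]] = {}

    peptides = truth.peptides
    if not include_anchors:
        peptides = peptides[~peptides["is_anchor"]]
    for row in peptides.itertuples():
        wins = windows_containing(row.mz, scheme)
        if row.is_anchor and not wins:
            raise ValueError(
                f"anchor {row.mz:.4f} m/z falls outside the window scheme"
            )
        if not wins:
            continue
        ab = truth.abundance.loc[row.peptide, list(pop_of)].to_numpy(dtype=float)
        if ab.sum() == 0 and not row.is_anchor:
            # knocked out everywhere: nothing to emit
            if not np.any(ab > 0):
                continue
        apex = float(warp(row.rt_apex))
        sigma = row.fwhm / _FWHM_TO_SIGMA
        for w in wins:
            t_off = w * dwell
            c_lo = max(0, int(math.floor((apex - 4 * sigma - t_off) / ct)))
            c_hi = min(n_cycles - 1, int(math.ceil((apex + 4 * sigma - t_off) / ct)))
            if c_hi < c_lo:
                continue
            cycles = np.arange(c_lo, c_hi + 1)
            t = cycles * ct + t_off
            g = np.exp(-0.5 * ((t - apex) / sigma) ** 2)
            contrib = scale * np.outer(g, ab)
            if s_ln > 0:
                contrib = contrib * rng.lognormal(0.0, s_ln, size=contrib.shape)
            rep[cycles, w - 1, :] += contrib
            prec = noise.residual_precursor_fraction * contrib.sum(axis=1)
            for c, val in zip(cycles, prec):
                if val > 0:
                    prec_peaks.setdefault((int(c), w), []).append((row.mz, val))

    theo_mz = np.array(channels.mz)
    scans: list[MsmsScan] = []
    scan_number = 0
    for c in range(n_cycles):
        if include_ms1:
            scan_number += 1
            ms1_mz = np.sort(rng.uniform(*scheme.precursor_range, size=5))
            scans.append(
                MsmsScan(
                    run_id=run_id,
                    scan_number=scan_number,
                    rt=c * ct,
                    isolation_center=0.0,
                    isolation_width=0.0,
                    mz_array=ms1_mz,
                    intensity_array=rng.uniform(10.0, 100.0, size=5),
                    ms_level=1,
                )
            )
        for w in range(1, n_w + 1):
            scan_number += 1
            rt = c * ct + w * dwell
            intens = rep[c, w - 1].copy()
            if noise.floor > 0:
                # background reporter signal is sample-derived (co-isolated
                # labelled ions), so it scales with the loaded amount
                intens = intens + noise.floor * scale * rng.lognormal(0.0, 0.4, size=n_ch)
            keep = intens > 0
            jitter = rng.uniform(
                -noise.mz_jitter_ppm, noise.mz_jitter_ppm, size=n_ch
            )
            mz_list = [theo_mz[keep] * (1.0 + jitter[keep] * 1e-6)]
            int_list = [intens[keep]]
            for pmz, pint in prec_peaks.get((c, w), ()):
                mz_list.append(np.array([pmz]))
                int_list.append(np.array([pint]))
            if noise.background_peaks > 0 and noise.floor > 0:
                bg_mz = rng.uniform(200.0, 1200.0, size=noise.background_peaks)
                bg_mz = np.where(bg_mz < 135.0, bg_mz + 135.0, bg_mz)
                mz_list.append(bg_mz)
                int_list.append(
                    noise.floor * scale
                    * rng.lognormal(0.0, 0.6, size=noise.background_peaks)
                )
            mz_all = np.concatenate(mz_list) if mz_list else np.empty(0)
            int_all = np.concatenate(int_list) if int_list else np.empty(0)
            mz_all, int_all = _merge_peaks(mz_all, int_all)
            lo, hi = scheme.windows[w - 1]
            scans.append(
                MsmsScan(
                    run_id=run_id,
                    scan_number=scan_number,
                    rt=rt,
                    isolation_center=(lo + hi) / 2.0,
                    isolation_width=scheme.width,
                    mz_array=mz_all,
                    intensity_array=int_all,
                )
            )
    if out_path is not None:
        write_mzml(scans, out_path, run_id=run_id)
    return scans


# ---------------------------------------------------------------------------
# experiment presets


@dataclass
class Experiment:
    """A simulated cohort: runs, per-run designs, manifests and ground truth."""

    preset: str
    scheme: WindowScheme
    manifests: list[RunManifest]
    scans: dict[str, list[MsmsScan]]
    designs: dict[str, MixDesign]
    truths: dict[str, GroundTruth]
    seed: int

    @property
    def n_samples(self) -> int:
        return sum(m.plex for m in self.manifests)


PRESETS = ("helakq562_12runs", "tko11_4runs", "combined_16runs")

_INPUT_SERIES = (0.5, 1.0, 5.0, 10.0)


def _human_truth(seed: int, gradient: float, n_peptides: int, n_proteins: int) -> GroundTruth:
    return generate_truth(
        n_peptides=n_peptides,
        n_proteins=n_proteins,
        populations=("K562", "HeLa"),
        fc_sigma=1.0,
        seed=seed,
        gradient=gradient,
    )


def _yeast_truth(seed: int, gradient: float, n_peptides: int, n_proteins: int) -> GroundTruth:
    return generate_truth(
        n_peptides=n_peptides,
        n_proteins=n_proteins,
        populations=("WT", "met6", "his4", "ura2"),
        knockout_spec={"met6": "met6", "his4": "his4", "ura2": "ura2"},
        fc_sigma=0.0,
        seed=seed,
        gradient=gradient,
    )


def emit_experiment(
    preset: str,
    seed: int = 0,
    *,
    gradient: float = 320.0,
    n_peptides: int = 1500,
    n_proteins: int = 300,
    noise: NoiseParams = NoiseParams(),
    scheme: WindowScheme | None = None,
    out_dir: str | Path | None = None,
) -> Experiment:
    """Simulate one of the benchmark cohort shapes.

    * ``helakq562_12runs`` — 12 TMT10 runs: 3 label-swap mixes × 4 peptide
      inputs (0.5/1/5/10 ng) of two human cell lines → 120 samples.
    * ``tko11_4runs`` — 4 TMT11 runs of the yeast knockout standard at the
      4 inputs → 44 samples.
    * ``combined_16runs`` — both cohorts on the same scheme → 164 samples.

    The first run of a preset carries the identity RT warp and serves as
    the alignment reference; later runs get random monotone warps.  With
    ``out_dir`` set, mzML files, a manifest TSV and truth tables are
    written there.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    scheme = scheme or build_window_scheme(400.0, 800.0, 6.0, 1.0, 8.0)
    rng = np.random.default_rng(seed)

    truths: dict[str, GroundTruth] = {}
    plan: list[tuple[str, str, MixDesign]] = []  # (run_id, truth key, design)
    if preset in ("helakq562_12runs", "combined_16runs"):
        truths["human"] = _human_truth(seed, gradient, n_peptides, n_proteins)
        for ng in _INPUT_SERIES:
            for mk, mix in (("1", MixDesign.mix1), ("2", MixDesign.mix2), ("3", MixDesign.mix3)):
                rid = f"hk_mix{mk}_{ng:g}ng"
                plan.append((rid, "human", mix(ng)))
    if preset in ("tko11_4runs", "combined_16runs"):
        truths["yeast"] = _yeast_truth(seed + 1, gradient,
                                       (n_peptides * 2) // 3,
                                       max(4, (n_proteins * 4) // 5))
        for ng in _INPUT_SERIES:
            plan.append((f"tko_{ng:g}ng", "yeast", MixDesign.tko11(ng)))

    manifests: list[RunManifest] = []
    scans: dict[str, list[MsmsScan]] = {}
    designs: dict[str, MixDesign] = {}
    out_dir = Path(out_dir) if out_dir is not None else None
    for i, (rid, tkey, design) in enumerate(plan):
        warp = RtWarp() if i == 0 else RtWarp.random(rng)
        run_seed = int(rng.integers(0, 2**31 - 1))
        path = str(out_dir / f"{rid}.mzML") if out_dir else ""
        scans[rid] = simulate_run(
            truths[tkey],
            design,
            scheme,
            gradient=gradient,
            rt_warp=warp,
            noise=noise,
            dilution_ng=design.input_ng,
            seed=run_seed,
            run_id=rid,
            out_path=path or None,
        )
        designs[rid] = design
        manifests.append(
            RunManifest(
                run_id=rid,
                path=path,
                mix=design.name,
                input_ng=design.input_ng,
                batch=rid,
                plex=len(ReporterChannelSet.from_name(design.plex)),
            )
        )
    if out_dir is not None:
        write_manifest(manifests, out_dir / "manifest.tsv")
        for key, truth in truths.items():
            truth.write_tsv(
                out_dir / f"truth_{key}_peptides.tsv",
                out_dir / f"truth_{key}_abundance.tsv",
            )
    return Experiment(
        preset=preset,
        scheme=scheme,
        manifests=manifests,
        scans=scans,
        designs=designs,
        truths=truths,
        seed=seed,
    )
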