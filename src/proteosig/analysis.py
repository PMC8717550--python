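"""Sample clustering and downstream comparisons.

PCA on the aggregated signature matrix is the workhorse: with complete,
normalized matrices the first component separates cell types while later
components absorb run-to-run effects.  Loadings of the separating
components, intersected with any available peptide identifications, name
the scans that drive a cluster.  The peptide-based comparisons (unique-
peptide collapse, replicate-overlap Venn counts, protein-vs-transcript
fold changes) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .alignment import AggregatedMatrix
from .normalize import log10_transform

__all__ = [
    "PcaResult",
    "OverlapSummary",
    "pca",
    "sign_partition_errors",
    "cluster_drivers",
    "collapse_unique_peptides",
    "replicate_overlap",
    "protein_transcript_comparison",
]


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of an exact PCA."""

    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # features × components
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(
    matrix: AggregatedMatrix | pd.DataFrame,
    *,
    log_transform: bool = True,
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
    pseudocount: float = 1.0,
) -> PcaResult:
    """Exact (full-SVD) PCA of the samples × features matrix.

    Default preprocessing is log10(x + 1) followed by feature mean-
    centering, without unit-variance scaling — the conservative choice for
    intensity matrices whose informative structure is multiplicative.
    """
    data = matrix.data if isinstance(matrix, AggregatedMatrix) else matrix
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    X = log10_transform(data, pseudocount) if log_transform else data.astype(float)
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X.loc[:, sd > 0] / sd[sd > 0]
    if float(X.var(axis=0, ddof=0).sum()) == 0.0:
        raise ValueError("constant matrix: PCA is degenerate")
    k = n_components or min(X.shape[0] - (1 if center else 0), X.shape[1])
    k = min(k, min(X.shape))
    model = PCA(n_components=k, svd_solver="full")
    # sklearn always centers; for center=False add the mean back via raw SVD
    if center:
        scores = model.fit_transform(X.to_numpy())
        comps = model.components_
        evr = model.explained_variance_ratio_
    else:
        U, s, Vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
        scores = U[:, :k] * s[:k]
        comps = Vt[:k]
        evr = (s[:k] ** 2) / (s**2).sum()
    pc_names = [f"PC{i+1}" for i in range(comps.shape[0])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.index, columns=pc_names),
        loadings=pd.DataFrame(comps.T, index=X.columns, columns=pc_names),
        explained_variance_ratio=np.asarray(evr),
    )


def sign_partition_errors(scores: pd.Series, labels: Sequence[str]) -> int:
    """Label errors when splitting samples by the sign of one PC score.

    The two groups are assigned to the two sides so as to minimize the
    mismatch count; 0 means the component partitions the samples exactly.
    """
    labels = pd.Series(list(labels), index=scores.index)
    uniq = labels.unique()
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 labels, got {list(uniq)}")
    positive = scores >= 0
    err_a = int(((labels == uniq[0]) != positive).sum())
    return min(err_a, len(labels) - err_a)


def cluster_drivers(
    result: PcaResult,
    component: int,
    top_k: int,
    psm_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Top-|loading| dID features of one component, joined to identifications.

    ``component`` is 1-based.  ``psm_table`` must carry a ``feature``
    column mapping identified scans to dID features (plus e.g. peptide /
    protein columns); features without identification keep empty
    annotations — the point of the identification-free analysis is that
    they still quantify.
    """
    if not 1 <= component <= result.n_components:
        raise ValueError(
            f"component {component} out of range 1..{result.n_components}"
        )
    col = f"PC{component}"
    load = result.loadings[col]
    top = load.abs().sort_values(ascending=False).head(top_k)
    drivers = pd.DataFrame(
        {
            "feature": top.index,
            "loading": load.loc[top.index].to_numpy(),
            "abs_loading": top.to_numpy(),
            "rank": np.arange(1, len(top) + 1),
        }
    )
    if psm_table is not None and len(psm_table):
        if "feature" not in psm_table.columns:
            raise ValueError("psm_table must carry a 'feature' column mapped to dIDs")
        ann_cols = [c for c in ("peptide", "protein") if c in psm_table.columns]
        ann = (
            psm_table.groupby("feature")[ann_cols]
            .agg(lambda s: ";".join(sorted(set(map(str, s)))))
            .reset_index()
        )
        drivers = drivers.merge(ann, on="feature", how="left")
    else:
        drivers["peptide"] = pd.NA
        drivers["protein"] = pd.NA
    return drivers


def collapse_unique_peptides(psm_table: pd.DataFrame) -> pd.DataFrame:
    """One row per peptide sequence: the best-scoring (minimum q-value) PSM."""
    if len(psm_table) == 0:
        return psm_table.copy()
    idx = psm_table.groupby("peptide")["q_value"].idxmin()
    return psm_table.loc[idx].sort_index().reset_index(drop=True)


@dataclass
class OverlapSummary:
    """Exact intersection counts of unique-peptide sets (Venn counts)."""

    set_sizes: tuple[int, ...]
    intersections: dict[tuple[int, ...], int]  # subset of 0-based set indices

    @property
    def n_sets(self) -> int:
        return len(self.set_sizes)

    @property
    def central(self) -> int:
        return self.intersections[tuple(range(self.n_sets))]

    def pairwise(self) -> dict[tuple[int, int], int]:
        return {
            k: v for k, v in self.intersections.items() if len(k) == 2
        }


def replicate_overlap(peptide_sets: Sequence[Iterable[str]]) -> OverlapSummary:
    """Intersection counts for every subset of ≥2 replicate peptide sets."""
    sets = [set(s) for s in peptide_sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 peptide sets")
    inter: dict[tuple[int, ...], int] = {}
    for r in range(2, len(sets) + 1):
        for combo in combinations(range(len(sets)), r):
            common = set.intersection(*(sets[i] for i in combo))
            inter[combo] = len(common)
    return OverlapSummary(
        set_sizes=tuple(len(s) for s in sets),
        intersections=inter,
    )


def protein_transcript_comparison(
    protein_quant: pd.DataFrame,
    fpkm_fc: pd.DataFrame,
    *,
    group_a: str | None = None,
    group_b: str | None = None,
    top_n: int = 300,
) -> tuple[pd.DataFrame, float, tuple[float, float]]:
    """Join protein and transcript fold changes per gene; Pearson r with CI.

    ``protein_quant`` is indexed by gene with one column of mean reporter
    intensity per group (two groups); ``fpkm_fc`` has columns ``gene`` and
    ``log2_fc``.  Returns the joined per-gene table (log2 protein FC, log2
    transcript FC, top-N protein-FC flag), the Pearson estimate and its
    95% confidence interval.
    """
    if protein_quant.shape[1] < 2 and (group_a is None or group_b is None):
        raise ValueError("protein_quant needs two group columns")
    ga = group_a or protein_quant.columns[0]
    gb = group_b or protein_quant.columns[1]
    if (protein_quant[[ga, gb]] <= 0).any().any():
        raise ValueError("group means must be positive to form log2 fold changes")
    prot = pd.DataFrame(
        {"log2_protein_fc": np.log2(protein_quant[ga] / protein_quant[gb])}
    )
    prot.index.name = "gene"
    fpkm = fpkm_fc.set_index("gene")["log2_fc"].rename("log2_transcript_fc")
    joined = prot.join(fpkm, how="inner").dropna()
    if len(joined) == 0:
        raise ValueError("no genes shared between protein and transcript tables")
    joined["top_protein_fc"] = False
    top_idx = joined["log2_protein_fc"].abs().nlargest(min(top_n, len(joined))).index
    joined.loc[top_idx, "top_protein_fc"] = True
    res = stats.pearsonr(joined["log2_protein_fc"], joined["log2_transcript_fc"])
    ci = res.confidence_interval(0.95)
    return joined, float(res.statistic), (float(ci.low), float(ci.high))
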