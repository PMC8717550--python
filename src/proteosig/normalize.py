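"""Channel normalization, noise imputation and batch correction.

Two analysis arms use different normalizations: the identification-free
signature matrices (complete, zero-filled) are scaled to equal total signal
per sample/channel, while peptide-based matrices (sparse, NaN-holding) are
global-median normalized in log space.  Missing values in the peptide arm
can be imputed by draws from a normal distribution down-shifted into the
noise (the common left-censored imputation: mean μ − 1.8σ, width 0.3σ in
log10 space, per sample).  Multi-batch effects are removed with a
parametric empirical-Bayes location/scale model (ComBat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AggregatedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationReport",
    "scale_equal_channel_signal",
    "global_median_normalize",
    "impute_noise",
    "eb_batch_correct",
    "log10_transform",
]


@dataclass
class NormalizationReport:
    """Scale factors and pre/post totals of one normalization step."""

    method: str
    factors: pd.Series
    pre_totals: pd.Series
    post_totals: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": self.factors,
                "pre_total": self.pre_totals,
                "post_total": self.post_totals,
            }
        )


def scale_equal_channel_signal(
    matrix: AggregatedMatrix,
) -> tuple[AggregatedMatrix, NormalizationReport]:
    """Scale every sample row so all row totals equal the pre-scaling mean.

    Equal total signal per channel removes the per-sample loading and
    dilution differences that dominate raw reporter sums; targeting the
    mean total conserves the overall matrix signal.
    """
    totals = matrix.data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero total signal cannot be scaled: "
            f"{', '.join(map(str, zero.index[:5]))}"
        )
    target = totals.mean()
    factors = target / totals
    data = matrix.data.mul(factors, axis=0)
    report = NormalizationReport(
        method="scale_equal_channel_signal",
        factors=factors,
        pre_totals=totals,
        post_totals=data.sum(axis=1),
    )
    return AggregatedMatrix(data=data, meta=matrix.meta.copy()), report


def global_median_normalize(peptide_matrix: pd.DataFrame) -> pd.DataFrame:
    """Equalize per-sample medians across experiments (peptide-based arm).

    Each sample (row) is shifted in log space so its median observed value
    equals the global median of per-sample medians; missing entries (NaN)
    are ignored and preserved.
    """
    observed = peptide_matrix.notna().sum(axis=1)
    empty = observed[observed == 0]
    if len(empty):
        raise ValueError(
            f"sample(s) with no observed values: "
            f"{', '.join(map(str, empty.index[:5]))}"
        )
    if (peptide_matrix <= 0).any().any():
        raise ValueError("median normalization requires positive observed values")
    log = np.log10(peptide_matrix)
    medians = log.median(axis=1)
    target = medians.median()
    shifted = log.add(target - medians, axis=0)
    return 10.0 ** shifted


def impute_noise(
    matrix: pd.DataFrame,
    downshift: float = 1.8,
    width: float = 0.3,
    seed: int | np.random.Generator | None = None,
    *,
    mode: str = "sd",
) -> pd.DataFrame:
    """Replace missing entries with draws from a down-shifted noise normal.

    Per sample (row) s with observed log10 mean μ_s and SD σ_s, missing
    entries are drawn from Normal(μ_s − downshift·σ_s, (width·σ_s)²)
    (``mode="sd"``, the usual left-censored convention).  With
    ``mode="absolute"`` the shift is ``downshift`` log10 units and the
    width ``width`` log10 units, independent of σ_s.  Observed entries are
    never altered; a fixed seed makes the imputation deterministic.
    """
    if mode not in ("sd", "absolute"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = matrix.copy()
    mask = matrix.isna()
    if not mask.to_numpy().any():
        return out
    for sample in matrix.index:
        row = matrix.loc[sample]
        obs = row.dropna()
        miss = mask.loc[sample]
        n_miss = int(miss.sum())
        if n_miss == 0:
            continue
        if len(obs) < 2:
            raise ValueError(
                f"sample {sample!r} has {len(obs)} observed value(s); "
                "at least 2 are needed to estimate the noise distribution"
            )
        if (obs <= 0).any():
            raise ValueError(f"sample {sample!r} has non-positive observed values")
        log_obs = np.log10(obs.to_numpy())
        mu, sigma = log_obs.mean(), log_obs.std(ddof=1)
        if mode == "sd":
            loc, scale = mu - downshift * sigma, width * sigma
        else:
            loc, scale = mu - downshift, width
        draws = rng.normal(loc, scale, size=n_miss)
        out.loc[sample, miss] = 10.0 ** draws
    return out


def eb_batch_correct(
    matrix: pd.DataFrame,
    batch_labels: Sequence[str],
) -> pd.DataFrame:
    """Parametric empirical-Bayes (ComBat) location/scale batch adjustment.

    Expects log-transformed data (samples × features) and models no
    biological covariates: features are standardized, per-batch additive
    (γ) and multiplicative (δ) effects are shrunk toward pooled priors and
    removed.  A single batch is a no-op; a batch with one sample is an
    error (its variance is inestimable).  Features that are constant
    across all samples are passed through unchanged.
    """
    labels = pd.Series(list(batch_labels), index=matrix.index, dtype="object")
    counts = labels.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(
            f"batch(es) with a single sample cannot be corrected: {bad}"
        )
    if counts.size == 1:
        return matrix.copy()

    variances = matrix.var(axis=0, ddof=0)
    variable = variances > 0
    if not variable.any():
        return matrix.copy()

    import anndata
    import scanpy as sc

    sub = matrix.loc[:, variable]
    adata = anndata.AnnData(
        X=sub.to_numpy(dtype=np.float64, copy=True),
        obs=pd.DataFrame({"batch": pd.Categorical(labels)}, index=sub.index.astype(str)),
    )
    sc.pp.combat(adata, key="batch")
    out = matrix.copy()
    out.loc[:, variable] = np.asarray(adata.X)
    return out


def log10_transform(matrix: AggregatedMatrix | pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log10(x + pseudocount) for zero-containing signature matrices."""
    data = matrix.data if isinstance(matrix, AggregatedMatrix) else matrix
    return np.log10(data + pseudocount)
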