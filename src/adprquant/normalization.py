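"""Between-column scaling normalization for reporter intensities.

Implements trimmed-mean-of-M-values (TMM) scaling factors and the
log2-per-million transform.  TMM computes, for each column against a
reference column, per-protein log-ratios M and average log-abundances A
(both on library-size-scaled intensities), discards proteins in the extreme
quantiles of M (30% each tail by default) and of A (5% each tail), and
averages the surviving M values weighted by their inverse asymptotic
(delta-method binomial) variance.  Factors are rescaled to geometric mean 1
so that effective library sizes preserve the overall intensity scale.

Zeros must be removed upstream (the quality filter keeps only proteins with
strictly positive intensity everywhere), so no prior count is added by
default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass
class NormalizationResult:
    """TMM factors and the normalized log2-per-million matrix."""

    library_sizes: np.ndarray      # per-column sums of raw intensities
    tmm_factors: np.ndarray        # geometric-mean-1 scaling factors
    effective_sizes: np.ndarray    # library_size * factor
    matrix_log2pm: pd.DataFrame | np.ndarray


def _as_array(matrix) -> np.ndarray:
    return matrix.to_numpy(float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)


def _reference_column(mat: np.ndarray, lib: np.ndarray) -> int:
    # Robinson–Oshlack convention: column whose upper quartile of
    # library-size-scaled intensities is closest to the mean upper quartile.
    f75 = np.quantile(mat, 0.75, axis=0) / lib
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _pairwise_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    w_var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        logger.warning("TMM: all proteins trimmed for a column; factor set to 1")
        return 1.0
    f = np.sum(m[keep] / w_var[keep]) / np.sum(1.0 / w_var[keep])
    return float(2.0 ** f)


def tmm_factors(
    matrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: int | None = None,
) -> np.ndarray:
    """Per-column TMM scaling factors, rescaled to geometric mean 1.

    Parameters
    ----------
    matrix:
        proteins × columns strictly positive intensities.
    trim_m, trim_a:
        Two-sided trim fractions on the log-ratio (M) and average
        log-abundance (A) statistics.
    reference:
        Reference column index; auto-selected by the upper-quartile rule
        when None.
    """
    mat = _as_array(matrix)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("TMM needs a 2-D matrix with at least 2 columns")
    if (mat <= 0).any():
        raise ValueError("TMM requires strictly positive intensities; filter zeros upstream")
    lib = mat.sum(axis=0)
    ref = _reference_column(mat, lib) if reference is None else int(reference)

    factors = np.ones(mat.shape[1])
    for k in range(mat.shape[1]):
        if k == ref:
            continue
        factors[k] = _pairwise_factor(mat[:, k], mat[:, ref], lib[k], lib[ref], trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def log2_per_million(matrix, factors=None, prior_count: float = 0.0):
    """log2 of each intensity as a per-million share of its column's
    effective total (library size × TMM factor).

    With ``factors`` None all factors are taken as 1 (library-size-only
    scaling).  A ``prior_count`` may be added to the intensities for
    robustness, but defaults to 0 because upstream filtering removes zeros.
    """
    mat = _as_array(matrix)
    if (mat + prior_count <= 0).any():
        g, k = np.argwhere(mat + prior_count <= 0)[0]
        raise ValueError(f"non-positive intensity at protein row {g}, column {k}")
    lib = mat.sum(axis=0)
    f = np.ones(mat.shape[1]) if factors is None else np.asarray(factors, float)
    if (f <= 0).any():
        raise ValueError("normalization factors must be positive")
    eff = lib * f
    out = np.log2(1e6 * (mat + prior_count) / eff)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def normalize(
    matrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: int | None = None,
    prior_count: float = 0.0,
) -> NormalizationResult:
    """TMM factors plus the log2-per-million matrix, in one call.

    Normalization is computed jointly across all replicates' columns of the
    experiment; pass per-replicate column subsets for per-plex mode.
    """
    mat = _as_array(matrix)
    lib = mat.sum(axis=0)
    f = tmm_factors(matrix, trim_m=trim_m, trim_a=trim_a, reference=reference)
    log2pm = log2_per_million(matrix, f, prior_count=prior_count)
    return NormalizationResult(
        library_sizes=lib,
        tmm_factors=f,
        effective_sizes=lib * f,
        matrix_log2pm=log2pm,
    )
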