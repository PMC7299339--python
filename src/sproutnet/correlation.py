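"""All-pairs miRNA-gene Pearson correlation with a permutation null.

The "correlator" is the Pearson coefficient between a miRNA's and a gene's
log2 expression profiles across samples.  Significance can be assessed
analytically (t transform, n-2 df) or against an empirical null obtained by
sample-label randomization: per permutation the miRNA matrix columns are
shuffled once (equivalent, under exchangeability, to shuffling either
matrix) and every pair correlation is recomputed; the pooled draws form the
null distribution.  With six samples only 720 distinct orderings exist, so
permutations are sampled with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ContractError
from .io_formats import ExpressionMatrix

__all__ = [
    "CORRELATION_COLUMNS",
    "NullDistribution",
    "pairwise_correlation",
    "permutation_null",
    "attach_empirical_p",
    "stratified_distribution_test",
]

CORRELATION_COLUMNS = ("mirna", "gene", "r", "p_analytic", "undefined")


def _standardized_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled to zero mean / unit L2 norm; second return flags zero variance."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    return centered / safe[:, None], zero


def _analytic_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t transform with n-2 degrees of freedom."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def _check_sample_alignment(mirs: ExpressionMatrix, genes: ExpressionMatrix) -> int:
    if mirs.sample_ids != genes.sample_ids:
        raise ContractError("miRNA and gene matrices must share sample ordering")
    n = mirs.n_samples
    if n < 4:
        raise ContractError("need at least 4 common samples for correlation")
    return n


def pairwise_correlation(mirs: ExpressionMatrix, genes: ExpressionMatrix) -> pd.DataFrame:
    """Pearson r for every (miRNA, gene) pair, with analytic two-sided p.

    Expects both matrices on the log2(normalized+1) scale (use
    :meth:`ExpressionMatrix.to_log2`).  Zero-variance profiles yield records
    flagged ``undefined`` (r = NaN) which downstream stages exclude.
    """
    n = _check_sample_alignment(mirs, genes)
    if not (mirs.log_scale and genes.log_scale):
        raise ContractError("correlation operates on log2-scale matrices")
    X, x_zero = _standardized_rows(mirs.values.to_numpy(dtype=float))
    Y, y_zero = _standardized_rows(genes.values.to_numpy(dtype=float))
    r = X @ Y.T
    undefined = x_zero[:, None] | y_zero[None, :]
    r = np.where(undefined, np.nan, np.clip(r, -1.0, 1.0))

    n_mir, n_gene = r.shape
    df = pd.DataFrame({
        "mirna": np.repeat(mirs.feature_ids, n_gene),
        "gene": np.tile(genes.feature_ids, n_mir),
        "r": r.ravel(),
        "p_analytic": np.where(undefined.ravel(), np.nan,
                               _analytic_p(r.ravel(), n)),
        "undefined": undefined.ravel(),
    })
    df.attrs["n_samples"] = n
    return df


@dataclass
class NullDistribution:
    """Pooled correlator draws under sample-label randomization."""

    samples: np.ndarray
    n_permutations: int
    n_pairs_per_perm: int
    _abs_sorted: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_pooled(self) -> int:
        return self.samples.size

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    def empirical_p(self, r_obs: np.ndarray | float) -> np.ndarray:
        """Add-one empirical two-sided p: (1 + #{null |r| >= |r_obs|}) / (1 + N)."""
        if self._abs_sorted is None:
            self._abs_sorted = np.sort(np.abs(self.samples))
        r_abs = np.abs(np.atleast_1d(np.asarray(r_obs, dtype=float)))
        n = self._abs_sorted.size
        n_ge = n - np.searchsorted(self._abs_sorted, r_abs, side="left")
        out = (1.0 + n_ge) / (1.0 + n)
        return np.where(np.isnan(r_abs), np.nan, out)


def permutation_null(mirs: ExpressionMatrix, genes: ExpressionMatrix,
                     n_perm: int = 1000, seed: int = 0) -> NullDistribution:
    """Null correlator distribution from ``n_perm`` sample-label shuffles.

    One shuffle of the miRNA matrix columns per permutation keeps the null
    joint across all pairs.  Pairs involving a zero-variance profile are
    excluded from the pool.  Deterministic under ``seed``.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    n = _check_sample_alignment(mirs, genes)
    if not (mirs.log_scale and genes.log_scale):
        raise ContractError("correlation operates on log2-scale matrices")
    X, x_zero = _standardized_rows(mirs.values.to_numpy(dtype=float))
    Y, y_zero = _standardized_rows(genes.values.to_numpy(dtype=float))
    X, Y = X[~x_zero], Y[~y_zero]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_pairs = X.shape[0] * Y.shape[0]
    pool = np.empty(n_perm * n_pairs, dtype=np.float32)
    for i in range(n_perm):
        perm = rng.permutation(n)
        r = X[:, perm] @ Y.T
        pool[i * n_pairs:(i + 1) * n_pairs] = np.clip(r, -1.0, 1.0).ravel()
    return NullDistribution(pool, n_permutations=n_perm, n_pairs_per_perm=n_pairs)


def attach_empirical_p(ct: pd.DataFrame, null: NullDistribution) -> pd.DataFrame:
    """Return a copy of the correlation table with a ``p_empirical`` column."""
    out = ct.copy()
    out["p_empirical"] = null.empirical_p(ct["r"].to_numpy())
    out.attrs.update(ct.attrs)
    out.attrs["n_null_pooled"] = null.n_pooled
    return out


def stratified_distribution_test(ct: pd.DataFrame, pt: pd.DataFrame,
                                 stratum: str = "conserved",
                                 bins: int = 40) -> dict:
    """Compare the correlator distribution of a prediction stratum to all pairs.

    Returns histogram summaries of r for all pairs and for the stratum, the
    two-sample Kolmogorov-Smirnov statistic D, and a one-sided p for a
    stochastic shift of the stratum toward negative r (stratum ECDF above the
    all-pairs ECDF).
    """
    if stratum not in ("conserved", "nonconserved"):
        raise ConfigurationError(f"unknown stratum {stratum!r}")
    valid = ct[~ct["undefined"]]
    all_r = valid["r"].to_numpy(dtype=float)
    pairs = set(zip(pt.loc[pt["conservation"] == stratum, "mirna"],
                    pt.loc[pt["conservation"] == stratum, "gene"]))
    mask = [(m, g) in pairs for m, g in zip(valid["mirna"], valid["gene"])]
    stratum_r = valid.loc[mask, "r"].to_numpy(dtype=float)
    if stratum_r.size == 0:
        raise ContractError(f"stratum {stratum!r} is empty after intersection")

    # one-sided: stratum stochastically smaller (more negative) than all pairs
    ks_two = stats.ks_2samp(stratum_r, all_r, alternative="two-sided")
    ks_neg = stats.ks_2samp(stratum_r, all_r, alternative="greater")

    edges = np.linspace(-1.0, 1.0, bins + 1)
    hist_all, _ = np.histogram(all_r, bins=edges)
    hist_stratum, _ = np.histogram(stratum_r, bins=edges)
    return {
        "stratum": stratum,
        "n_all": int(all_r.size),
        "n_stratum": int(stratum_r.size),
        "d": float(ks_two.statistic),
        "p_two_sided": float(ks_two.pvalue),
        "d_negative_shift": float(ks_neg.statistic),
        "p_negative_shift": float(ks_neg.pvalue),
        "mean_r_all": float(all_r.mean()),
        "mean_r_stratum": float(stratum_r.mean()),
        "hist_edges": edges.tolist(),
        "hist_all": hist_all.tolist(),
        "hist_stratum": hist_stratum.tolist(),
    }
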