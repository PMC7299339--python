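"""Downstream statistics: over-representation, cohort scoring and ΔΔCt cards.

The hypergeometric test is computed with exact rational arithmetic.  The
endothelial score summarizes a tumor sample's angiogenic activity as the
mean of per-gene z-scored expression over a user-supplied endothelial
signature; samples are returned ranked by it.  ΔΔCt card processing follows
the comparative-Ct convention: ΔCt normalizes each sample against reference
assays (or the per-sample global mean), ΔΔCt = ΔCt_treated - ΔCt_control
after averaging replicates on the Ct scale, and the relative quantity is
Rq = 2^(-ΔΔCt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .exceptions import ContractError
from .io_formats import ExpressionMatrix

__all__ = [
    "HypergeomResult",
    "hypergeometric_test",
    "endothelial_score",
    "module_score_correlation",
    "ddct_analysis",
]


@dataclass
class HypergeomResult:
    k: int          # observed successes in the draw
    K: int          # successes in the population
    n: int          # draw size
    N: int          # population size
    p_upper: float  # P(X >= k)
    p_exact: Fraction


def hypergeometric_test(k: int, K: int, n: int, N: int) -> HypergeomResult:
    """Upper-tail hypergeometric probability P(X >= k), exact arithmetic.

    ``k`` successes observed in a draw of ``n`` from a population of ``N``
    containing ``K`` successes.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise ContractError("infeasible hypergeometric parameters")
    if k > min(K, n):
        raise ContractError("k exceeds min(K, n)")
    denom = comb(N, n)
    total = sum(comb(K, i) * comb(N - K, n - i)
                for i in range(k, min(K, n) + 1))
    p = Fraction(total, denom)
    return HypergeomResult(k=k, K=K, n=n, N=N, p_upper=float(p), p_exact=p)


def endothelial_score(cohort: ExpressionMatrix, signature: Sequence[str],
                      min_present_fraction: float = 0.8) -> pd.Series:
    """Per-sample endothelial score: mean of z-scored signature-gene expression.

    Genes absent from the cohort are skipped (warning when fewer than
    ``min_present_fraction`` of the signature is present); zero-variance
    genes are excluded from the mean with a warning.  Returns scores ranked
    descending.
    """
    signature = [str(g) for g in signature]
    present = [g for g in signature if g in cohort.values.index]
    if not present:
        raise ContractError("no signature gene present in the cohort")
    if len(present) < min_present_fraction * len(signature):
        warnings.warn(
            f"only {len(present)}/{len(signature)} signature genes present",
            stacklevel=2)
    sub = cohort.values.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"excluding constant signature gene(s): {sub.index[constant].tolist()}",
            stacklevel=2)
        sub = sub.loc[~constant]
        sd = sd[~constant]
    if sub.empty:
        raise ContractError("all present signature genes are constant")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    scores = z.mean(axis=0)
    scores.name = "endothelial_score"
    return scores.sort_values(ascending=False)


def module_score_correlation(cohort: ExpressionMatrix, module: Sequence[str],
                             scores: pd.Series) -> tuple[float, float]:
    """Pearson correlation between the mean z-scored module expression and a
    per-sample score, with analytic two-sided p."""
    module = [str(g) for g in module]
    present = [g for g in module if g in cohort.values.index]
    if len(present) < 2:
        raise ContractError("need at least 2 module genes present in the cohort")
    sub = cohort.values.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=1)
    sub = sub.loc[sd > 0]
    if sub.shape[0] < 2:
        raise ContractError("module expression is degenerate (constant genes)")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    module_mean = z.mean(axis=0)
    aligned = scores.reindex(module_mean.index)
    if aligned.isna().any():
        raise ContractError("scores missing for some cohort samples")
    if module_mean.std(ddof=1) == 0 or aligned.std(ddof=1) == 0:
        raise ContractError("degenerate variance in module mean or scores")
    r, p = stats.pearsonr(module_mean.to_numpy(), aligned.to_numpy())
    return float(r), float(p)


def ddct_analysis(ct_table: pd.DataFrame, condition: Mapping[str, str],
                  reference_assays: Sequence[str] = (),
                  control_condition: str = "control",
                  threshold: float = 2.0) -> pd.DataFrame:
    """Comparative-Ct analysis of a qPCR card.

    ``ct_table`` is a wide assays x samples table of Ct values; ``condition``
    maps samples to conditions, one of which is the control.  Per sample,
    ΔCt subtracts the mean Ct of the reference assays (the per-sample global
    mean over all assays when ``reference_assays`` is empty).  Replicates
    are averaged on the Ct scale within a condition, then per treated
    condition ΔΔCt = ΔCt_treated - ΔCt_control and Rq = 2^(-ΔΔCt).

    Returns one row per non-reference assay with columns ``dct_control``,
    ``dct_<cond>``, ``ddct``, ``rq``, ``passes_threshold`` (strict
    |ΔΔCt| > ``threshold`` in at least one treated condition).  Surviving
    rows are ordered by hierarchical clustering of -ΔΔCt (Euclidean,
    complete linkage); the order is stored in ``df.attrs["cluster_order"]``.
    """
    samples = ct_table.columns.tolist()
    missing = [s for s in samples if s not in condition]
    if missing:
        raise ContractError(f"samples without condition label: {missing}")
    conds = pd.Series({s: condition[s] for s in samples})
    if control_condition not in conds.values:
        raise ContractError(f"no sample in control condition {control_condition!r}")
    treated_conditions = [c for c in conds.unique() if c != control_condition]
    if not treated_conditions:
        raise ContractError("no treated condition present")
    if ct_table.isna().any().any():
        raise ContractError("Ct table contains missing values")

    reference_assays = [str(a) for a in reference_assays]
    absent = [a for a in reference_assays if a not in ct_table.index]
    if absent:
        raise ContractError(f"reference assays absent from the card: {absent}")
    if reference_assays:
        ref_mean = ct_table.loc[reference_assays].mean(axis=0)
    else:
        ref_mean = ct_table.mean(axis=0)
    dct = ct_table.sub(ref_mean, axis=1)
    dct = dct.drop(index=reference_assays, errors="ignore")

    per_cond = {c: dct[[s for s in samples if conds[s] == c]].mean(axis=1)
                for c in conds.unique()}
    out = pd.DataFrame({"dct_control": per_cond[control_condition]})
    ddct_cols = []
    for c in treated_conditions:
        out[f"dct_{c}"] = per_cond[c]
        col = f"ddct_{c}" if len(treated_conditions) > 1 else "ddct"
        out[col] = per_cond[c] - per_cond[control_condition]
        ddct_cols.append(col)
    for col in ddct_cols:
        rq_col = col.replace("ddct", "rq")
        out[rq_col] = 2.0 ** (-out[col])
    out["passes_threshold"] = (out[ddct_cols].abs() > threshold).any(axis=1)

    surviving = out[out["passes_threshold"]]
    order = surviving.index.tolist()
    if len(order) > 2:
        mat = -surviving[ddct_cols].to_numpy(dtype=float)
        link = hierarchy.linkage(pdist(mat, metric="euclidean"), method="complete")
        order = [surviving.index[i] for i in hierarchy.leaves_list(link)]
    out.attrs["cluster_order"] = order
    out.attrs["threshold"] = threshold
    out.attrs["reference_assays"] = list(reference_assays)
    return out
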