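"""Expression filtering, normalization and a two-condition DE stage.

The differential-expression stage is intentionally simple: a two-sample t
statistic on log2(x+1) normalized counts with empirical-Bayes variance
moderation (pooled per-feature variance shrunk toward the across-feature
mean with a small prior df — essential for any power at 3+3 replicates),
Benjamini-Hochberg correction, and the study's modulation thresholds
(|log2FC| > 0.5, FDR < 0.05).  It provides the same thresholding semantics
as a dedicated count-model tool without reimplementing one; externally
computed DE tables can be ingested instead.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ContractError, FormatError, SizeFactorError
from .io_formats import ExpressionMatrix

__all__ = [
    "DE_COLUMNS",
    "filter_expressed",
    "normalize_counts",
    "differential_expression",
    "ingest_de_table",
    "assign_direction",
    "write_de_table",
]

#: columns of a DE table (a plain :class:`pandas.DataFrame`)
DE_COLUMNS = ("feature_id", "base_mean", "log2fc", "p", "fdr", "direction")


def filter_expressed(m: ExpressionMatrix, min_raw: float = 5.0) -> ExpressionMatrix:
    """Keep features whose mean raw count over all samples is strictly > ``min_raw``.

    Feature order is preserved.  Raises :class:`ContractError` on normalized
    input (the cutoff is defined on raw counts).
    """
    if m.normalized:
        raise ContractError("filter_expressed operates on raw counts")
    keep = m.values.mean(axis=1) > min_raw
    return ExpressionMatrix(m.values.loc[keep], dict(m.condition), m.kind)


def normalize_counts(m: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios normalization.

    Size factor per sample = median over reference features (those with a
    strictly positive geometric mean, i.e. no zero count) of
    count / geometric-mean.  Each sample is divided by its size factor and
    the result flagged normalized.
    """
    if m.normalized:
        return m
    if m.n_samples < 2:
        raise ContractError("normalization needs at least 2 samples")
    counts = m.values.to_numpy(dtype=float)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise SizeFactorError("every feature contains a zero count")
    ref = counts[allpos]
    log_gm = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_gm[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    values = pd.DataFrame(counts / size_factors[None, :],
                          index=m.values.index, columns=m.values.columns)
    out = ExpressionMatrix(values, dict(m.condition), m.kind, normalized=True)
    out.values.attrs["size_factors"] = dict(zip(m.sample_ids, size_factors.tolist()))
    return out


def assign_direction(log2fc: pd.Series, fdr: pd.Series,
                     lfc_threshold: float = 0.5,
                     fdr_cutoff: float = 0.05) -> pd.Series:
    """up iff log2fc > threshold and fdr < cutoff; down symmetric; else ns.

    Both comparisons are strict, matching the study's "|log2FC| > 0.5 and
    FDR < 0.05" rule.
    """
    direction = pd.Series("ns", index=log2fc.index, dtype=object)
    sig = fdr < fdr_cutoff
    direction[sig & (log2fc > lfc_threshold)] = "up"
    direction[sig & (log2fc < -lfc_threshold)] = "down"
    return direction


def differential_expression(m: ExpressionMatrix, lfc_threshold: float = 0.5,
                            fdr_cutoff: float = 0.05,
                            control_label: str = "control",
                            treated_label: str = "treated",
                            moderation_prior_df: float = 4.0) -> pd.DataFrame:
    """Two-condition DE on a normalized matrix.

    log2fc = log2((mean_treated + 1) / (mean_control + 1)) on the normalized
    scale.  The p-value comes from a pooled-variance t on log2(x+1) values
    with empirical-Bayes moderation: the per-feature pooled variance s2 is
    shrunk toward the across-feature mean s0 as
    ``(d0*s0 + df*s2) / (d0 + df)`` with ``d0 = moderation_prior_df`` and the
    statistic referred to a t distribution on ``df + d0`` degrees of freedom.
    ``moderation_prior_df=0`` recovers the plain pooled t.  FDR by
    Benjamini-Hochberg over all features; features with zero variance in
    both groups and a zero prior get p = 1.
    """
    if not m.normalized:
        raise ContractError("differential_expression expects normalized counts")
    if moderation_prior_df < 0:
        raise ContractError("moderation_prior_df must be >= 0")
    ctrl = m.samples_in(control_label)
    trt = m.samples_in(treated_label)
    if len(ctrl) < 2 or len(trt) < 2:
        raise ContractError("each condition needs at least 2 samples")
    x_ctrl = m.values[ctrl].to_numpy(dtype=float)
    x_trt = m.values[trt].to_numpy(dtype=float)

    base_mean = m.values.to_numpy(dtype=float).mean(axis=1)
    log2fc = np.log2((x_trt.mean(axis=1) + 1.0) / (x_ctrl.mean(axis=1) + 1.0))

    lc, lt = np.log2(x_ctrl + 1.0), np.log2(x_trt + 1.0)
    n1, n2 = lt.shape[1], lc.shape[1]
    df = n1 + n2 - 2
    s2 = (lt.var(axis=1, ddof=1) * (n2 - 1) + lc.var(axis=1, ddof=1) * (n1 - 1)) / df
    d0 = moderation_prior_df
    s2_mod = (d0 * s2.mean() + df * s2) / (d0 + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (lt.mean(axis=1) - lc.mean(axis=1)) / np.sqrt(s2_mod * (1 / n1 + 1 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df=df + d0)
    p = np.where(np.isnan(p), 1.0, p)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")

    df = pd.DataFrame({
        "feature_id": m.feature_ids,
        "base_mean": base_mean,
        "log2fc": log2fc,
        "p": p,
        "fdr": fdr,
    })
    df["direction"] = assign_direction(
        df["log2fc"], df["fdr"], lfc_threshold, fdr_cutoff
    ).to_numpy()
    df.attrs["lfc_threshold"] = lfc_threshold
    df.attrs["fdr_cutoff"] = fdr_cutoff
    return df


def ingest_de_table(path: str | Path, lfc_threshold: float = 0.5,
                    fdr_cutoff: float = 0.05) -> pd.DataFrame:
    """Read an externally computed DE table (feature, log2fc, p, fdr columns).

    Directions are recomputed from the thresholds so external tables follow
    the same modulation semantics as the internal stage.
    """
    df = pd.read_csv(path, sep="\t")
    aliases = {"feature": "feature_id", "gene": "feature_id", "padj": "fdr",
               "log2FoldChange": "log2fc", "pvalue": "p"}
    df = df.rename(columns=aliases)
    required = ["feature_id", "log2fc", "p", "fdr"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"DE table {path} lacks columns {missing}")
    if "base_mean" not in df.columns:
        df["base_mean"] = np.nan
    df = df[["feature_id", "base_mean", "log2fc", "p", "fdr"]].copy()
    df["feature_id"] = df["feature_id"].astype(str).str.strip()
    df["direction"] = assign_direction(
        df["log2fc"], df["fdr"], lfc_threshold, fdr_cutoff
    ).to_numpy()
    df.attrs["provenance"] = f"external:{path}"
    df.attrs["lfc_threshold"] = lfc_threshold
    df.attrs["fdr_cutoff"] = fdr_cutoff
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df[list(DE_COLUMNS)].to_csv(path, sep="\t", index=False)
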