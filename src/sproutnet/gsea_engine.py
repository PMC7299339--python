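"""A from-scratch gene set enrichment analysis engine.

Supports the two phenotype flavours the pipeline needs: a continuous
profile (a miRNA's expression, or a per-sample score) ranked by Pearson
correlation, and two-class labels ranked by signal-to-noise.  The weighted
enrichment score is the signed maximum deviation of the running sum; the
null is built either from random member sets of equal size ("geneset"
permutation, the default — appropriate when only six samples exist) or from
phenotype shuffles.  NES normalizes by the sign-matched null mean, the
permutation p is one-sided with add-one smoothing, and the FDR q follows the
sign-stratified pooled-NES ratio procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .exceptions import ConfigurationError, ContractError
from .io_formats import ExpressionMatrix, GeneSetCollection

__all__ = [
    "rank_genes",
    "enrichment_score",
    "run_gsea",
    "mirna_association_matrix",
    "AssociationMatrix",
]

_SIGMA_FLOOR_FRACTION = 0.2
_SIGMA_FLOOR_MIN = 0.2


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _continuous_metric(values: np.ndarray, profile: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero = norms == 0
    p = profile - profile.mean()
    p_norm = np.linalg.norm(p)
    if p_norm == 0:
        raise ContractError("phenotype profile has zero variance")
    r = (centered @ p) / (np.where(zero, 1.0, norms) * p_norm)
    return np.where(zero, 0.0, r), zero


def _signal_to_noise(x_pos: np.ndarray, x_neg: np.ndarray) -> np.ndarray:
    mu1, mu0 = x_pos.mean(axis=1), x_neg.mean(axis=1)
    s1 = x_pos.std(axis=1, ddof=1)
    s0 = x_neg.std(axis=1, ddof=1)
    s1 = np.maximum(s1, np.maximum(_SIGMA_FLOOR_FRACTION * np.abs(mu1), _SIGMA_FLOOR_MIN))
    s0 = np.maximum(s0, np.maximum(_SIGMA_FLOOR_FRACTION * np.abs(mu0), _SIGMA_FLOOR_MIN))
    return (mu1 - mu0) / (s1 + s0)


def rank_genes(genes: ExpressionMatrix, phenotype,
               positive_class: str | None = None) -> pd.DataFrame:
    """Rank genes against a phenotype.

    ``phenotype`` may be a continuous per-sample profile (sequence/Series in
    the matrix's sample order; metric = Pearson r) or a mapping
    sample -> class label (metric = signal-to-noise (mu1-mu0)/(s1+s0) with
    each sigma floored at max(0.2*|mu|, 0.2)).  Rows are sorted by metric
    descending, ties broken by feature id.  Zero-variance genes under a
    continuous phenotype get metric 0 and are flagged.
    """
    if isinstance(phenotype, Mapping) or (
            isinstance(phenotype, pd.Series) and phenotype.dtype == object):
        labels = pd.Series(dict(phenotype))
        labels = labels.reindex(genes.sample_ids)
        if labels.isna().any():
            raise ContractError("phenotype labels missing for some samples")
        classes = sorted(labels.unique())
        if len(classes) != 2:
            raise ContractError(f"two-class phenotype needs 2 labels, got {classes}")
        pos = positive_class if positive_class is not None else classes[0]
        if pos not in classes:
            raise ContractError(f"positive_class {pos!r} not among {classes}")
        neg = [c for c in classes if c != pos][0]
        pos_cols = labels[labels == pos].index.tolist()
        neg_cols = labels[labels == neg].index.tolist()
        if len(pos_cols) < 2 or len(neg_cols) < 2:
            raise ContractError("each class needs at least 2 samples")
        metric = _signal_to_noise(genes.values[pos_cols].to_numpy(dtype=float),
                                  genes.values[neg_cols].to_numpy(dtype=float))
        flagged = np.zeros(metric.size, dtype=bool)
        descriptor = f"two-class:{pos}-vs-{neg}"
    else:
        profile = np.asarray(pd.Series(phenotype).to_numpy(), dtype=float)
        if profile.size != genes.n_samples:
            raise ContractError("phenotype profile length must match sample count")
        metric, flagged = _continuous_metric(
            genes.values.to_numpy(dtype=float), profile)
        descriptor = "continuous"

    df = pd.DataFrame({"gene": genes.feature_ids, "metric": metric,
                       "flagged": flagged})
    df = df.sort_values(["metric", "gene"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df.attrs["phenotype"] = descriptor
    return df


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(rl: pd.DataFrame, gene_set: Sequence[str],
                     weight: float = 1.0) -> tuple[float, np.ndarray, list[str]]:
    """Weighted running-sum enrichment score of ``gene_set`` in a ranked list.

    Walking the list, a hit adds ``|metric|^weight / sum_set |metric|^weight``
    and a miss subtracts ``1/(N - N_hits)``; the ES is the signed maximum
    deviation from zero.  The leading edge holds the set members at or
    before the maximum (at or after the minimum, for negative ES).

    Returns ``(es, running_sum, leading_edge)``.
    """
    genes = rl["gene"].to_numpy()
    metrics = rl["metric"].to_numpy(dtype=float)
    members = set(map(str, gene_set))
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=genes.size)
    n = genes.size
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ContractError("gene set has no overlap with the ranked list")

    w = np.abs(metrics) ** weight
    hit_total = w[hit].sum()
    if hit_total == 0:
        # all hit metrics are exactly zero: fall back to unweighted hits
        increments = np.where(hit, 1.0 / n_hits, 0.0)
    else:
        increments = np.where(hit, w / hit_total, 0.0)
    if n_hits == n:
        running = np.cumsum(increments)
        return 1.0, running, [str(g) for g in genes]
    miss = 1.0 / (n - n_hits)
    steps = np.where(hit, increments, -miss)
    running = np.cumsum(steps)

    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        leading = [str(g) for g in genes[: i_max + 1][hit[: i_max + 1]]]
    else:
        es = float(running[i_min])
        leading = [str(g) for g in genes[i_min:][hit[i_min:]]]
    return es, running, leading


def _es_from_positions(pos: np.ndarray, absw: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many member sets given their sorted hit positions.

    ``pos`` is (n_sets, k) of 0-based positions into the ranked list, sorted
    ascending per row; ``absw`` are the |metric|^weight values of the list.
    Extrema of the running sum occur immediately after a hit (for maxima) or
    immediately before one (for minima), which is all this needs to examine.
    """
    n_sets, k = pos.shape
    if k == n:
        return np.ones(n_sets)
    w = absw[pos]
    totals = w.sum(axis=1, keepdims=True)
    fallback = totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.cumsum(w, axis=1) / totals
    if fallback.any():
        flat = np.tile(np.arange(1, k + 1) / k, (n_sets, 1))
        cum = np.where(fallback, flat, cum)
    miss = 1.0 / (n - k)
    offsets = np.arange(k)[None, :]
    after = cum - (pos - offsets) * miss          # value just after each hit
    before = np.concatenate(
        [np.zeros((n_sets, 1)), cum[:, :-1]], axis=1) - (pos - offsets) * miss
    max_dev = after.max(axis=1)
    min_dev = np.minimum(before.min(axis=1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _random_position_sets(rng: np.random.Generator, n_perm: int, n: int,
                          k: int) -> np.ndarray:
    keys = rng.random((n_perm, n))
    pos = np.argpartition(keys, k - 1, axis=1)[:, :k]
    pos.sort(axis=1)
    return pos


def _exhaustive_position_sets(n: int, k: int) -> np.ndarray:
    return np.array(list(combinations(range(n), k)), dtype=int)


@dataclass
class _SetResult:
    name: str
    size: int
    n_hits: int
    es: float
    nes: float
    p_perm: float
    leading_edge: list[str]
    null_nes: np.ndarray


def _null_stats(es_obs: float, null_es: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(nes, p_perm, normalized null) against a sign-matched null."""
    pos_null = null_es[null_es >= 0]
    neg_null = null_es[null_es < 0]
    mean_pos = pos_null.mean() if pos_null.size else np.nan
    mean_neg = np.abs(neg_null).mean() if neg_null.size else np.nan

    null_nes = np.empty_like(null_es)
    if pos_null.size:
        null_nes[null_es >= 0] = null_es[null_es >= 0] / mean_pos
    if neg_null.size:
        null_nes[null_es < 0] = null_es[null_es < 0] / mean_neg

    if es_obs >= 0:
        matched = pos_null
        nes = es_obs / mean_pos if pos_null.size else np.nan
        n_extreme = int((matched >= es_obs).sum()) if matched.size else 0
    else:
        matched = neg_null
        nes = -(np.abs(es_obs) / mean_neg) if neg_null.size else np.nan
        n_extreme = int((matched <= es_obs).sum()) if matched.size else 0
    p = (1.0 + n_extreme) / (1.0 + matched.size)
    return float(nes), float(p), null_nes


def _fdr_q(results: list[_SetResult]) -> dict[str, float]:
    """Sign-stratified FDR over the pooled normalized null."""
    obs = np.array([r.nes for r in results])
    pooled = np.concatenate([r.null_nes for r in results]) if results else np.array([])
    pooled = pooled[~np.isnan(pooled)]
    q: dict[str, float] = {}
    n_pos_null = int((pooled >= 0).sum())
    n_neg_null = int((pooled < 0).sum())
    finite = obs[~np.isnan(obs)]
    n_pos_obs = int((finite >= 0).sum())
    n_neg_obs = int((finite < 0).sum())
    for r in results:
        if math.isnan(r.nes):
            q[r.name] = float("nan")
            continue
        # add-one smoothing keeps q honest when the matched-sign null is sparse
        if r.nes >= 0:
            frac_null = (1.0 + (pooled >= r.nes).sum()) / (1.0 + n_pos_null)
            frac_obs = ((finite >= r.nes).sum() / n_pos_obs) if n_pos_obs else 1.0
        else:
            frac_null = (1.0 + (pooled <= r.nes).sum()) / (1.0 + n_neg_null)
            frac_obs = ((finite <= r.nes).sum() / n_neg_obs) if n_neg_obs else 1.0
        q[r.name] = float(min(1.0, frac_null / max(frac_obs, 1e-300)))
    return q


def run_gsea(genes: ExpressionMatrix, phenotype, collection: GeneSetCollection,
             n_perm: int = 1000, perm_type: str = "geneset", seed: int = 0,
             weight: float = 1.0, positive_class: str | None = None,
             exhaustive_limit: int = 200_000) -> pd.DataFrame:
    """GSEA over a gene-set collection.

    ``perm_type="geneset"`` draws random member sets of equal size from the
    ranked universe (exhaustively enumerated when C(N, k) does not exceed
    ``exhaustive_limit`` and is at most ``n_perm``); ``perm_type="phenotype"``
    shuffles the profile/labels and re-ranks.  Deterministic under ``seed``.

    Returns one row per set: es, nes, p_perm, fdr_q, leading_edge, n_hits.
    """
    if len(collection) == 0:
        raise ContractError("empty gene-set collection")
    if perm_type not in ("geneset", "phenotype"):
        raise ConfigurationError(f"unknown perm_type {perm_type!r}")
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    rl = rank_genes(genes, phenotype, positive_class=positive_class)
    n = len(rl)
    gene_pos = {g: i for i, g in enumerate(rl["gene"])}
    absw = np.abs(rl["metric"].to_numpy(dtype=float)) ** weight
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    overlaps: dict[str, list[int]] = {}
    for name, members in collection:
        if len(members) > n:
            raise ContractError(f"set {name!r} larger than the ranked universe")
        hit_pos = sorted(gene_pos[g] for g in members if g in gene_pos)
        if not hit_pos:
            raise ContractError(f"set {name!r} has no overlap with the ranked list")
        overlaps[name] = hit_pos

    results: list[_SetResult] = []
    if perm_type == "geneset":
        null_cache: dict[int, np.ndarray] = {}
        for name, members in collection:
            hit_pos = overlaps[name]
            k = len(hit_pos)
            es, _, leading = enrichment_score(rl, members, weight=weight)
            if k not in null_cache:
                n_comb = math.comb(n, k)
                if n_comb <= min(exhaustive_limit, n_perm):
                    pos = _exhaustive_position_sets(n, k)
                else:
                    pos = _random_position_sets(rng, n_perm, n, k)
                null_cache[k] = _es_from_positions(pos, absw, n)
            nes, p, null_nes = _null_stats(es, null_cache[k])
            results.append(_SetResult(name, len(members), k, es, nes, p,
                                      leading, null_nes))
    else:
        values = genes.values.to_numpy(dtype=float)
        null_es: dict[str, list[float]] = {name: [] for name, _ in collection}
        es_leading: dict[str, tuple[float, list[str], int]] = {}
        for name, members in collection:
            es, _, leading = enrichment_score(rl, members, weight=weight)
            es_leading[name] = (es, leading, len(overlaps[name]))
        is_two_class = isinstance(phenotype, Mapping) or (
            isinstance(phenotype, pd.Series) and phenotype.dtype == object)
        for _ in range(n_perm):
            if is_two_class:
                labels = pd.Series(dict(phenotype)).reindex(genes.sample_ids)
                shuffled = pd.Series(rng.permutation(labels.to_numpy()),
                                     index=genes.sample_ids)
                rl_p = rank_genes(genes, shuffled, positive_class=positive_class)
            else:
                profile = pd.Series(phenotype).to_numpy(dtype=float)
                rl_p = rank_genes(genes, rng.permutation(profile))
            absw_p = np.abs(rl_p["metric"].to_numpy(dtype=float)) ** weight
            pos_of = {g: i for i, g in enumerate(rl_p["gene"])}
            for name, members in collection:
                hit = np.array(sorted(pos_of[g] for g in members if g in pos_of),
                               dtype=int)[None, :]
                null_es[name].append(float(_es_from_positions(hit, absw_p, n)[0]))
        for name, members in collection:
            es, leading, k = es_leading[name]
            nes, p, null_nes = _null_stats(es, np.array(null_es[name]))
            results.append(_SetResult(name, len(members), k, es, nes, p,
                                      leading, null_nes))

    q = _fdr_q(results)
    out = pd.DataFrame({
        "set_name": [r.name for r in results],
        "size": [r.size for r in results],
        "n_hits": [r.n_hits for r in results],
        "es": [r.es for r in results],
        "nes": [r.nes for r in results],
        "p_perm": [r.p_perm for r in results],
        "fdr_q": [q[r.name] for r in results],
        "leading_edge": [r.leading_edge for r in results],
    })
    out.attrs["perm_type"] = perm_type
    out.attrs["n_perm"] = n_perm
    out.attrs["weight"] = weight
    return out


# ---------------------------------------------------------------------------
# miRNA x gene-set association matrix
# ---------------------------------------------------------------------------

@dataclass
class AssociationMatrix:
    """GSEA association of every miRNA (columns) with every gene set (rows)."""

    nes: pd.DataFrame
    fdr_q: pd.DataFrame
    masked_nes: pd.DataFrame            # sign of nes where fdr_q < threshold, else 0
    row_order: list[str]
    col_order: list[str]
    row_clusters: dict[str, int]
    core_enrichment: dict[int, list[str]]
    fdr_threshold: float


def mirna_association_matrix(mirs: ExpressionMatrix, genes: ExpressionMatrix,
                             collection: GeneSetCollection, n_perm: int = 1000,
                             seed: int = 0, weight: float = 1.0,
                             fdr_threshold: float = 0.05,
                             n_clusters: int = 5) -> AssociationMatrix:
    """One continuous-phenotype GSEA per miRNA, assembled into a matrix.

    Each miRNA's log2 profile serves as the phenotype; cells hold (NES,
    FDR q).  Rows and columns are ordered by hierarchical clustering
    (Euclidean distance, complete linkage) of the significance-masked NES
    sign matrix, and per row-cluster the union of leading-edge genes of the
    significant cells ("core enrichment") is reported.
    """
    if mirs.sample_ids != genes.sample_ids:
        raise ContractError("miRNA and gene matrices must share sample ordering")
    nes_cols, q_cols, leading = {}, {}, {}
    # one shared seed: identical miRNA profiles must give identical columns
    for mirna in mirs.feature_ids:
        profile = mirs.values.loc[mirna].to_numpy(dtype=float)
        res = run_gsea(genes, profile, collection, n_perm=n_perm,
                       perm_type="geneset", seed=seed, weight=weight)
        res = res.set_index("set_name")
        nes_cols[mirna] = res["nes"]
        q_cols[mirna] = res["fdr_q"]
        leading[mirna] = res["leading_edge"].to_dict()

    nes = pd.DataFrame(nes_cols)
    fdr_q = pd.DataFrame(q_cols)
    significant = fdr_q < fdr_threshold
    masked = pd.DataFrame(np.where(significant, np.sign(nes), 0.0),
                          index=nes.index, columns=nes.columns)

    row_order = masked.index.tolist()
    col_order = masked.columns.tolist()
    row_clusters = {name: 1 for name in row_order}
    if masked.shape[0] > 1:
        d = pdist(masked.to_numpy(), metric="euclidean")
        link = hierarchy.linkage(d, method="complete")
        row_order = [masked.index[i] for i in hierarchy.leaves_list(link)]
        k = min(n_clusters, masked.shape[0])
        assignment = hierarchy.fcluster(link, t=k, criterion="maxclust")
        row_clusters = dict(zip(masked.index, (int(c) for c in assignment)))
    if masked.shape[1] > 1:
        d = pdist(masked.to_numpy().T, metric="euclidean")
        link = hierarchy.linkage(d, method="complete")
        col_order = [masked.columns[i] for i in hierarchy.leaves_list(link)]

    core: dict[int, set[str]] = {}
    for set_name, cluster in row_clusters.items():
        for mirna in masked.columns:
            if significant.loc[set_name, mirna]:
                core.setdefault(cluster, set()).update(leading[mirna][set_name])
    core_enrichment = {c: sorted(g) for c, g in core.items()}

    return AssociationMatrix(nes=nes, fdr_q=fdr_q, masked_nes=masked,
                             row_order=row_order, col_order=col_order,
                             row_clusters=row_clusters,
                             core_enrichment=core_enrichment,
                             fdr_threshold=fdr_threshold)
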