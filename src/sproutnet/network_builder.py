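"""Assembly and topology analysis of the signed bipartite regulatory network.

An edge (miRNA, gene) enters the network only when four filters agree: the
pair is predicted (per the requested conservation mode), its correlator is
negative and significant, and both endpoints are differentially expressed
with opposite directions.  The result is an undirected bipartite graph whose
miRNA out-degrees and gene in-degrees can be tested against the discrete
power law p(x) ~ x^-alpha using maximum likelihood over candidate xmin
values (Hurwitz-zeta normalization, KS-minimizing xmin) with a
semi-parametric bootstrap goodness of fit; the fit is deemed plausible when
the bootstrap p exceeds 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .exceptions import ConfigurationError, ContractError

__all__ = [
    "build_network",
    "network_summary",
    "PowerLawFit",
    "fit_power_law",
    "extract_subnetwork",
    "shared_target_mirnas",
]


def build_network(de_mir: pd.DataFrame, de_gene: pd.DataFrame,
                  ct: pd.DataFrame, pt: pd.DataFrame,
                  p_threshold: float = 0.05,
                  conservation_mode: str = "conserved_only",
                  p_column: str = "p_analytic",
                  require_de: bool = True) -> nx.Graph:
    """Assemble the signed bipartite miRNA-target network.

    An edge (m, g) exists iff (m, g) is predicted (conserved only, or both
    classes per ``conservation_mode``), r(m, g) < 0 with p < ``p_threshold``
    (from ``p_column``), and — unless ``require_de`` is switched off — both
    endpoints are differentially expressed with opposite directions.
    Isolated nodes are dropped; an empty result is permitted (warning).
    """
    if conservation_mode not in ("conserved_only", "both"):
        raise ConfigurationError(f"unknown conservation_mode {conservation_mode!r}")
    if p_column not in ct.columns:
        raise ConfigurationError(f"correlation table has no column {p_column!r}")

    preds = pt if conservation_mode == "both" else pt[pt["conservation"] == "conserved"]
    # best (max percentile) record per pair decides the edge attributes
    preds = (preds.sort_values("percentile", ascending=False)
             .drop_duplicates(subset=["mirna", "gene"]))

    de_mir_idx = de_mir.set_index("feature_id")
    de_gene_idx = de_gene.set_index("feature_id")
    corr = ct[~ct["undefined"]].set_index(["mirna", "gene"])

    net = nx.Graph()
    for row in preds.itertuples(index=False):
        m, g = row.mirna, row.gene
        try:
            crec = corr.loc[(m, g)]
        except KeyError:
            continue
        r = float(crec["r"])
        p = float(crec[p_column])
        if not (r < 0 and p < p_threshold):
            continue
        if m not in de_mir_idx.index or g not in de_gene_idx.index:
            if require_de:
                continue
            m_dir = m_lfc = g_dir = g_lfc = None
        else:
            m_dir = de_mir_idx.at[m, "direction"]
            g_dir = de_gene_idx.at[g, "direction"]
            m_lfc = float(de_mir_idx.at[m, "log2fc"])
            g_lfc = float(de_gene_idx.at[g, "log2fc"])
            if require_de:
                if m_dir == "ns" or g_dir == "ns":
                    continue
                if m_dir == g_dir:
                    continue
        net.add_node(m, type="mirna", direction=m_dir, log2fc=m_lfc)
        net.add_node(g, type="gene", direction=g_dir, log2fc=g_lfc)
        net.add_edge(m, g, r=r, p=p, conservation=row.conservation,
                     percentile=float(row.percentile))
    if net.number_of_edges() == 0:
        warnings.warn("network is empty after filtering", stacklevel=2)
    return net


def network_summary(net: nx.Graph, n_hubs: int = 10) -> dict:
    """Node/edge counts, components, degree sequences and hub miRNAs."""
    mirnas = sorted(n for n, d in net.nodes(data=True) if d.get("type") == "mirna")
    genes = sorted(n for n, d in net.nodes(data=True) if d.get("type") == "gene")
    out_degrees = {m: net.degree(m) for m in mirnas}
    in_degrees = {g: net.degree(g) for g in genes}
    components = sorted((sorted(c) for c in nx.connected_components(net)),
                        key=lambda c: (-len(c), c))
    hubs = sorted(out_degrees.items(), key=lambda kv: (-kv[1], kv[0]))[:n_hubs]
    return {
        "n_mirna": len(mirnas),
        "n_gene": len(genes),
        "n_edges": net.number_of_edges(),
        "n_components": len(components),
        "component_sizes": [len(c) for c in components],
        "components": components,
        "mirna_out_degrees": out_degrees,
        "gene_in_degrees": in_degrees,
        "hubs": [{"mirna": m, "out_degree": d} for m, d in hubs],
    }


# ---------------------------------------------------------------------------
# discrete power-law fitting
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    alpha: float
    xmin: int
    ks_d: float
    p_gof: float | None
    n_tail: int
    n_bootstrap: int
    small_tail: bool = False     # fewer than 10 points at or above xmin
    degenerate: bool = False


def _alpha_mle(tail: np.ndarray, xmin: int, bounds=(1.01, 20.0)) -> float:
    n = tail.size
    logsum = np.log(tail).sum()

    def nll(a: float) -> float:
        return n * np.log(zeta(a, xmin)) + a * logsum

    res = minimize_scalar(nll, bounds=bounds, method="bounded",
                          options={"xatol": 1e-5})
    return float(res.x)


def _ks_distance(tail: np.ndarray, alpha: float, xmin: int) -> float:
    # ECDF vs fitted CDF over the full integer support of the tail
    xs = np.arange(xmin, tail.max() + 1)
    ecdf = np.searchsorted(np.sort(tail), xs, side="right") / tail.size
    cdf = 1.0 - zeta(alpha, xs + 1.0) / zeta(alpha, xmin)
    return float(np.max(np.abs(ecdf - cdf)))


def _fit_tail(degrees: np.ndarray, max_candidates: int = 75,
              min_tail_fraction: float = 0.05,
              ) -> tuple[float, int, float, int]:
    """Best (alpha, xmin, ks_d, n_tail) over candidate xmin values.

    Candidate xmins are the unique observed degrees whose tail retains at
    least ``min_tail_fraction`` of the sample (and never fewer than 2
    points): the KS-minimizing xmin otherwise drifts into sparse tails where
    the fit is unfalsifiable.
    """
    uniq = np.unique(degrees)
    floor = max(2, int(np.ceil(min_tail_fraction * degrees.size)))
    candidates = np.array([x for x in uniq if (degrees >= x).sum() >= floor])
    if candidates.size == 0:
        candidates = np.array([x for x in uniq if (degrees >= x).sum() >= 2])
    if candidates.size == 0:
        candidates = uniq[:1]
    if candidates.size > max_candidates:
        idx = np.unique(np.linspace(0, candidates.size - 1, max_candidates).astype(int))
        candidates = candidates[idx]
    best = None
    for xmin in candidates:
        tail = degrees[degrees >= xmin]
        alpha = _alpha_mle(tail, int(xmin))
        d = _ks_distance(tail, alpha, int(xmin))
        if best is None or d < best[2]:
            best = (alpha, int(xmin), d, tail.size)
    return best


def _power_law_sampler(alpha: float, xmin: int, table_max: int = 100_000):
    """Exact inverse-CDF sampler for the fitted discrete power law."""
    xs = np.arange(xmin, table_max + 1)
    cdf = 1.0 - zeta(alpha, xs + 1.0) / zeta(alpha, xmin)

    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        u = rng.random(size)
        idx = np.minimum(np.searchsorted(cdf, u, side="right"), xs.size - 1)
        return xs[idx]

    return draw


def fit_power_law(degrees, n_bootstrap: int = 1000, seed: int = 0,
                  max_candidates: int = 75) -> PowerLawFit:
    """Fit a discrete power law to a degree sequence, with bootstrap GOF.

    For each candidate xmin (the unique observed degrees, thinned to
    ``max_candidates``), alpha maximizes the discrete log-likelihood with
    Hurwitz-zeta normalization; the chosen xmin minimizes the KS distance
    between the tail ECDF and the fitted CDF.  The goodness-of-fit p is the
    fraction of semi-parametric bootstrap replicates (observed values below
    xmin, fitted model at and above it, refit from scratch) whose KS distance
    is at least the observed one.  Deterministic under ``seed``.
    """
    degrees = np.asarray(degrees, dtype=int)
    if degrees.size < 10:
        raise ContractError("need at least 10 degree values")
    if (degrees < 1).any():
        raise ContractError("degrees must be positive integers")
    if np.unique(degrees).size == 1:
        return PowerLawFit(alpha=float("nan"), xmin=int(degrees[0]),
                           ks_d=float("nan"), p_gof=None, n_tail=degrees.size,
                           n_bootstrap=0, degenerate=True)

    alpha, xmin, ks_d, n_tail = _fit_tail(degrees, max_candidates)
    small_tail = n_tail < 10
    if small_tail:
        warnings.warn(f"only {n_tail} tail points at xmin={xmin}", stacklevel=2)

    p_gof = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        draw = _power_law_sampler(alpha, xmin)
        below = degrees[degrees < xmin]
        p_below = below.size / degrees.size
        n = degrees.size
        exceed = 0
        for _ in range(n_bootstrap):
            n_below = rng.binomial(n, p_below) if below.size else 0
            parts = []
            if n_below:
                parts.append(rng.choice(below, size=n_below, replace=True))
            parts.append(draw(rng, n - n_below))
            synth = np.concatenate(parts)
            if np.unique(synth).size == 1:
                continue
            _, _, d_b, _ = _fit_tail(synth, max_candidates)
            if d_b >= ks_d:
                exceed += 1
        p_gof = exceed / n_bootstrap
    return PowerLawFit(alpha=alpha, xmin=xmin, ks_d=ks_d, p_gof=p_gof,
                       n_tail=n_tail, n_bootstrap=n_bootstrap,
                       small_tail=small_tail)


# ---------------------------------------------------------------------------
# subnetworks
# ---------------------------------------------------------------------------

def extract_subnetwork(net: nx.Graph, seeds) -> nx.Graph:
    """Induced subgraph around seed nodes.

    Gene seeds pull in the seed genes plus all their targeting miRNAs;
    miRNA seeds pull in the seed miRNAs plus all their target genes.  Edge
    attributes are preserved.  Seeds absent from the network are ignored
    (empty result with a warning when none is present).
    """
    seeds = [str(s) for s in seeds]
    if not seeds:
        raise ContractError("seed list is empty")
    present = [s for s in seeds if s in net]
    if not present:
        warnings.warn("no seed node present in the network", stacklevel=2)
        return nx.Graph()
    nodes = set(present)
    for s in present:
        nodes.update(net.neighbors(s))
    return net.subgraph(nodes).copy()


def shared_target_mirnas(net: nx.Graph, hub: str, candidates) -> list[tuple[str, int]]:
    """miRNAs among ``candidates`` sharing at least one target gene with ``hub``.

    Returns (miRNA, shared-target count) sorted by count descending, ties by id.
    """
    if hub not in net:
        raise ContractError(f"hub {hub!r} not in network")
    hub_targets = set(net.neighbors(hub))
    out = []
    for c in candidates:
        c = str(c)
        if c == hub or c not in net:
            continue
        shared = hub_targets & set(net.neighbors(c))
        if shared:
            out.append((c, len(shared)))
    return sorted(out, key=lambda kv: (-kv[1], kv[0]))
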