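import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sproutnet as sn

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def expression_matrix(values, condition=None, kind="gene", **kw):
    """Build an ExpressionMatrix from a dict/DataFrame of feature -> values."""
    df = pd.DataFrame(values).T if isinstance(values, dict) else pd.DataFrame(values)
    if condition is not None and isinstance(df.columns, pd.RangeIndex):
        df.columns = list(condition)
    if condition is None:
        n = df.shape[1]
        half = n // 2
        cols = [f"ctrl_{i+1}" for i in range(half)] + \
               [f"trt_{i+1}" for i in range(n - half)]
        df.columns = cols
        condition = {c: ("control" if c.startswith("ctrl") else "treated")
                     for c in cols}
    return sn.ExpressionMatrix(df.astype(float), condition, kind, **kw)


@pytest.fixture(scope="session")
def default_run():
    """One full synthetic run at the reference study conditions, processed
    through DE, correlation and network assembly."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mir, gene, preds, coll, truth = sn.generate_experiment(
            sn.SyntheticConfig(seed=0))
        mir_n = sn.normalize_counts(sn.filter_expressed(mir))
        gene_n = sn.normalize_counts(sn.filter_expressed(gene))
        de_mir = sn.differential_expression(mir_n)
        de_gene = sn.differential_expression(gene_n)
        ct = sn.pairwise_correlation(mir_n.to_log2(), gene_n.to_log2())
        net = sn.build_network(de_mir, de_gene, ct, preds)
    return {
        "mir": mir, "gene": gene, "preds": preds, "collection": coll,
        "truth": truth, "mir_n": mir_n, "gene_n": gene_n,
        "de_mir": de_mir, "de_gene": de_gene, "ct": ct, "net": net,
    }


def recovered_edges(net):
    """Edge set of a network oriented (mirna, gene)."""
    edges = set()
    for u, v in net.edges():
        if net.nodes[u].get("type") == "mirna":
            edges.add((u, v))
        else:
            edges.add((v, u))
    return edges


@pytest.fixture
def toy_tables():
    """The printed toy inputs for network assembly: two miRNAs with opposite
    regulation, three genes, three conserved predictions, three correlators.
    Hand-applying all four edge filters leaves exactly {(m1,g1), (m2,g2)}."""
    de_mir = pd.DataFrame({
        "feature_id": ["m1", "m2"],
        "base_mean": [100.0, 100.0],
        "log2fc": [1.0, -1.0],
        "p": [1e-4, 1e-4],
        "fdr": [1e-3, 1e-3],
        "direction": ["up", "down"],
    })
    de_gene = pd.DataFrame({
        "feature_id": ["g1", "g2", "g3"],
        "base_mean": [50.0, 50.0, 50.0],
        "log2fc": [-1.2, 0.9, -0.8],
        "p": [1e-4, 1e-4, 1e-4],
        "fdr": [1e-3, 1e-3, 1e-3],
        "direction": ["down", "up", "down"],
    })
    ct = pd.DataFrame({
        "mirna": ["m1", "m1", "m2"],
        "gene": ["g1", "g2", "g2"],
        "r": [-0.95, -0.20, -0.92],
        "p_analytic": [0.004, 0.70, 0.01],
        "undefined": [False, False, False],
    })
    pt = pd.DataFrame({
        "mirna": ["m1", "m1", "m2"],
        "gene": ["g1", "g2", "g2"],
        "conservation": ["conserved"] * 3,
        "percentile": [60.0, 70.0, 55.0],
    })
    return de_mir, de_gene, ct, pt


@pytest.fixture
def toy_network(toy_tables):
    return sn.build_network(*toy_tables)
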