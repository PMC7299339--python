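"""Synthetic two-condition miRNA/mRNA experiments with planted regulation.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomial counts over two conditions with a handful of
replicates, a small set of regulator miRNAs shifted up or down on VEGF-style
stimulation, target genes shifted in the opposite direction (miRNA
repression induces anti-correlation across conditions), a TargetScan-style
prediction table containing every planted interaction plus decoy
predictions, and a gene-set collection aligned with the planted modules.
Alongside the data it returns the ground-truth key used by every recovery
test.

The negative binomial is parameterized by mean ``mu`` and dispersion ``d``
with variance ``mu + d * mu**2`` (the standard RNA-seq noise model).  Every
artifact draws from its own random stream split from the master seed, so
adding one output never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io_formats import ExpressionMatrix, GeneSetCollection

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_experiment",
    "generate_cohort",
    "generate_ct_card",
    "sample_discrete_power_law",
]


@dataclass
class SyntheticConfig:
    """Parameters of a planted two-condition experiment.

    Defaults are the reference study conditions used throughout the test
    suite: 40 miRNAs, 400 genes, 3+3 replicates, 5 upregulated and 5
    downregulated regulator miRNAs jointly planting 300 edges, an effect of
    |log2FC| = 2, NB dispersion 0.05, and 3 decoy predictions per planted one.
    """

    n_mirna: int = 40
    n_gene: int = 400
    n_regulator_up: int = 5
    n_regulator_down: int = 5
    out_degree_alpha: float = 2.5
    n_planted_edges: int | None = 300
    effect_lfc: float = 2.0
    nb_dispersion: float = 0.05
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    replicates_per_condition: int = 3
    decoy_prediction_ratio: float = 3.0
    n_decoy_predictions: int | None = None
    decoy_nonconserved_fraction: float = 0.5
    target_pool_fraction: float = 0.15
    size_factor_spread: float = 0.2
    n_random_sets: int = 8
    random_set_size: tuple[int, int] = (20, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regulator_up + self.n_regulator_down > self.n_mirna:
            raise ConfigurationError("regulator counts exceed n_mirna")
        if self.out_degree_alpha <= 1:
            raise ConfigurationError("out_degree_alpha must be > 1")
        if self.replicates_per_condition < 2:
            raise ConfigurationError("need at least 2 replicates per condition")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.effect_lfc < 0:
            raise ConfigurationError("effect_lfc must be >= 0")
        if self.decoy_prediction_ratio < 0:
            raise ConfigurationError("decoy_prediction_ratio must be >= 0")
        if not 0 < self.target_pool_fraction <= 0.5:
            raise ConfigurationError("target_pool_fraction must be in (0, 0.5]")
        if not 0 <= self.decoy_nonconserved_fraction <= 1:
            raise ConfigurationError("decoy_nonconserved_fraction must be in [0, 1]")
        if not 0 <= self.size_factor_spread < 1:
            raise ConfigurationError("size_factor_spread must be in [0, 1)")
        pool = int(round(self.target_pool_fraction * self.n_gene))
        demand = self.n_planted_edges
        if demand is not None:
            n_reg = self.n_regulator_up + self.n_regulator_down
            if n_reg == 0 and demand > 0:
                raise ConfigurationError("planted edges requested but no regulators")
            if n_reg and demand > 0:
                # each direction's edges must fit its target pool
                per_dir_cap_up = self.n_regulator_up * pool
                per_dir_cap_down = self.n_regulator_down * pool
                if demand > per_dir_cap_up + per_dir_cap_down:
                    raise ConfigurationError(
                        f"{demand} planted edges exceed target-slot capacity "
                        f"{per_dir_cap_up + per_dir_cap_down}"
                    )


@dataclass
class SyntheticTruth:
    """Ground-truth key for a synthetic run."""

    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    mirna_direction: dict[str, str] = field(default_factory=dict)
    gene_direction: dict[str, str] = field(default_factory=dict)
    module_sets: dict[str, list[str]] = field(default_factory=dict)
    cohort_beta: float | None = None
    latent_score: pd.Series | None = None
    response_labels: pd.Series | None = None
    shifted_assays: list[str] = field(default_factory=list)
    reference_assays: list[str] = field(default_factory=list)


def sample_discrete_power_law(rng: np.random.Generator, alpha: float,
                              size: int, xmin: int = 1,
                              table_max: int = 100_000) -> np.ndarray:
    """Draw from the discrete power law p(x) ~ x^-alpha, x >= xmin.

    Uses exact inverse-CDF sampling over a tabulated support up to
    ``table_max`` (mass beyond is negligible for alpha > 1.5 and is capped).
    """
    from scipy.special import zeta

    if alpha <= 1:
        raise ConfigurationError("power-law exponent must be > 1")
    xs = np.arange(xmin, table_max + 1)
    # survival beyond x: zeta(alpha, x+1) / zeta(alpha, xmin)
    norm = zeta(alpha, xmin)
    cdf = 1.0 - zeta(alpha, xs + 1.0) / norm
    u = rng.random(size)
    idx = np.searchsorted(cdf, u, side="right")
    idx = np.minimum(idx, len(xs) - 1)
    return xs[idx]


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance mu + d*mu^2 (Poisson at d=0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _draw_out_degrees(rng: np.random.Generator, n_reg: int, alpha: float,
                      pool_size: int, total: int | None) -> np.ndarray:
    """Out-degree per regulator: i.i.d. discrete power-law draws, capped at the
    pool size; when ``total`` is given the sequence is adjusted to sum to it."""
    if n_reg == 0:
        return np.zeros(0, dtype=int)
    deg = np.minimum(sample_discrete_power_law(rng, alpha, n_reg), pool_size)
    if total is None:
        return deg
    deg = deg.astype(int)
    # proportional rescale, then greedy fix-up to hit the exact total
    scale = total / max(deg.sum(), 1)
    deg = np.maximum(1, np.minimum(pool_size, np.round(deg * scale).astype(int)))
    while deg.sum() > total:
        deg[int(np.argmax(deg))] -= 1
    while deg.sum() < total:
        candidates = np.flatnonzero(deg < pool_size)
        if candidates.size == 0:
            raise ConfigurationError("target-slot capacity exhausted")
        deg[candidates[int(rng.integers(candidates.size))]] += 1
    return deg


def generate_experiment(config: SyntheticConfig | None = None,
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix,
                                   pd.DataFrame, GeneSetCollection, SyntheticTruth]:
    """Generate a full synthetic experiment plus its ground-truth key.

    Returns ``(mirna_counts, gene_counts, predictions, collection, truth)``.
    Identical config (including seed) gives identical output.
    """
    cfg = config if config is not None else SyntheticConfig()
    master = np.random.SeedSequence(cfg.seed)
    (ss_structure, ss_mir, ss_gene, ss_pred, ss_sets) = master.spawn(5)
    rng_structure = np.random.default_rng(ss_structure)
    rng_mir = np.random.default_rng(ss_mir)
    rng_gene = np.random.default_rng(ss_gene)
    rng_pred = np.random.default_rng(ss_pred)
    rng_sets = np.random.default_rng(ss_sets)

    mirna_ids = [f"miR-{i+1:03d}" for i in range(cfg.n_mirna)]
    gene_ids = [f"G{i+1:04d}" for i in range(cfg.n_gene)]
    reps = cfg.replicates_per_condition
    samples = [f"ctrl_{i+1}" for i in range(reps)] + [f"trt_{i+1}" for i in range(reps)]
    condition = {s: ("control" if s.startswith("ctrl") else "treated") for s in samples}

    # --- planted structure ----------------------------------------------------
    up_regs = mirna_ids[: cfg.n_regulator_up]
    down_regs = mirna_ids[cfg.n_regulator_up: cfg.n_regulator_up + cfg.n_regulator_down]
    pool = int(round(cfg.target_pool_fraction * cfg.n_gene))
    down_pool = gene_ids[:pool]                 # targets of up regulators
    up_pool = gene_ids[pool: 2 * pool]          # targets of down regulators

    total = cfg.n_planted_edges
    n_reg = len(up_regs) + len(down_regs)
    if total is not None and n_reg:
        total_up = int(round(total * len(up_regs) / n_reg))
        total_down = total - total_up
    else:
        total_up = total_down = None
    deg_up = _draw_out_degrees(rng_structure, len(up_regs), cfg.out_degree_alpha,
                               pool, total_up)
    deg_down = _draw_out_degrees(rng_structure, len(down_regs), cfg.out_degree_alpha,
                                 pool, total_down)

    truth = SyntheticTruth()
    truth.mirna_direction = {m: "null" for m in mirna_ids}
    truth.gene_direction = {g: "null" for g in gene_ids}
    for m in up_regs:
        truth.mirna_direction[m] = "up"
    for m in down_regs:
        truth.mirna_direction[m] = "down"

    for regs, degs, target_pool, gene_dir in (
        (up_regs, deg_up, down_pool, "down"),
        (down_regs, deg_down, up_pool, "up"),
    ):
        for m, k in zip(regs, degs):
            targets = rng_structure.choice(target_pool, size=int(k), replace=False)
            for g in targets:
                truth.planted_edges.add((m, str(g)))
                truth.gene_direction[str(g)] = gene_dir

    truth.module_sets = {
        "planted_down_module": sorted(g for g, d in truth.gene_direction.items() if d == "down"),
        "planted_up_module": sorted(g for g, d in truth.gene_direction.items() if d == "up"),
    }
    truth.module_sets = {k: v for k, v in truth.module_sets.items() if v}

    # --- counts ---------------------------------------------------------------
    def make_counts(rng: np.random.Generator, ids: Sequence[str], kind: str,
                    direction: dict[str, str]) -> ExpressionMatrix:
        base_mu = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                                    size=len(ids))
        shift = np.array([{"up": cfg.effect_lfc, "down": -cfg.effect_lfc,
                           "null": 0.0}[direction[f]] for f in ids])
        mu_ctrl = base_mu
        mu_trt = base_mu * 2.0 ** shift
        sf = 1.0 + rng.uniform(-cfg.size_factor_spread, cfg.size_factor_spread,
                               size=len(samples))
        mu = np.column_stack([mu_ctrl] * reps + [mu_trt] * reps) * sf[None, :]
        counts = _nb_counts(rng, mu, cfg.nb_dispersion)
        values = pd.DataFrame(counts, index=list(ids), columns=samples, dtype=float)
        return ExpressionMatrix(values, dict(condition), kind)

    mir_m = make_counts(rng_mir, mirna_ids, "mirna", truth.mirna_direction)
    gene_m = make_counts(rng_gene, gene_ids, "gene", truth.gene_direction)

    # --- prediction table -----------------------------------------------------
    records = [
        {"mirna": m, "gene": g, "conservation": "conserved",
         "percentile": 50.0 + 50.0 * (1.0 - rng_pred.random())}
        for m, g in sorted(truth.planted_edges)
    ]
    n_planted = len(truth.planted_edges)
    if cfg.n_decoy_predictions is not None:
        n_decoy = cfg.n_decoy_predictions
    else:
        n_decoy = int(round(cfg.decoy_prediction_ratio * n_planted))
    decoys: set[tuple[str, str]] = set()
    max_decoys = cfg.n_mirna * cfg.n_gene - n_planted
    n_decoy = min(n_decoy, max_decoys)
    while len(decoys) < n_decoy:
        m = mirna_ids[int(rng_pred.integers(cfg.n_mirna))]
        g = gene_ids[int(rng_pred.integers(cfg.n_gene))]
        if (m, g) not in truth.planted_edges:
            decoys.add((m, g))
    decoy_list = sorted(decoys)
    n_noncons = int(round(cfg.decoy_nonconserved_fraction * len(decoy_list)))
    noncons_idx = set(
        rng_pred.choice(len(decoy_list), size=n_noncons, replace=False).tolist()
    ) if decoy_list else set()
    for i, (m, g) in enumerate(decoy_list):
        if i in noncons_idx:
            records.append({"mirna": m, "gene": g, "conservation": "nonconserved",
                            "percentile": 90.0 + 10.0 * (1.0 - rng_pred.random())})
        else:
            records.append({"mirna": m, "gene": g, "conservation": "conserved",
                            "percentile": 50.0 + 50.0 * (1.0 - rng_pred.random())})
    predictions = pd.DataFrame.from_records(
        records, columns=["mirna", "gene", "conservation", "percentile"])

    # --- gene sets ------------------------------------------------------------
    sets = {name: list(genes) for name, genes in truth.module_sets.items()}
    lo, hi = cfg.random_set_size
    for i in range(cfg.n_random_sets):
        size = int(rng_sets.integers(lo, hi + 1))
        size = min(size, cfg.n_gene)
        members = rng_sets.choice(gene_ids, size=size, replace=False)
        sets[f"random_set_{i+1:02d}"] = sorted(str(g) for g in members)
    collection = GeneSetCollection(sets, {k: "synthetic" for k in sets})

    return mir_m, gene_m, predictions, collection, truth


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def generate_cohort(n_samples: int, signature_genes: Sequence[str],
                    module_genes: Sequence[str], beta: float, noise_sd: float,
                    responder_effect: float, seed: int,
                    signature_loading: float = 1.0,
                    module_shared_noise_sd: float = 0.8,
                    n_background: int = 200,
                    responder_fraction: float = 0.5,
                    ) -> tuple[ExpressionMatrix, list[str], pd.Series, SyntheticTruth]:
    """Generate a tumor-cohort expression matrix with a latent angiogenesis score.

    Per sample, a latent score ``z ~ N(0, 1)`` drives the endothelial
    signature genes (loading ``signature_loading``) and the module genes
    (loading ``beta``).  Module genes additionally share a per-sample noise
    component (``module_shared_noise_sd``) so that the module *mean* does not
    trivially converge to ``z`` when many module genes are averaged —
    mimicking stromal-content confounding in bulk tumor data.  Responders
    (label 1) receive ``+responder_effect`` on the module genes.

    Returns ``(cohort, signature_genes, response_labels, truth)``.
    """
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be > 0")
    if n_samples < 10:
        raise ConfigurationError("n_samples must be >= 10")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples = [f"T{i+1:04d}" for i in range(n_samples)]
    z = rng.standard_normal(n_samples)
    shared = rng.standard_normal(n_samples) * module_shared_noise_sd

    labels = np.zeros(n_samples, dtype=int)
    n_resp = int(round(responder_fraction * n_samples))
    resp_idx = rng.choice(n_samples, size=n_resp, replace=False)
    labels[resp_idx] = 1

    signature_genes = [str(g) for g in signature_genes]
    module_genes = [str(g) for g in module_genes]
    background = [f"BG{i+1:04d}" for i in range(n_background)]

    rows: dict[str, np.ndarray] = {}
    for g in signature_genes:
        rows[g] = signature_loading * z + rng.standard_normal(n_samples) * noise_sd
    for g in module_genes:
        base = beta * z + shared + rng.standard_normal(n_samples) * noise_sd
        rows[g] = base + responder_effect * labels
    for g in background:
        rows.setdefault(g, rng.standard_normal(n_samples) * noise_sd)

    values = pd.DataFrame(rows, index=samples).T
    condition = {s: ("responder" if l else "nonresponder")
                 for s, l in zip(samples, labels)}
    cohort = ExpressionMatrix(values, condition, "gene", normalized=True)

    truth = SyntheticTruth(
        cohort_beta=beta,
        latent_score=pd.Series(z, index=samples, name="latent_score"),
        response_labels=pd.Series(labels, index=samples, name="responder"),
        module_sets={"cohort_module": list(module_genes)},
    )
    return cohort, signature_genes, truth.response_labels, truth


# ---------------------------------------------------------------------------
# qPCR card generator
# ---------------------------------------------------------------------------

def generate_ct_card(n_mirna: int, shifted_ids: Sequence[str], shift_ddct: float,
                     seed: int, noise_sd: float = 0.0, n_replicates: int = 2,
                     base_ct_mean: float = 26.0, base_ct_sd: float = 2.0,
                     ) -> tuple[pd.DataFrame, dict[str, str], SyntheticTruth]:
    """Generate a TaqMan-card-style Ct table over two conditions.

    The card carries ``n_mirna`` miRNA assays plus two never-shifted
    reference assays (returned in the truth) against which ΔCt normalization
    is exact.  Assays in ``shifted_ids`` are offset by ``shift_ddct`` Ct
    cycles in the treated condition (positive shift = lower expression);
    all others are planted null.

    Returns ``(ct_table, condition_map, truth)`` where ``ct_table`` is a wide
    assays x samples DataFrame of Ct values.
    """
    if not math.isfinite(shift_ddct):
        raise ConfigurationError("shift_ddct must be finite")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    assays = [f"miR-{i+1:03d}" for i in range(n_mirna)]
    shifted = [str(s) for s in shifted_ids]
    unknown = set(shifted) - set(assays)
    if unknown:
        raise ConfigurationError(f"shifted ids not on the card: {sorted(unknown)}")
    refs = ["ref-A", "ref-B"]
    samples = [f"ctrl_{i+1}" for i in range(n_replicates)] + \
              [f"trt_{i+1}" for i in range(n_replicates)]
    condition = {s: ("control" if s.startswith("ctrl") else "treated")
                 for s in samples}

    base = rng.normal(base_ct_mean, base_ct_sd, size=n_mirna + len(refs))
    table = np.tile(base[:, None], (1, len(samples)))
    all_assays = assays + refs
    shift_vec = np.array([shift_ddct if a in shifted else 0.0 for a in all_assays])
    treated_cols = [i for i, s in enumerate(samples) if condition[s] == "treated"]
    table[:, treated_cols] += shift_vec[:, None]
    if noise_sd > 0:
        table = table + rng.normal(0.0, noise_sd, size=table.shape)
    ct_table = pd.DataFrame(table, index=all_assays, columns=samples)

    truth = SyntheticTruth(shifted_assays=shifted, reference_assays=refs)
    return ct_table, condition, truth
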