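"""Readers and writers for every external representation the pipeline touches.

The on-disk dialect is deliberately plain: tab-separated UTF-8 text with "."
as the decimal mark and no quoting.  Counts tables carry sample ids in the
header row and feature ids in the first column (whose own header cell is
ignored).  Gene and miRNA identifiers are compared case-sensitively after
whitespace stripping; no symbol aliasing is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ContractError, FormatError

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "PREDICTION_COLUMNS",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_predictions",
    "write_predictions",
    "write_network",
    "read_network",
]

#: columns of a prediction table (a plain :class:`pandas.DataFrame`)
PREDICTION_COLUMNS = ("mirna", "gene", "conservation", "percentile")

_CONSERVATION_CLASSES = ("conserved", "nonconserved")


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix with per-sample condition labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
    condition
        Mapping sample id -> condition label (``"control"``/``"treated"`` for
        the two-condition sprouting design; cohort matrices may use other
        labels such as responder classes).
    kind
        ``"mirna"`` or ``"gene"``.
    normalized
        ``False`` for raw counts; set by :func:`sproutnet.diffexpr.normalize_counts`.
    log_scale
        ``True`` once values are log2(x+1) transformed.
    """

    values: pd.DataFrame
    condition: dict[str, str]
    kind: str
    normalized: bool = False
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("mirna", "gene"):
            raise ConfigurationError(f"unknown matrix kind {self.kind!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dupes}")
        if cols.duplicated().any():
            raise FormatError(f"duplicate sample ids: {cols[cols.duplicated()].tolist()}")
        missing = [s for s in cols if s not in self.condition]
        if missing:
            raise ConfigurationError(f"samples missing a condition label: {missing}")
        self.condition = {s: self.condition[s] for s in cols}
        labels = pd.Series(self.condition)
        for label, count in labels.value_counts().items():
            if count < 2:
                raise ConfigurationError(
                    f"condition {label!r} has {count} sample(s); at least 2 required"
                )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise FormatError("expression values must be finite")
        if not self.normalized and (arr < 0).any():
            raise FormatError("raw counts must be non-negative")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, label: str) -> list[str]:
        return [s for s, c in self.condition.items() if c == label]

    def condition_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.condition.values():
            seen.setdefault(c)
        return list(seen)

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [f for f in self.values.index if f in set(feature_ids)]
        return ExpressionMatrix(
            self.values.loc[keep], dict(self.condition), self.kind,
            normalized=self.normalized, log_scale=self.log_scale,
        )

    def to_log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """Return a log2(x + pseudocount) transformed copy."""
        if self.log_scale:
            return self
        return ExpressionMatrix(
            np.log2(self.values + pseudocount), dict(self.condition), self.kind,
            normalized=self.normalized, log_scale=True,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty member lists,
    no duplicated gene within a set."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} contains duplicated genes")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# counts tables
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, condition_map: Mapping[str, str], kind: str,
                normalized: bool = False) -> ExpressionMatrix:
    """Read a counts TSV (header row of sample ids, first column feature ids).

    Row order of the file is preserved.  Raises :class:`FormatError` for
    duplicate ids or non-numeric cells and :class:`ConfigurationError` when a
    sample has no entry in ``condition_map``.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse counts table {path}: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    df.index.name = None  # the first header cell is ignored by the dialect
    df.columns = df.columns.astype(str).str.strip()
    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric cell in counts table {path}: {exc}") from exc
    return ExpressionMatrix(values, dict(condition_map), kind, normalized=normalized)


def write_counts(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    Duplicate genes within a line are collapsed (first occurrence kept).
    Lines with fewer than three fields raise :class:`FormatError`.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            unique = list(dict.fromkeys(g for g in genes if g))
            if not unique:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# target-prediction tables
# ---------------------------------------------------------------------------

def read_predictions(path: str | Path, conserved_min_pct: float = 50.0,
                     nonconserved_min_pct: float = 90.0) -> pd.DataFrame:
    """Read a miRNA-target prediction TSV and apply the percentile filters.

    Only records whose weighted context++ score percentile is *strictly* above
    the class-specific cutoff are retained (conserved: > ``conserved_min_pct``,
    non-conserved: > ``nonconserved_min_pct``).  The thresholds used are
    recorded on ``df.attrs``.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse prediction table {path}: {exc}") from exc
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"prediction table {path} lacks columns {missing}")
    df = df[list(PREDICTION_COLUMNS)].copy()
    for col in ("mirna", "gene", "conservation"):
        df[col] = df[col].astype(str).str.strip()
    bad = sorted(set(df["conservation"]) - set(_CONSERVATION_CLASSES))
    if bad:
        raise FormatError(f"unknown conservation flag(s) {bad}")
    try:
        df["percentile"] = pd.to_numeric(df["percentile"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric percentile in {path}: {exc}") from exc
    if ((df["percentile"] < 0) | (df["percentile"] > 100)).any():
        raise FormatError("percentile outside [0, 100]")
    return filter_predictions(df, conserved_min_pct, nonconserved_min_pct)


def filter_predictions(df: pd.DataFrame, conserved_min_pct: float = 50.0,
                       nonconserved_min_pct: float = 90.0) -> pd.DataFrame:
    """Apply the strict class-specific percentile cutoffs to an in-memory table."""
    cutoff = df["conservation"].map(
        {"conserved": conserved_min_pct, "nonconserved": nonconserved_min_pct}
    )
    out = df[df["percentile"] > cutoff].reset_index(drop=True)
    out.attrs["conserved_min_pct"] = conserved_min_pct
    out.attrs["nonconserved_min_pct"] = nonconserved_min_pct
    return out


def write_predictions(df: pd.DataFrame, path: str | Path) -> None:
    df[list(PREDICTION_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

_NODE_ATTRS = ("type", "direction", "log2fc")
_EDGE_ATTRS = ("r", "p", "conservation", "percentile")


def write_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a regulatory network as GraphML, an edge-attribute TSV, or SIF.

    GraphML and edge TSV preserve node attributes (type, direction, log2fc)
    and edge attributes (r, p, conservation, percentile); SIF keeps topology
    only (``mirna<TAB>targets<TAB>gene``).
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edge_tsv":
        rows = []
        for u, v, data in net.edges(data=True):
            # orient every row miRNA -> gene
            if net.nodes[u].get("type") == "mirna":
                m, g = u, v
            else:
                m, g = v, u
            rows.append({
                "mirna": m,
                "gene": g,
                **{k: data.get(k) for k in _EDGE_ATTRS},
                "mirna_direction": net.nodes[m].get("direction"),
                "gene_direction": net.nodes[g].get("direction"),
                "mirna_log2fc": net.nodes[m].get("log2fc"),
                "gene_log2fc": net.nodes[g].get("log2fc"),
            })
        cols = ["mirna", "gene", *_EDGE_ATTRS,
                "mirna_direction", "gene_direction", "mirna_log2fc", "gene_log2fc"]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in net.edges():
                if net.nodes[u].get("type") == "mirna":
                    m, g = u, v
                else:
                    m, g = v, u
                fh.write(f"{m}\ttargets\t{g}\n")
            # keep isolated nodes representable
            for n in net.nodes():
                if net.degree(n) == 0:
                    fh.write(f"{n}\n")
    else:
        raise ConfigurationError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a network previously written by :func:`write_network`."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        net = nx.Graph()
        for row in df.itertuples(index=False):
            net.add_node(row.mirna, type="mirna", direction=row.mirna_direction,
                         log2fc=float(row.mirna_log2fc))
            net.add_node(row.gene, type="gene", direction=row.gene_direction,
                         log2fc=float(row.gene_log2fc))
            net.add_edge(row.mirna, row.gene, r=float(row.r), p=float(row.p),
                         conservation=row.conservation, percentile=float(row.percentile))
        return net
    if format == "sif":
        net = nx.Graph()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) == 1 and fields[0]:
                    net.add_node(fields[0])
                elif len(fields) >= 3:
                    src, _interaction, *targets = fields
                    for t in targets:
                        net.add_edge(src, t)
                elif fields and fields[0]:
                    raise FormatError(f"malformed SIF line: {line!r}")
        return net
    raise ConfigurationError(f"unknown network format {format!r}")
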