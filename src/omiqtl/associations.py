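"""Association-edge extraction and summary analytics.

An association edge is a (feature, feature type, gene) pair whose
clean-stage coefficient survived selection; its strength is the coefficient
magnitude, thresholded by rho (0.1 for prediction-oriented summaries, 0.3
for networks).  The analytics reproduce the standard downstream views:
Venn classification of genes by associated feature types, decile-wise
prediction accuracy, top-K relative type contribution, hub features ranked
by gene degree, and cis flags for methylation features at their own gene.

Everything here is a pure function of the fitted results and the
configuration; rerunning yields identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd

from .fitting import BLOCK_ORDER, FitResults
from .omics_io import METHYLATION, ExpressionTraits

EDGE_COLUMNS = [
    "feature_id", "feature_type", "gene_id", "strength", "beta", "p_value",
]

DEFAULT_K_LIST = (100, 200, 400, 800, 1600, 3200, 6400)


@dataclass
class AnalysisConfig:
    rho: float = 0.1
    rho_network: float = 0.3
    k_list: tuple[int, ...] = DEFAULT_K_LIST
    n_bins: int = 10
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.rho < 0 or self.rho_network < 0:
            raise ValueError("strength thresholds must be nonnegative")
        if list(self.k_list) != sorted(set(self.k_list)):
            raise ValueError("k_list must be strictly increasing")


def extract_edges(results: FitResults | list[FitResults], rho: float = 0.1) -> pd.DataFrame:
    """One edge per (gene, feature) with a nonzero cleaned coefficient of
    magnitude >= rho, stably sorted by (strength desc, gene_id, feature_id).

    A list of results (e.g. the three single-type fits) is pooled into one
    edge table.
    """
    if isinstance(results, FitResults):
        results = [results]
    rows = []
    for res in results:
        fids = res.metadata["feature_ids"]
        for fit in res:
            for t in BLOCK_ORDER:
                if t not in fit.beta:
                    continue
                b = fit.beta[t]
                for j in np.flatnonzero(b):
                    s = abs(float(b[j]))
                    if s >= rho:
                        rows.append(
                            (fids[t][j], t, fit.gene_id, s, float(b[j]),
                             float(fit.p_values[t][j]))
                        )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    edges = edges.sort_values(
        ["strength", "gene_id", "feature_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return edges


def _class_label(types: frozenset[str]) -> str:
    return "+".join(t for t in BLOCK_ORDER if t in types)


ALL_CLASSES = tuple(
    _class_label(frozenset(c))
    for c in (
        {BLOCK_ORDER[0]}, {BLOCK_ORDER[1]}, {BLOCK_ORDER[2]},
        {BLOCK_ORDER[0], BLOCK_ORDER[1]}, {BLOCK_ORDER[0], BLOCK_ORDER[2]},
        {BLOCK_ORDER[1], BLOCK_ORDER[2]}, set(BLOCK_ORDER),
    )
)


def classify_genes(edges: pd.DataFrame) -> tuple[pd.Series, dict[str, int]]:
    """Assign every gene with >= 1 edge to one of the 7 Venn classes of
    associated feature types; the class counts partition those genes."""
    if edges.empty:
        return pd.Series(dtype=object), {c: 0 for c in ALL_CLASSES}
    types_per_gene = edges.groupby("gene_id")["feature_type"].agg(frozenset)
    labels = types_per_gene.map(_class_label)
    counts = {c: 0 for c in ALL_CLASSES}
    for lab, n in labels.value_counts().items():
        counts[lab] = int(n)
    return labels, counts


def decile_analysis(
    expression: ExpressionTraits,
    results: FitResults,
    stat: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Bin genes into ``n_bins`` equal-sized groups by mu, sigma or mu/sigma
    and summarize per-bin mean prediction accuracy and association counts.

    Genes are ranked ascending by the chosen statistic with ties broken by
    gene id (so an all-tied statistic degrades to gene-id order).  With G
    genes and B bins, the remainder r = G mod B is distributed one extra
    gene per bin to the lowest bins.  Per bin the mean cross-validated
    accuracy is taken over genes that retain >= 1 association at the rho
    strength filter; the count of such genes is reported alongside.
    """
    config = config or AnalysisConfig()
    if stat not in ("mu", "sigma", "mu_over_sigma"):
        raise ValueError("stat must be one of {'mu','sigma','mu_over_sigma'}")
    genes = [g for g in expression.gene_ids if g in results.fits]
    if len(genes) < config.n_bins:
        raise ValueError(
            f"need at least n_bins={config.n_bins} fitted genes, got {len(genes)}"
        )
    idx = {g: i for i, g in enumerate(expression.gene_ids)}
    mu = np.array([expression.mu[idx[g]] for g in genes])
    sigma = np.array([expression.sigma[idx[g]] for g in genes])
    if stat == "mu":
        values = mu
    elif stat == "sigma":
        values = sigma
    else:
        with np.errstate(divide="ignore"):
            values = np.where(sigma > 0, mu / sigma, np.inf)
    order = sorted(range(len(genes)), key=lambda i: (values[i], genes[i]))

    edges = extract_edges(results, config.rho)
    genes_with_edge = set(edges["gene_id"]) if not edges.empty else set()

    G, B = len(genes), config.n_bins
    base, rem = divmod(G, B)
    sizes = [base + 1] * rem + [base] * (B - rem)
    rows = []
    pos = 0
    for b, size in enumerate(sizes):
        members = [genes[i] for i in order[pos: pos + size]]
        pos += size
        surv = [g for g in members if g in genes_with_edge]
        accs = [results.fits[g].accuracy for g in surv]
        accs = [0.0 if np.isnan(a) else a for a in accs]
        rows.append(
            {
                "bin": b + 1,
                "stat": stat,
                "n_genes": size,
                "n_genes_with_association": len(surv),
                "mean_accuracy": float(np.mean(accs)) if accs else float("nan"),
                "stat_min": float(values[order[pos - size]]),
                "stat_max": float(values[order[pos - 1]]),
            }
        )
    return pd.DataFrame(rows)


def top_k_contribution(
    edges: pd.DataFrame, k_list: tuple[int, ...] = DEFAULT_K_LIST
) -> pd.DataFrame:
    """Per-type proportion of distinct (gene, feature type) pairs among the
    K strongest edges, for each K (clamped to the edge count).

    One gene with several edges of the same type counts once for that type,
    so the proportions answer "what fraction of gene--type associations does
    each type contribute"; they sum to 1 for every K.
    """
    rows = []
    for K in k_list:
        if edges.empty:
            rows.append(
                {"K": K, "n_edges_used": 0, "undefined": True,
                 **{t: float("nan") for t in BLOCK_ORDER}}
            )
            continue
        top = edges.iloc[: min(K, len(edges))]
        pairs = top[["gene_id", "feature_type"]].drop_duplicates()
        counts = pairs["feature_type"].value_counts()
        total = int(counts.sum())
        rows.append(
            {"K": K, "n_edges_used": len(top), "undefined": False,
             **{t: float(counts.get(t, 0)) / total for t in BLOCK_ORDER}}
        )
    return pd.DataFrame(rows)


def hub_features(edges: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Features ranked by the number of distinct associated genes (degree
    desc, ties by feature id), with the gene list for external enrichment."""
    if edges.empty:
        raise ValueError("hub ranking needs a non-empty edge table")
    grouped = edges.groupby(["feature_id", "feature_type"])["gene_id"].agg(
        lambda s: sorted(set(s))
    )
    df = grouped.reset_index().rename(columns={"gene_id": "genes"})
    df["degree"] = df["genes"].map(len)
    df = df.sort_values(
        ["degree", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df.loc[: top_n - 1, ["feature_id", "feature_type", "degree", "genes"]]


def flag_cis_associations(
    edges: pd.DataFrame, feature_to_gene_map: dict[str, str] | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Mark methylation edges at the gene itself as cis.

    By default a methylation feature maps to the gene of the same symbol;
    an explicit feature -> gene mapping overrides this.  Non-methylation
    edges are always trans.  Returns the annotated edges and
    {cis, trans, unmapped_methylation} counts.
    """
    edges = edges.copy()
    if edges.empty:
        edges["is_cis"] = pd.Series(dtype=bool)
        return edges, {"cis": 0, "trans": 0, "unmapped_methylation": 0}

    unmapped = 0

    def _is_cis(row) -> bool:
        nonlocal unmapped
        if row["feature_type"] != METHYLATION:
            return False
        if feature_to_gene_map is None:
            return row["feature_id"] == row["gene_id"]
        mapped = feature_to_gene_map.get(row["feature_id"])
        if mapped is None:
            unmapped += 1
            return False
        return mapped == row["gene_id"]

    edges["is_cis"] = edges.apply(_is_cis, axis=1)
    n_cis = int(edges["is_cis"].sum())
    return edges, {
        "cis": n_cis,
        "trans": int(len(edges) - n_cis),
        "unmapped_methylation": unmapped,
    }
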