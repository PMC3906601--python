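"""Analytics layer: edge extraction, Venn classes, deciles, top-K, hubs, cis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omiqtl import (
    CNA,
    METHYLATION,
    MIRNA,
    AnalysisConfig,
    ExpressionTraits,
    classify_genes,
    decile_analysis,
    extract_edges,
    flag_cis_associations,
    hub_features,
    top_k_contribution,
)
from omiqtl.associations import ALL_CLASSES, EDGE_COLUMNS
from omiqtl.fitting import FitResults, SparseFit


def make_results(coefs, mode="integrative", accuracy=0.5):
    """coefs: gene -> {(type, j): beta}; block sizes fixed at 4/6/5."""
    sizes = {CNA: 4, METHYLATION: 6, MIRNA: 5}
    fids = {t: [f"{t[:2]}{j}" for j in range(n)] for t, n in sizes.items()}
    fits = {}
    for g, d in coefs.items():
        beta = {t: np.zeros(n) for t, n in sizes.items()}
        pv = {t: np.full(n, np.nan) for t, n in sizes.items()}
        for (t, j), b in d.items():
            beta[t][j] = b
            pv[t][j] = 0.01
        fits[g] = SparseFit(gene_id=g, mode=mode, beta=beta, p_values=pv,
                            lam=1.0, accuracy=accuracy)
    return FitResults(mode=mode, fits=fits, metadata={"feature_ids": fids})


def edge_frame(rows):
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


class TestExtractEdges:
    def test_threshold_arithmetic(self):
        res = make_results({"g1": {(CNA, 0): 0.05, (CNA, 1): 0.2, (MIRNA, 2): -0.35}})
        edges = extract_edges(res, rho=0.1)
        assert len(edges) == 2
        assert set(edges["strength"].round(6)) == {0.2, 0.35}

    def test_rho_zero_counts_all_nonzero(self):
        res = make_results({"g1": {(CNA, 0): 0.01, (METHYLATION, 5): -2.0}})
        assert len(extract_edges(res, rho=0.0)) == 2

    def test_tie_break_stable(self):
        res = make_results({
            "g2": {(CNA, 1): 0.5},
            "g1": {(MIRNA, 0): 0.5, (MIRNA, 1): -0.5},
        })
        edges = extract_edges(res, rho=0.1)
        assert list(edges["gene_id"]) == ["g1", "g1", "g2"]
        assert list(edges["feature_id"][:2]) == ["mi0", "mi1"]

    def test_monotone_in_rho(self):
        rng = np.random.default_rng(2)
        coefs = {
            f"g{k}": {(MIRNA, int(rng.integers(5))): float(rng.normal())}
            for k in range(20)
        }
        res = make_results(coefs)
        prev = None
        for rho in (0.0, 0.2, 0.5, 1.0):
            cur = {tuple(r) for r in extract_edges(res, rho)[
                ["gene_id", "feature_id"]].itertuples(index=False)}
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestClassifyGenes:
    def test_pair_class(self):
        res = make_results({"g": {(CNA, 0): 1.0, (MIRNA, 1): 0.5}})
        labels, counts = classify_genes(extract_edges(res, 0.1))
        assert labels["g"] == f"{CNA}+{MIRNA}"
        assert counts[f"{CNA}+{MIRNA}"] == 1
        assert sum(counts.values()) == 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 15), st.sampled_from([CNA, METHYLATION, MIRNA]),
                  st.integers(0, 3), st.floats(0.2, 2.0)),
        max_size=60,
    ))
    def test_partition_property(self, raw):
        rows = [(f"f{j}", t, f"g{g}", s, s, 0.01) for g, t, j, s in raw]
        labels, counts = classify_genes(edge_frame(rows))
        assert set(counts) == set(ALL_CLASSES)
        assert sum(counts.values()) == len({f"g{g}" for g, *_ in raw})
        assert len(labels) == sum(counts.values())


class TestTopK:
    def test_forced_split(self):
        rows = [("c1", CNA, "g1", 0.9, 0.9, 0.0), ("m1", METHYLATION, "g2", 0.8, 0.8, 0.0),
                ("m2", METHYLATION, "g3", 0.7, 0.7, 0.0), ("r1", MIRNA, "g4", 0.6, 0.6, 0.0)]
        out = top_k_contribution(edge_frame(rows), (2,))
        row = out.iloc[0]
        assert row[CNA] == 0.5 and row[METHYLATION] == 0.5 and row[MIRNA] == 0.0

    def test_single_type_degenerate(self):
        rows = [(f"m{j}", METHYLATION, f"g{j}", 1.0 - j * 0.01, 1.0, 0.0)
                for j in range(10)]
        out = top_k_contribution(edge_frame(rows), (3, 100))
        assert (out[METHYLATION] == 1.0).all()

    def test_k_clamped(self):
        rows = [("m1", METHYLATION, "g1", 0.9, 0.9, 0.0),
                ("c1", CNA, "g2", 0.8, 0.8, 0.0)]
        out = top_k_contribution(edge_frame(rows), (2, 50))
        assert out.iloc[0][CNA] == out.iloc[1][CNA]
        assert out.iloc[1]["n_edges_used"] == 2

    def test_empty_edges_flagged(self):
        out = top_k_contribution(edge_frame([]), (10,))
        assert bool(out.iloc[0]["undefined"])
        assert np.isnan(out.iloc[0][CNA])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 10), st.sampled_from([CNA, METHYLATION, MIRNA]),
                  st.integers(0, 5), st.floats(0.1, 3.0)),
        min_size=1, max_size=50,
    ))
    def test_proportions_sum_to_one(self, raw):
        rows = [(f"f{t[:2]}{j}", t, f"g{g}", s, s, 0.01) for g, t, j, s in raw]
        edges = edge_frame(rows).sort_values(
            ["strength", "gene_id", "feature_id"], ascending=[False, True, True]
        )
        out = top_k_contribution(edges, (1, 5, 9000))
        sums = out[[CNA, METHYLATION, MIRNA]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestHubs:
    def test_degree_ranking_and_gene_lists(self):
        rows = [("hub", MIRNA, g, 0.5, 0.5, 0.0) for g in ("g1", "g2", "g3")]
        rows += [("leaf", CNA, "g1", 0.7, 0.7, 0.0)]
        out = hub_features(edge_frame(rows), top_n=10)
        assert list(out["feature_id"]) == ["hub", "leaf"]
        assert list(out["degree"]) == [3, 1]
        assert out.iloc[0]["genes"] == ["g1", "g2", "g3"]

    def test_equal_degree_lexicographic(self):
        rows = [("b", CNA, "g1", 0.5, 0.5, 0.0), ("a", CNA, "g2", 0.4, 0.4, 0.0)]
        out = hub_features(edge_frame(rows), top_n=2)
        assert list(out["feature_id"]) == ["a", "b"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hub_features(edge_frame([]))


class TestCisFlags:
    def test_identity_mapping(self):
        rows = [("SPRY4", METHYLATION, "SPRY4", 0.9, 0.9, 0.0),
                ("SPRY4", METHYLATION, "OTHER", 0.5, 0.5, 0.0),
                ("SPRY4", CNA, "SPRY4", 0.4, 0.4, 0.0)]
        edges, counts = flag_cis_associations(edge_frame(rows))
        assert list(edges["is_cis"]) == [True, False, False]
        assert counts == {"cis": 1, "trans": 2, "unmapped_methylation": 0}

    def test_explicit_mapping_and_unmapped(self):
        rows = [("probeX", METHYLATION, "TP53", 0.9, 0.9, 0.0),
                ("probeY", METHYLATION, "TP53", 0.5, 0.5, 0.0)]
        edges, counts = flag_cis_associations(
            edge_frame(rows), {"probeX": "TP53"})
        assert list(edges["is_cis"]) == [True, False]
        assert counts["unmapped_methylation"] == 1


class TestDecileAnalysis:
    @staticmethod
    def _expression(n_genes, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((n_genes, 30)) + np.arange(n_genes)[:, None]
        return ExpressionTraits([f"g{k}" for k in range(n_genes)],
                                [f"s{i}" for i in range(30)], vals)

    def test_equal_bins_and_counts(self):
        expr = self._expression(20)
        res = make_results({f"g{k}": {(CNA, 0): 0.5} for k in range(20)})
        out = decile_analysis(expr, res, "mu", AnalysisConfig(n_bins=10))
        assert list(out["n_genes"]) == [2] * 10
        assert out["n_genes_with_association"].sum() == 20

    def test_remainder_goes_to_lowest_bins(self):
        expr = self._expression(23)
        res = make_results({f"g{k}": {(CNA, 0): 0.5} for k in range(23)})
        out = decile_analysis(expr, res, "sigma", AnalysisConfig(n_bins=10))
        assert list(out["n_genes"]) == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]

    def test_tied_stat_falls_back_to_gene_id_order(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal(30)
        vals = np.vstack([base + k for k in range(12)])  # same sigma for all
        expr = ExpressionTraits([f"g{k:02d}" for k in range(12)],
                                [f"s{i}" for i in range(30)], vals)
        res = make_results({f"g{k:02d}": {(CNA, 0): 0.5} for k in range(12)})
        out = decile_analysis(expr, res, "sigma", AnalysisConfig(n_bins=6))
        assert list(out["n_genes"]) == [2] * 6

    def test_fewer_genes_than_bins_rejected(self):
        expr = self._expression(5)
        res = make_results({f"g{k}": {(CNA, 0): 0.5} for k in range(5)})
        with pytest.raises(ValueError, match="n_bins"):
            decile_analysis(expr, res, "mu", AnalysisConfig(n_bins=10))

    def test_rho_filter_excludes_weak_genes_from_accuracy(self):
        expr = self._expression(10)
        coefs = {f"g{k}": {(CNA, 0): (0.5 if k % 2 else 0.05)} for k in range(10)}
        res = make_results(coefs, accuracy=0.8)
        out = decile_analysis(expr, res, "mu", AnalysisConfig(n_bins=10, rho=0.1))
        assert out["n_genes_with_association"].sum() == 5


def test_decile_trends_follow_trait_archetypes():
    """On synthetic data where high-mean traits are CNA-driven and
    high-variance traits methylation-driven, the CNA single-mode accuracy
    is highest in the top mean-expression bins and the methylation
    single-mode accuracy highest in the top variability bins."""
    from omiqtl import FitConfig, SimConfig, fit_all_genes, generate_dataset

    cfg = SimConfig(n_samples=200, n_genes=20, frac_null=0.2, frac_multi=0.0,
                    seed=77)
    ds, _ = generate_dataset(cfg)
    fc = FitConfig(seed=3)
    acfg = AnalysisConfig(n_bins=5, rho=0.1)

    def weighted(bins_df, rows):
        sub = bins_df.iloc[rows]
        w = sub["n_genes_with_association"].to_numpy(dtype=float)
        a = sub["mean_accuracy"].fillna(0.0).to_numpy()
        return float((w * a).sum() / max(w.sum(), 1.0))

    cna = decile_analysis(
        ds.expression, fit_all_genes(ds, "single:CNA", fc), "mu", acfg
    )
    meth = decile_analysis(
        ds.expression, fit_all_genes(ds, "single:methylation", fc), "sigma", acfg
    )
    assert weighted(cna, [4]) > weighted(cna, [0, 1])
    assert weighted(meth, [4]) > weighted(meth, [0, 1])


def test_analysis_config_validation():
    with pytest.raises(ValueError):
        AnalysisConfig(rho=-0.1)
    with pytest.raises(ValueError):
        AnalysisConfig(k_list=(100, 100))
    with pytest.raises(ValueError):
        AnalysisConfig(k_list=(200, 100))
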