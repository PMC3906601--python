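import numpy as np
import pytest

from omiqtl import (
    CNA,
    METHYLATION,
    MIRNA,
    ExpressionTraits,
    OmicsBlock,
    OmicsValidationError,
    align_samples,
    gistic_to_cna,
    preprocess,
    read_dataset_dir,
    read_expression_matrix,
    read_feature_matrix,
    variance_filter,
    write_dataset_dir,
    zscore_normalize,
)


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")


class TestReadFeatureMatrix:
    def test_well_formed(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_tsv(p, ["", "s1", "s2"], [["fA", 0.1, 0.2], ["fB", 0.3, 0.4], ["fC", 1, 2]])
        b = read_feature_matrix(p, MIRNA)
        assert b.n_features == 3 and b.n_samples == 2
        assert b.sample_ids == ["s1", "s2"]
        assert b.values[1, 2] == 2.0  # sample s2, feature fC
        assert not b.normalized

    def test_cna_category_violation(self, tmp_path):
        p = tmp_path / "c.tsv"
        write_tsv(p, ["", "s1", "s2"], [["1p36", 0, 3]])
        with pytest.raises(OmicsValidationError, match="-2,-1,0,1,2"):
            read_feature_matrix(p, CNA)

    def test_cna_valid_categories(self, tmp_path):
        p = tmp_path / "c.tsv"
        write_tsv(p, ["", "s1", "s2"], [["1p36", -2, 2], ["8q24", 0, 1]])
        b = read_feature_matrix(p, CNA)
        assert b.n_features == 2

    def test_duplicate_feature_id(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_tsv(p, ["", "s1"], [["fA", 1.0], ["fA", 2.0]])
        with pytest.raises(OmicsValidationError, match="fA"):
            read_feature_matrix(p, MIRNA)

    def test_duplicate_sample_id(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_tsv(p, ["", "s1", "s1"], [["fA", 1.0, 2.0]])
        with pytest.raises(OmicsValidationError, match="s1"):
            read_feature_matrix(p, MIRNA)

    def test_non_numeric_cell_named(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_tsv(p, ["", "s1", "s2"], [["fA", 1.0, "oops"]])
        with pytest.raises(OmicsValidationError, match="fA.*s2"):
            read_feature_matrix(p, MIRNA)

    def test_missing_value_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("\ts1\ts2\nfA\t1.0\t\n")
        with pytest.raises(OmicsValidationError):
            read_feature_matrix(p, MIRNA)


class TestVarianceFilter:
    @staticmethod
    def _block_with_variances(variances):
        # feature j = sqrt(var_j) * [-1, 1] has population variance var_j
        vals = np.array([[-np.sqrt(v), np.sqrt(v)] for v in variances]).T
        return OmicsBlock(
            type_label=METHYLATION,
            feature_ids=[f"f{j}" for j in range(len(variances))],
            sample_ids=["s1", "s2"],
            values=vals + 0.5,  # shift irrelevant to variance
        )

    def test_quantile_cut_distinct_variances(self):
        b = self._block_with_variances([1, 2, 3, 4, 5, 6, 7, 8])
        out = variance_filter(b, 0.25)
        assert out.feature_ids == ["f2", "f3", "f4", "f5", "f6", "f7"]
        assert out.n_features == int(np.ceil(0.75 * 8))

    def test_zero_quantile_identity(self):
        b = self._block_with_variances([3, 1, 2])
        out = variance_filter(b, 0.0)
        assert out.feature_ids == b.feature_ids
        np.testing.assert_array_equal(out.values, b.values)

    def test_all_constant_variance_errors(self):
        b = self._block_with_variances([2, 2, 2])
        with pytest.raises(OmicsValidationError, match="identical variance"):
            variance_filter(b, 0.25)

    def test_refuses_normalized_input(self):
        b = zscore_normalize(self._block_with_variances([1, 2, 3, 4]))
        with pytest.raises(OmicsValidationError, match="before"):
            variance_filter(b, 0.25)


class TestZscoreNormalize:
    def test_values(self):
        b = OmicsBlock(METHYLATION, ["f"], ["a", "b", "c"], np.array([[1.0], [2.0], [3.0]]))
        out = zscore_normalize(b)
        np.testing.assert_allclose(
            out.values[:, 0], [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )
        assert out.normalized

    def test_idempotent(self, rng):
        b = OmicsBlock(
            MIRNA, [f"f{j}" for j in range(5)], [f"s{i}" for i in range(20)],
            rng.standard_normal((20, 5)) * 3 + 1,
        )
        once = zscore_normalize(b)
        twice = zscore_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_population_convention_xtx(self, rng):
        n = 17
        b = OmicsBlock(
            MIRNA, ["f0", "f1"], [f"s{i}" for i in range(n)],
            rng.standard_normal((n, 2)),
        )
        z = zscore_normalize(b).values
        np.testing.assert_allclose(np.diag(z.T @ z), [n, n], atol=1e-9)

    def test_constant_column_named(self):
        b = OmicsBlock(METHYLATION, ["flat"], ["a", "b", "c"], np.full((3, 1), 5.0))
        with pytest.raises(OmicsValidationError, match="flat"):
            zscore_normalize(b)


class TestAlignSamples:
    @staticmethod
    def _block(label, samples, seed=0):
        rng = np.random.default_rng(seed)
        if label == CNA:
            vals = rng.choice([-1.0, 0.0, 1.0], size=(len(samples), 2))
        else:
            vals = rng.standard_normal((len(samples), 2))
        return OmicsBlock(label, ["f1", "f2"], list(samples), vals)

    @staticmethod
    def _expr(samples, seed=1):
        rng = np.random.default_rng(seed)
        return ExpressionTraits(
            ["g1", "g2"], list(samples), rng.standard_normal((2, len(samples)))
        )

    def test_intersection(self):
        blocks = [
            self._block(CNA, ["A", "B", "C"]),
            self._block(METHYLATION, ["A", "B"]),
            self._block(MIRNA, ["A", "B", "D"]),
        ]
        ds = align_samples(blocks, self._expr(["A", "B"]))
        assert ds.N == 2 and ds.sample_ids == ["A", "B"]
        assert ds.alignment_report[CNA] == ["C"]
        assert ds.alignment_report[MIRNA] == ["D"]

    def test_order_invariance(self):
        b1 = [self._block(CNA, ["B", "A", "C"], seed=3)]
        expr = self._expr(["C", "A", "B"])
        ds1 = align_samples(b1, expr)
        # permute the block's samples: same rows must land in the same place
        perm = [2, 0, 1]
        b2 = [
            OmicsBlock(CNA, ["f1", "f2"],
                       [b1[0].sample_ids[i] for i in perm],
                       b1[0].values[perm])
        ]
        ds2 = align_samples(b2, expr)
        assert ds1.sample_ids == ds2.sample_ids == ["A", "B", "C"]
        np.testing.assert_array_equal(ds1.blocks[CNA].values, ds2.blocks[CNA].values)

    def test_disjoint_errors(self):
        with pytest.raises(OmicsValidationError, match="no sample"):
            align_samples([self._block(CNA, ["A"])], self._expr(["B"]))


def test_preprocess_pipeline_produces_normalized_dataset():
    rng = np.random.default_rng(7)
    samples = [f"s{i}" for i in range(30)]
    cna_vals = rng.choice([-2, -1, 0, 1, 2], p=[0.05, 0.15, 0.6, 0.15, 0.05],
                          size=(30, 3)).astype(float)
    cna_vals[0] = [1, -1, 2]  # guard against constant columns
    blocks = [
        OmicsBlock(CNA, ["c1", "c2", "c3"], samples, cna_vals),
        OmicsBlock(METHYLATION, [f"m{j}" for j in range(8)], samples,
                   rng.uniform(0.05, 0.95, (30, 8))),
        OmicsBlock(MIRNA, ["r1", "r2"], samples, rng.standard_normal((30, 2))),
    ]
    expr = ExpressionTraits(["g1", "g2"], samples, rng.standard_normal((2, 30)))
    ds = preprocess(blocks, expr)
    assert ds.M == 3 and ds.N == 30
    # methylation lost its lowest-variance quartile; others untouched
    assert ds.blocks[METHYLATION].n_features == 6
    assert ds.blocks[CNA].n_features == 3
    for b in ds.blocks.values():
        assert b.normalized
        np.testing.assert_allclose(b.values.mean(0), 0, atol=1e-10)
        np.testing.assert_allclose(b.values.std(0), 1, atol=1e-10)


def test_dataset_dir_roundtrip(tmp_path, rng):
    samples = [f"s{i}" for i in range(10)]
    blocks = [
        OmicsBlock(CNA, ["c1"], samples,
                   rng.choice([-1.0, 0.0, 1.0], size=(10, 1))),
        OmicsBlock(MIRNA, ["r1", "r2"], samples, rng.standard_normal((10, 2))),
    ]
    expr = ExpressionTraits(["g1"], samples, rng.standard_normal((1, 10)))
    out = write_dataset_dir(tmp_path / "ds", blocks, expr, params={"seed": 1})
    blocks2, expr2, manifest = read_dataset_dir(out)
    assert manifest["n_samples"] == 10
    assert {b.type_label for b in blocks2} == {CNA, MIRNA}
    got = {b.type_label: b for b in blocks2}
    for b in blocks:
        np.testing.assert_allclose(got[b.type_label].values, b.values, rtol=1e-9)
    np.testing.assert_allclose(expr2.values, expr.values, rtol=1e-9)


def test_gistic_converter(tmp_path):
    header = ["Unique Name", "Descriptor", "q values", "Amplitude Threshold",
              "TCGA-01", "TCGA-02"]
    rows = [
        ["Amplification Peak 1", "8q24.21", "1e-5", "0: t< ...", 0, 2],
        ["Amplification Peak 1 - CN values", "8q24.21", "1e-5", "Actual Copy Change Given", 0.1, 2.3],
        ["Deletion Peak 1", "9p21.3", "1e-7", "0: t> ...", 1, 0],
    ]
    p = tmp_path / "all_lesions.txt"
    p.write_text("\n".join("\t".join(map(str, r)) for r in [header] + rows) + "\n")
    b = gistic_to_cna(p)
    assert b.type_label == CNA
    assert b.feature_ids == ["8q24.21", "9p21.3"]
    assert b.sample_ids == ["TCGA-01", "TCGA-02"]
    # deletion calls are negated
    np.testing.assert_array_equal(b.values, [[0.0, -1.0], [2.0, 0.0]])


def test_expression_zero_variance_flagged(tmp_path):
    p = tmp_path / "e.tsv"
    p.write_text("\ts1\ts2\ts3\ngFlat\t2\t2\t2\ngVar\t1\t2\t3\n")
    e = read_expression_matrix(p)
    assert e.zero_variance_genes() == ["gFlat"]
    np.testing.assert_allclose(e.mu, [2.0, 2.0])
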