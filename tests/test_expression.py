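import logging

import numpy as np
import pandas as pd
import pytest

from pathcombo import (
    ValidationError,
    compute_cnr,
    quantile_normalize,
    read_expression,
)
from conftest import make_matrix


def naive_quantile_normalize(vals: np.ndarray) -> np.ndarray:
    """Brute-force oracle: each value gets the mean of the reference
    distribution over the sorted positions its tie group occupies."""
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals, dtype=float)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        pos = np.empty(n, dtype=int)
        pos[order] = np.arange(n)
        for i in range(n):
            tied = [k for k in range(n) if col[k] == col[i]]
            out[i, j] = np.mean([ref[pos[k]] for k in tied])
    return out


def write_pair(tmp_path, table, meta):
    e = tmp_path / "expr.tsv"
    m = tmp_path / "meta.tsv"
    e.write_text(table)
    m.write_text(meta)
    return e, m


META = (
    "sample\tcell_line\tdrug\ttimepoint_weeks\tis_control\n"
    "s1\tSKOV-3\tnone\t0\t1\n"
    "s2\tSKOV-3\tnone\t4\t1\n"
    "s3\tSKOV-3\tDRUG-A\t4\t0\n"
    "s4\tSKOV-3\tDRUG-A\t8\t0\n"
)


class TestReadExpression:
    def test_shape_and_metadata(self, tmp_path):
        e, m = write_pair(
            tmp_path,
            "gene\ts1\ts2\ts3\ts4\nA\t1\t2\t3\t4\nB\t5\t6\t7\t8\nC\t9\t1\t2\t3\n",
            META,
        )
        mat = read_expression(e, m)
        assert mat.values.shape == (3, 4)
        assert mat.control_samples == ("s1", "s2")
        assert mat.case_samples == ("s3", "s4")
        assert mat.condition_of("s3") == ("SKOV-3", "DRUG-A", 4)

    def test_duplicate_gene_collapsed_by_max(self, tmp_path, caplog):
        e, m = write_pair(
            tmp_path,
            "gene\ts1\ts2\ts3\ts4\nGENEA\t1\t9\t3\t4\nGENEA\t5\t2\t7\t1\n",
            META,
        )
        with caplog.at_level(logging.WARNING, logger="pathcombo.expression"):
            mat = read_expression(e, m)
        assert list(mat.values.loc["GENEA"]) == [5.0, 9.0, 7.0, 4.0]
        assert any("collapsing" in r.message for r in caplog.records)

    def test_sample_missing_from_metadata(self, tmp_path):
        e, m = write_pair(
            tmp_path,
            "gene\ts1\ts2\ts3\ts4\ts5\nA\t1\t2\t3\t4\t5\n",
            META,
        )
        with pytest.raises(ValidationError, match="s5"):
            read_expression(e, m)

    def test_negative_intensity_rejected(self, tmp_path):
        e, m = write_pair(
            tmp_path, "gene\ts1\ts2\ts3\ts4\nA\t1\t-2\t3\t4\n", META
        )
        with pytest.raises(ValidationError, match="negative"):
            read_expression(e, m)


class TestQuantileNormalize:
    def test_two_sample_reference_distribution(self):
        m = make_matrix(
            {"c1": [1, 2, 3], "case": [4, 5, 6]}, ["A", "B", "C"], {"c1"}
        )
        q = quantile_normalize(m)
        assert list(q.values["c1"]) == [2.5, 3.5, 4.5]
        assert list(q.values["case"]) == [2.5, 3.5, 4.5]

    def test_tied_values_share_mean_reference(self):
        m = make_matrix(
            {"c1": [1, 1, 2], "case": [10, 20, 30]}, ["A", "B", "C"], {"c1"}
        )
        q = quantile_normalize(m)
        # reference = mean of sorted columns = [5.5, 10.5, 16]
        assert list(q.values["c1"]) == [8.0, 8.0, 16.0]
        assert list(q.values["case"]) == [5.5, 10.5, 16.0]

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_matches_bruteforce_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 8, size=(12, 4)).astype(float)  # many ties
        m = make_matrix(
            {f"s{j}": vals[:, j] for j in range(4)},
            [f"G{i}" for i in range(12)],
            {"s0"},
        )
        q = quantile_normalize(m)
        np.testing.assert_allclose(
            q.values.to_numpy(), naive_quantile_normalize(vals), rtol=1e-12
        )

    def test_idempotent(self, four_sample_matrix):
        q1 = quantile_normalize(four_sample_matrix)
        q2 = quantile_normalize(q1)
        np.testing.assert_allclose(
            q2.values.to_numpy(), q1.values.to_numpy(), rtol=1e-12
        )

    def test_preserves_within_sample_rank_order(self, four_sample_matrix):
        q = quantile_normalize(four_sample_matrix)
        for s in four_sample_matrix.samples:
            orig = four_sample_matrix.values[s].to_numpy()
            normed = q.values[s].to_numpy()
            assert np.array_equal(np.argsort(orig), np.argsort(normed))

    def test_single_gene_unchanged(self, caplog):
        m = make_matrix({"c1": [5.0], "case": [9.0]}, ["A"], {"c1"})
        with caplog.at_level(logging.WARNING, logger="pathcombo.expression"):
            q = quantile_normalize(m)
        assert q.values.equals(m.values)


class TestCnr:
    def test_geometric_mean_pooling(self):
        m = make_matrix(
            {"c1": [10], "c2": [10], "c3": [40], "case": [20]},
            ["A"],
            {"c1", "c2", "c3"},
        )
        cnr = compute_cnr(m, "case")
        assert cnr["A"] == pytest.approx(20 / (10 * 10 * 40) ** (1 / 3), rel=1e-9)
        assert cnr["A"] == pytest.approx(1.2599, abs=1e-4)

    def test_case_equal_to_geomean_gives_unity(self):
        m = make_matrix(
            {"c1": [10], "c2": [40], "case": [20]}, ["A"], {"c1", "c2"}
        )
        assert compute_cnr(m, "case")["A"] == pytest.approx(1.0)

    def test_floor_guards_zero_case_value(self):
        m = make_matrix(
            {"c1": [100], "c2": [100], "case": [0]}, ["A"], {"c1", "c2"}
        )
        assert compute_cnr(m, "case", floor=1.0)["A"] == pytest.approx(0.01)

    def test_scale_invariance_above_floor(self, four_sample_matrix):
        base = compute_cnr(four_sample_matrix, "case1")
        scaled = make_matrix(
            {
                s: four_sample_matrix.values[s].to_numpy() * 7.3
                for s in four_sample_matrix.samples
            },
            four_sample_matrix.genes,
            set(four_sample_matrix.control_samples),
        )
        np.testing.assert_allclose(
            compute_cnr(scaled, "case1").ratios, base.ratios, rtol=1e-10
        )

    def test_control_permutation_invariance(self):
        vals = {"c1": [10.0], "c2": [25.0], "c3": [3.0], "case": [11.0]}
        m1 = make_matrix(vals, ["A"], {"c1", "c2", "c3"})
        perm = {"c3": vals["c1"], "c1": vals["c2"], "c2": vals["c3"],
                "case": vals["case"]}
        m2 = make_matrix(perm, ["A"], {"c1", "c2", "c3"})
        assert compute_cnr(m1, "case")["A"] == pytest.approx(
            compute_cnr(m2, "case")["A"], rel=1e-12
        )

    def test_errors(self, four_sample_matrix):
        with pytest.raises(ValidationError, match="unknown sample"):
            compute_cnr(four_sample_matrix, "nope")
        with pytest.raises(ValidationError, match="control sample"):
            compute_cnr(four_sample_matrix, "ctrl1")
        other = make_matrix(
            {"c1": [1.0], "case": [2.0]}, ["A"], {"c1"}, cell_line="NGP-127"
        )
        other.metadata.loc["case", "cell_line"] = "SKOV-3"  # no matched controls
        with pytest.raises(ValidationError, match="no control samples"):
            compute_cnr(other, "case")
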