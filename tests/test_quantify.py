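"""Metrics, scoring, aggregation and ranking against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest

from trichoseg.annot import SparseMask, rasterize
from trichoseg.quantify import (
    aggregate,
    evaluate_pairs,
    f1,
    flag_nonmonotone_classes,
    iou,
    lts,
    rank_correlation,
    rank_genotypes,
    score_oracle,
)
from trichoseg.synthleaf import default_panel, generate_panel


def mask_rows(rows, shape=(4, 4)):
    dense = np.zeros(shape, dtype=np.uint8)
    dense[list(rows), :] = 1
    return SparseMask.from_dense(dense)


class TestIoU:
    def test_identical(self):
        m = mask_rows([0, 1])
        assert iou(m, m) == 1.0

    def test_disjoint(self):
        assert iou(mask_rows([0]), mask_rows([2])) == 0.0

    def test_hand_enumeration(self):
        # P = rows 0-1, G = rows 1-2 of 4x4: |inter| = 4, |union| = 12
        assert iou(mask_rows([0, 1]), mask_rows([1, 2])) == pytest.approx(1 / 3)

    def test_both_empty_is_one(self):
        e = SparseMask.empty((4, 4))
        assert iou(e, e) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            iou(SparseMask.empty((4, 4)), SparseMask.empty((5, 5)))


class TestF1:
    def test_identical(self):
        m = mask_rows([0, 1])
        assert f1(m, m) == (1.0, 1.0, 1.0)

    def test_hand_enumeration(self):
        score, precision, recall = f1(mask_rows([0, 1]), mask_rows([1, 2]))
        assert (score, precision, recall) == (0.5, 0.5, 0.5)

    def test_empty_prediction_warns(self):
        with pytest.warns(UserWarning, match="precision"):
            score, precision, recall = f1(SparseMask.empty((4, 4)), mask_rows([1]))
        assert (score, precision) == (0.0, 0.0)

    def test_dice_jaccard_identity(self):
        # F1 == 2*IoU / (1 + IoU) on random mask pairs, to 1e-12
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = SparseMask.from_dense((rng.random((32, 32)) < 0.2).astype(np.uint8))
            g = SparseMask.from_dense((rng.random((32, 32)) < 0.2).astype(np.uint8))
            j = iou(p, g)
            assert f1(p, g)[0] == pytest.approx(2 * j / (1 + j), abs=1e-12)


class TestLTS:
    def test_empty(self):
        assert lts(SparseMask.empty((768, 768))).lts == 0.0

    def test_full(self):
        assert lts(SparseMask.from_dense(np.ones((32, 32), np.uint8))).lts == 1000.0

    def test_direct_arithmetic(self):
        dense = np.zeros((768, 768), dtype=np.uint8)
        dense.flat[:3072] = 1
        result = lts(SparseMask.from_dense(dense))
        assert result.lts == pytest.approx(1000 * 3072 / 589824)
        # exact rational identity: lts * n_total == 1000 * n_fg
        assert result.exact * result.n_total == 1000 * result.n_fg

    def test_scale_equivariance_exact(self):
        rng = np.random.default_rng(1)
        dense = (rng.random((32, 32)) < 0.15).astype(np.uint8)
        up = dense.repeat(2, axis=0).repeat(2, axis=1)
        assert lts(SparseMask.from_dense(dense)).lts == lts(
            SparseMask.from_dense(up)
        ).lts


class TestEvaluatePairs:
    def test_perfect_predictions(self):
        m = mask_rows([0, 2])
        frame = evaluate_pairs([(m, m), (m, m)])
        mean_row = frame.iloc[-1]
        assert mean_row["iou"] == 1.0 and mean_row["f1"] == 1.0


class TestScoreOracle:
    def test_zero_records(self):
        frame = score_oracle([])
        assert len(frame) == 0

    def test_table_matches_truth_lts(self, ranking_panel):
        _, records = ranking_panel
        frame = score_oracle(records[:4])
        for row, rec in zip(frame.itertuples(), records[:4]):
            expect = lts(rasterize(rec.splines, rec.size, 2)).lts
            assert row.lts == pytest.approx(expect)
            assert row.genotype == rec.meta["genotype"]

    def test_density_ordering(self):
        panel = default_panel(3, count_means=[5, 40, 90])
        records = generate_panel(panel, 5, seed=2)
        frame = score_oracle(records)
        means = frame.groupby("genotype", sort=False)["lts"].mean()
        means = means[[g.name for g in panel]]
        assert means.is_monotonic_increasing


class TestAggregate:
    def test_single_group(self):
        table = pd.DataFrame({"genotype": ["a"] * 4, "lts": [1.0, 2.0, 3.0, 4.0]})
        out = aggregate(table, ["genotype"])
        assert out.loc[0, "mean"] == 2.5

    def test_identical_values_zero_sd(self):
        table = pd.DataFrame(
            {"genotype": ["a", "a", "b", "b"], "lts": [7.0, 7.0, 7.0, 7.0]}
        )
        out = aggregate(table, ["genotype"])
        assert (out["mean"] == 7.0).all() and (out["sd"] == 0.0).all()

    def test_hand_built_table(self):
        # spreadsheet oracle: means and sample sd computed by hand
        table = pd.DataFrame(
            {
                "environment": ["GH", "GH", "GH", "FD", "FD", "FD"],
                "lts": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
            }
        )
        out = aggregate(table, ["environment"]).set_index("environment")
        assert out.loc["GH", "mean"] == 2.0
        assert out.loc["FD", "mean"] == 20.0
        assert out.loc["FD", "sd"] == pytest.approx(10.0)
        # t-interval with n=3, df=2: mean +- 4.3027 * sd / sqrt(3)
        assert out.loc["GH", "ci_hi"] == pytest.approx(2.0 + 4.302653 * 1 / np.sqrt(3), rel=1e-4)

    def test_singleton_group_no_sd(self):
        table = pd.DataFrame({"genotype": ["a"], "lts": [5.0]})
        out = aggregate(table, ["genotype"])
        assert np.isnan(out.loc[0, "sd"])

    def test_unknown_key(self):
        with pytest.raises(KeyError, match="nope"):
            aggregate(pd.DataFrame({"lts": [1.0]}), ["nope"])

    def test_median_option(self):
        table = pd.DataFrame({"genotype": ["a"] * 3, "lts": [1.0, 2.0, 30.0]})
        assert aggregate(table, ["genotype"], statistic="median").loc[0, "median"] == 2.0


class TestRankGenotypes:
    def make_table(self, means):
        rows = []
        for name, mean in means.items():
            for v in (mean - 1, mean, mean + 1):
                rows.append(
                    {"genotype": name, "lts": v, "environment": "GH", "ghs": "3"}
                )
        return pd.DataFrame(rows)

    def test_ascending_order(self):
        table = self.make_table({"a": 5.0, "b": 1.0, "c": 3.0})
        ranking = rank_genotypes(table, within="GH")
        assert ranking["genotype"].tolist() == ["b", "c", "a"]
        assert ranking["rank"].tolist() == [1, 2, 3]

    def test_tie_broken_by_name(self):
        table = self.make_table({"zeta": 2.0, "alpha": 2.0})
        ranking = rank_genotypes(table)
        assert ranking["genotype"].tolist() == ["alpha", "zeta"]

    def test_empty_selection(self):
        table = self.make_table({"a": 1.0})
        with pytest.raises(ValueError, match="no rows"):
            rank_genotypes(table, within="FD")

    def test_carries_ghs(self):
        ranking = rank_genotypes(self.make_table({"a": 1.0}))
        assert ranking.loc[0, "ghs"] == "3"


class TestRankCorrelation:
    def test_identical(self):
        assert rank_correlation(["a", "b", "c"], ["a", "b", "c"]) == 1.0

    def test_reversed(self):
        assert rank_correlation(["a", "b", "c"], ["c", "b", "a"]) == -1.0

    def test_adjacent_swap_formula(self):
        # n=4, one adjacent swap: rho = 1 - 6*2 / (4*15) = 0.8
        assert rank_correlation(
            ["a", "b", "c", "d"], ["a", "c", "b", "d"]
        ) == pytest.approx(0.8)

    def test_disjoint_items(self):
        with pytest.raises(ValueError, match="same item set"):
            rank_correlation(["a"], ["b"])


class TestNonmonotoneFlag:
    def test_detects_dip(self):
        # constructed table mimicking a dip at class '4' below '3/4'
        rows = []
        for ghs, mean in [("3", 10.0), ("3/4", 14.0), ("4", 11.0), ("4/4+", 16.0)]:
            rows.extend({"ghs": ghs, "lts": mean + d} for d in (-1.0, 0.0, 1.0))
        table = pd.DataFrame(rows)
        assert flag_nonmonotone_classes(table) == ["4"]

    def test_monotone_clean(self):
        rows = []
        for ghs, mean in [("1", 1.0), ("2", 2.0), ("3", 3.0)]:
            rows.append({"ghs": ghs, "lts": mean})
        assert flag_nonmonotone_classes(pd.DataFrame(rows)) == []
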