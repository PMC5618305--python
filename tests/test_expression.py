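import numpy as np
import pandas as pd
import pytest

from mirloop import (
    ExpressionMatrix,
    bh_fdr,
    differential_expression,
    direction_concordance,
    generate_expression,
    overlap_sets,
    significant_genes,
)


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Step-up definition applied literally: sort, scale by m/rank, enforce
    monotonicity from the largest p down, clip at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    running = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(running, 1.0)
    return out


class TestBhFdr:
    def test_hand_computed_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_tied_pvalues_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert bh_fdr([0.1, 0.1, 0.1]) == pytest.approx([0.1, 0.1, 0.1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 60)))
            assert bh_fdr(p) == pytest.approx(bh_oracle(p), rel=1e-12)

    def test_nan_passthrough(self):
        out = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and not np.isnan(out[0])


def _matrix(values: np.ndarray, n_per_group: int = None) -> ExpressionMatrix:
    n = values.shape[1] // 2 if n_per_group is None else n_per_group
    samples = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(values.shape[1] - n)]
    groups = {s: ("control" if s.startswith("c") else "treated") for s in samples}
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), groups=groups
    )


class TestDifferentialExpression:
    def test_identical_groups_give_zero_effect_and_p_one(self):
        block = np.random.default_rng(1).normal(size=(20, 4))
        matrix = _matrix(np.hstack([block, block]))
        de = differential_expression(matrix, "control", "treated")
        assert np.allclose(de["effect"], 0)
        assert np.allclose(de["p"], 1.0)

    def test_constant_gene_flagged_undefined(self):
        values = np.vstack([np.ones(8), np.random.default_rng(2).normal(size=8)])
        de = differential_expression(_matrix(values), "control", "treated")
        assert np.isnan(de.loc[0, "p"]) and np.isnan(de.loc[0, "fdr"])
        assert not np.isnan(de.loc[1, "p"])

    def test_direction_follows_effect_sign(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(50, 10))
        values[:25, 5:] += 3.0
        values[25:, 5:] -= 3.0
        de = differential_expression(_matrix(values), "control", "treated")
        assert (de["direction"] == np.where(de["effect"] > 0, "up", "down")).all()
        assert (de.loc[:24, "direction"] == "up").all()

    def test_missing_group_rejected(self):
        matrix = _matrix(np.zeros((3, 8)))
        with pytest.raises(ValueError):
            differential_expression(matrix, "control", "mutant")

    def test_small_group_rejected(self):
        values = np.zeros((3, 3))
        with pytest.raises(ValueError, match="need >= 2"):
            differential_expression(_matrix(values, n_per_group=1), "control", "treated")

    def test_anova_detects_shift_across_three_groups(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(30, 12), scale=0.5)
        values[:10, 8:] += 2.0
        samples = (
            [f"c{i}" for i in range(4)]
            + [f"t{i}" for i in range(4)]
            + [f"x{i}" for i in range(4)]
        )
        groups = {s: {"c": "control", "t": "treated", "x": "late"}[s[0]] for s in samples}
        matrix = ExpressionMatrix(
            values=pd.DataFrame(values, index=[f"g{i}" for i in range(30)], columns=samples),
            groups=groups,
        )
        de = differential_expression(
            matrix, "control", "treated", method="anova", extra_groups=["late"]
        )
        assert (de.loc[:9, "fdr"] < 0.05).mean() > 0.8
        assert (de.loc[10:, "p"] > 0.01).mean() > 0.8

    def test_power_at_generator_defaults(self):
        """Most programmed DE genes are recovered at fdr < 0.05."""
        recalls = []
        for seed in range(5):
            mat, _, truth = generate_expression(n_genes=1000, n_de=100, seed=seed)
            de = differential_expression(mat, "control", "treated")
            sig = set(significant_genes(de))
            recalls.append(len(sig & set(truth.de_genes)) / len(truth.de_genes))
        assert np.median(recalls) >= 0.8


class TestOverlapAndConcordance:
    def test_overlap_examples(self):
        assert overlap_sets(["A", "B", "C"], ["B", "C", "D"]) == ["B", "C"]
        assert overlap_sets(["A"], ["B"]) == []
        assert overlap_sets(["Ccnb1"], ["CCNB1"]) == ["CCNB1"]

    def test_direction_percentages(self):
        dirs_a = {"g1": "up", "g2": "up", "g3": "down"}
        dirs_b = {"g1": "up", "g2": "down", "g3": "down"}
        oc = direction_concordance(dirs_a, dirs_b, ["g1", "g2", "g3"])
        assert oc.pct_same_direction == pytest.approx(200 / 3)
        assert oc.pct_both_up == pytest.approx(100 / 3)

    def test_all_up_and_fully_discordant(self):
        up = {"a": "up", "b": "up"}
        assert direction_concordance(up, up, ["a", "b"]).pct_both_up == 100.0
        down = {"a": "down", "b": "down"}
        oc = direction_concordance(up, down, ["a", "b"])
        assert oc.pct_same_direction == 0.0 and oc.pct_both_up == 0.0

    def test_empty_common_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            direction_concordance({"a": "up"}, {"a": "up"}, [])

    def test_self_concordance(self):
        rng = np.random.default_rng(5)
        dirs = {f"g{i}": ("up" if u < 0.3 else "down") for i, u in enumerate(rng.random(40))}
        oc = direction_concordance(dirs, dirs, list(dirs))
        assert oc.pct_same_direction == 100.0
        pct_up = 100 * sum(d == "up" for d in dirs.values()) / len(dirs)
        assert oc.pct_both_up == pytest.approx(pct_up)

    def test_invariant_both_up_bounded_by_same_direction(self):
        mat_a, mat_b, _ = generate_expression(n_genes=500, n_de=80, seed=9)
        de_a = differential_expression(mat_a, "control", "treated")
        de_b = differential_expression(mat_b, "control", "treated")
        common = overlap_sets(significant_genes(de_a), significant_genes(de_b))
        oc = direction_concordance(de_a, de_b, common)
        assert 0 <= oc.pct_both_up <= oc.pct_same_direction <= 100
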