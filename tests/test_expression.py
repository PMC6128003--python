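import itertools

import numpy as np
import pandas as pd
import pytest

from rlkfam import expression as ex
from rlkfam.types import RlkfamError


class TestRpkm:
    def test_closed_form(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g1"])
        out = ex.rpkm(counts, {"g1": 1000}, pd.Series({"s1": 1_000_000}))
        assert float(out.loc["g1", "s1"]) == pytest.approx(10.0)

    def test_zero_count_zero(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g1"])
        out = ex.rpkm(counts, {"g1": 500}, pd.Series({"s1": 1_000_000}))
        assert float(out.loc["g1", "s1"]) == 0.0

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s1": [10, 30], "s2": [5, 2]}, index=["g1", "g2"])
        lengths = {"g1": 1000, "g2": 2500}
        a = ex.rpkm(counts, lengths)
        b = ex.rpkm(counts * 2, lengths)
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestNormalize:
    def test_hand_computed_row(self):
        # [1,2,3] -> log2(+1): [1, 1.58496, 2]; z-scored to mean 0, sd 1
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        out = ex.normalize(m)
        logged = np.log2(np.array([1, 2, 3]) + 1)
        expected = (logged - logged.mean()) / logged.std()
        assert out.loc["g"].to_numpy() == pytest.approx(expected)
        assert out.loc["g"].mean() == pytest.approx(0, abs=1e-9)
        assert out.loc["g"].std(ddof=0) == pytest.approx(1, abs=1e-9)

    def test_constant_row_maps_to_zeros(self):
        m = pd.DataFrame([[4.0, 4.0, 4.0]], index=["g"], columns=list("abc"))
        assert (ex.normalize(m).loc["g"] == 0).all()

    def test_order_preserving_within_row(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(0, 100, size=(5, 8)).astype(float))
        out = ex.normalize(m)
        for i in range(5):
            assert list(np.argsort(m.iloc[i])) == list(np.argsort(out.iloc[i]))


def oracle_average_linkage(matrix):
    """Exhaustive agglomeration oracle for small n (1 - Pearson)."""
    items = {i: [i] for i in range(len(matrix))}
    corr = np.corrcoef(matrix)
    d = {(i, j): 1 - corr[i, j] for i, j in
         itertools.combinations(range(len(matrix)), 2)}
    merges = []
    while len(items) > 1:
        keys = sorted(items)
        best = min(
            ((i, j) for i, j in itertools.combinations(keys, 2)),
            key=lambda ij: (cluster_dist(items[ij[0]], items[ij[1]], d), ij),
        )
        merges.append(sorted(items[best[0]] + items[best[1]]))
        new_key = max(items) + 1
        items[new_key] = items.pop(best[0]) + items.pop(best[1])
    return merges


def cluster_dist(a, b, d):
    return float(np.mean([d[tuple(sorted((x, y)))] for x in a for y in b]))


class TestClustering:
    def test_identical_rows_merge_at_zero(self):
        m = pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [9, 1, 5, 2]],
            index=["a", "b", "c"], dtype=float,
        )
        linkage, order, _ = ex.hierarchical_cluster(m)
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)  # a,b perfectly correlated
        assert set(order) == {"a", "b", "c"}

    def test_three_row_merge_order_matches_oracle(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(3, 10)))
        linkage, _, _ = ex.hierarchical_cluster(m)
        oracle = oracle_average_linkage(m.to_numpy())
        first_pair = sorted(int(x) for x in linkage[0, :2])
        assert first_pair == oracle[0]

    def test_leaf_set_preserved(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(7, 5)),
                         index=[f"g{i}" for i in range(7)])
        _, order, reordered = ex.hierarchical_cluster(m)
        assert sorted(order) == sorted(m.index)
        assert reordered.shape == m.shape

    def test_planted_fiber_high_genes_cluster_together(self, small_config, tmp_path):
        """Genes planted with fiber-stage-specific expression co-cluster."""
        from scipy.cluster import hierarchy

        from rlkfam import io_formats
        from rlkfam.synthetic_data import generate_dataset

        hit_rates = []
        for seed in range(20):
            ds = generate_dataset(small_config, seed=100 + seed,
                                  out_dir=str(tmp_path / f"expr_{seed}"))
            counts = io_formats.read_counts(ds.paths["counts"])
            norm = ex.normalize(counts)
            linkage, order, _ = ex.hierarchical_cluster(norm)
            # top-level split: the two clusters merged last
            n = len(norm)
            tree = hierarchy.to_tree(linkage)
            left = {norm.index[i] for i in tree.left.pre_order()}
            right = {norm.index[i] for i in tree.right.pre_order()}
            high = {g for g, p in ds.truth.expression_pattern.items()
                    if p == "fiber_high"}
            frac = max(
                len(high & side) / len(high) for side in (left, right)
            )
            hit_rates.append(frac)
        assert sum(r >= 0.9 for r in hit_rates) >= 18


class TestDdct:
    def make(self, rows):
        return pd.DataFrame(rows, columns=["sample", "gene", "ct", "replicate",
                                           "group"])

    def test_hand_computed_fold(self):
        # treatment dCt = 5, calibrator dCt = 7 -> ddCt = -2 -> fold 4
        df = self.make([
            ("t1", "tgt", 20.0, 1, "treatment"),
            ("t1", "ref", 15.0, 1, "treatment"),
            ("c1", "tgt", 22.0, 1, "control"),
            ("c1", "ref", 15.0, 1, "control"),
        ])
        out = ex.ddct(df, "ref", "control")
        tr = out[out["group"] == "treatment"]
        assert float(tr["ddct"].iloc[0]) == pytest.approx(-2.0)
        assert float(tr["fold"].iloc[0]) == pytest.approx(4.0)

    def test_target_equal_reference_fold_one(self):
        df = self.make([
            (s, g, 18.0, 1, grp)
            for s, grp in [("c1", "control"), ("t1", "treatment")]
            for g in ("tgt", "ref")
        ])
        out = ex.ddct(df, "ref", "control")
        assert np.allclose(out["fold"], 1.0)

    def test_missing_reference_rejected(self):
        df = self.make([("t1", "tgt", 20.0, 1, "treatment"),
                        ("c1", "tgt", 22.0, 1, "control"),
                        ("c1", "ref", 15.0, 1, "control")])
        with pytest.raises(RlkfamError, match="reference"):
            ex.ddct(df, "ref", "control")

    def test_calibrator_geometric_mean_near_one(self, dataset):
        qpcr = ex.read_qpcr(dataset.paths["qpcr"])
        out = ex.ddct(qpcr, "GhActin2", "control")
        calib = out[out["group"] == "control"]["fold"]
        geo = float(np.exp(np.mean(np.log(calib))))
        assert geo == pytest.approx(1.0, abs=0.15)


class TestTtest:
    def test_identical_groups(self):
        t, p, stars = ex.ttest_annotate([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, p, stars) == (0.0, 1.0, "")

    def test_matches_closed_form_t_cdf(self):
        from scipy import stats

        a = np.array([3.1, 2.8, 3.6, 3.3, 2.9])
        b = np.array([2.1, 2.4, 1.9, 2.6, 2.2])
        t, p, stars = ex.ttest_annotate(a, b)
        # closed-form Student's t with pooled variance
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_exp = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p_exp = 2 * stats.t.sf(abs(t_exp), na + nb - 2)
        assert t == pytest.approx(t_exp, abs=1e-6)
        assert p == pytest.approx(p_exp, abs=1e-6)
        assert stars == "**"

    @pytest.mark.parametrize("p_target,stars", [(0.03, "*"), (0.2, ""), (0.005, "**")])
    def test_star_thresholds(self, p_target, stars):
        from scipy import stats

        # construct two groups with a prescribed p-value by shifting means
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1.0, size=8)
        other = base.copy()
        df = 2 * len(base) - 2
        t_needed = stats.t.isf(p_target / 2, df)
        sp = np.sqrt(base.var(ddof=1))
        other = other + t_needed * sp * np.sqrt(2 / len(base))
        t, p, got = ex.ttest_annotate(other, base)
        assert p == pytest.approx(p_target, abs=1e-9)
        assert got == stars
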