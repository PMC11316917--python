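import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sizestab.function_link import (
    LinkRecord,
    bh_adjust,
    d_values,
    multifunctionality,
    r_values,
    rho_matrix,
    size_regression,
    spearman_rho,
)
from sizestab.io_tables import CommunityTable


def brute_spearman(x, y):
    """Rank with mid-ranks, then Pearson — the definitional oracle."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


class TestMultifunctionality:
    def test_single_function_is_its_zscores(self):
        f = pd.DataFrame({"f1": [1.0, 2.0, 3.0]}, index=list("abc"))
        mf = multifunctionality(f)
        expected = (f["f1"] - 2.0) / f["f1"].std(ddof=0)
        pd.testing.assert_series_equal(mf, expected, check_names=False)

    def test_duplicate_function_changes_nothing(self):
        f = pd.DataFrame({"f1": [1.0, 2.0, 3.0], "f2": [1.0, 2.0, 3.0]},
                         index=list("abc"))
        mf = multifunctionality(f)
        single = multifunctionality(f[["f1"]])
        pd.testing.assert_series_equal(mf, single, check_names=False)

    def test_opposing_functions_cancel(self):
        f = pd.DataFrame({"up": [1.0, 2.0, 3.0], "down": [3.0, 2.0, 1.0]},
                         index=list("abc"))
        np.testing.assert_allclose(multifunctionality(f).to_numpy(), 0.0, atol=1e-12)

    def test_constant_function_dropped_with_warning(self, caplog):
        f = pd.DataFrame({"f1": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]},
                         index=list("abc"))
        with caplog.at_level("WARNING", logger="sizestab.function_link"):
            mf = multifunctionality(f)
        assert "flat" in caplog.text
        assert mf.mean() == pytest.approx(0.0, abs=1e-9)

    def test_all_constant_errors(self):
        f = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError):
            multifunctionality(f)


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_rho(x, [10, 20, 30, 40, 50])[0] == pytest.approx(1.0)
        assert spearman_rho(x, [5, 4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_shuffled_fixture(self):
        # sum of squared rank differences is 4 -> rho = 1 - 24/120 = 0.8
        rho, _ = spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-12)
        assert rho == pytest.approx(brute_spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(4, 30)
            x = rng.permutation(n).astype(float)  # tie-free
            y = rng.normal(size=n)
            assert spearman_rho(x, y)[0] == pytest.approx(
                brute_spearman(x, y), abs=1e-12
            )

    def test_tied_values_use_midranks(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, size=12).astype(float)
            y = rng.integers(0, 4, size=12).astype(float)
            if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
                continue
            assert spearman_rho(x, y)[0] == pytest.approx(
                brute_spearman(x, y), abs=1e-12
            )

    def test_exact_permutation_p_small_n(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho, p = spearman_rho(x, y)
        # enumerate the 120 permutations with an independent implementation
        obs = abs(brute_spearman(x, y))
        hits = sum(
            abs(brute_spearman(x, perm)) >= obs - 1e-12
            for perm in itertools.permutations(y)
        )
        assert p == pytest.approx(hits / math.factorial(5))

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(scale=2.0, size=40)
        rho, p = spearman_rho(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2, 3])


class TestRValues:
    def _setup(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        meta = pd.DataFrame(
            {
                "field_id": [f"f{i}" for i in range(n)],
                "crop": ["maize"] * n,
                "treatment": ["control"] * n,
            },
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        )
        mf_driver = rng.normal(size=n)
        groups = CommunityTable(
            pd.DataFrame(
                {"G1": np.exp(mf_driver), "G2": rng.uniform(0.1, 1, n)},
                index=meta.index,
            ),
            mode="counts",
        )
        functions = pd.DataFrame({"f1": mf_driver, "f2": mf_driver * 2},
                                 index=meta.index)
        return groups, functions, meta

    def test_perfectly_linked_group_has_r_one(self):
        groups, functions, meta = self._setup()
        recs = {r.group: r for r in r_values(groups, functions, meta)}
        assert recs["G1"].r_value == pytest.approx(1.0)
        assert recs["G1"].per_function_rho["f1"] == pytest.approx(1.0)

    def test_shuffled_abundance_centered_at_zero(self):
        rng = np.random.default_rng(1)
        groups, functions, meta = self._setup(n=30)
        rhos = []
        for _ in range(200):
            shuffled = CommunityTable(
                pd.DataFrame({"G1": rng.permutation(groups.data["G1"].to_numpy())},
                             index=groups.data.index),
                mode="counts",
            )
            rhos.append(r_values(shuffled, functions, meta)[0].r_value)
        se = np.std(rhos) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) < 2 * se + 0.02

    def test_small_stratum_skipped(self):
        groups, functions, meta = self._setup(n=3)
        assert r_values(groups, functions, meta) == []


class TestDValues:
    def _link(self, group, treatment, r):
        return LinkRecord(group, "maize", treatment, r, 0.5)

    def test_difference_and_antisymmetry(self):
        links = [self._link("G", "control", 0.2), self._link("G", "warming", 0.6)]
        (d,) = d_values(links)
        assert d.d_value == pytest.approx(0.4)
        flipped = [self._link("G", "control", 0.6), self._link("G", "warming", 0.2)]
        (d2,) = d_values(flipped)
        assert d2.d_value == pytest.approx(-0.4)

    def test_equal_r_gives_zero(self):
        links = [self._link("G", "control", 0.3), self._link("G", "N", 0.3)]
        assert d_values(links)[0].d_value == pytest.approx(0.0)

    def test_missing_control_errors(self):
        with pytest.raises(ValueError, match="G"):
            d_values([self._link("G", "warming", 0.6)])


class TestSizeRegression:
    def test_exact_line(self):
        sizes = {g: 10.0**i for i, g in enumerate("abcde")}
        metric = {g: -2 * math.log10(sizes[g]) + 1 for g in sizes}
        res = size_regression(metric, sizes)
        assert res.slope == pytest.approx(-2.0, abs=1e-9)
        assert res.intercept == pytest.approx(1.0, abs=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response(self):
        sizes = {g: 10.0**i for i, g in enumerate("abcd")}
        res = size_regression({g: 5.0 for g in sizes}, sizes)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)

    def test_four_point_fixture(self):
        # x=(0,1,2,3), y=(1,3,2,4): hand-solved normal equations
        sizes = {g: 10.0**i for i, g in enumerate("abcd")}
        res = size_regression(dict(zip("abcd", [1.0, 3.0, 2.0, 4.0])), sizes)
        assert res.slope == pytest.approx(0.8, abs=1e-12)
        assert res.intercept == pytest.approx(1.3, abs=1e-12)

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            size_regression({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 10.0})


class TestRhoMatrixAndBH:
    def test_matrix_layout(self):
        links = [
            LinkRecord("G1", "maize", "control", 0.5, 0.1, {"f1": 0.5, "f2": -0.2}),
            LinkRecord("G2", "maize", "control", 0.1, 0.9, {"f1": 0.0, "f2": 0.3}),
        ]
        m = rho_matrix(links, "control")
        assert m.shape == (2, 2)
        assert m.at["G1", "f2"] == pytest.approx(-0.2)

    def test_bh_monotone(self):
        p = [0.001, 0.01, 0.04, 0.5]
        adj = bh_adjust(p)
        assert (np.diff(adj) >= 0).all()
        assert (adj >= np.asarray(p)).all()
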