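import math

import numpy as np
import pandas as pd
import pytest

from sizestab.io_tables import CommunityTable
from sizestab.diversity_niche import (
    classify_generalists,
    community_breadth,
    group_gs_proportions,
    GSLabel,
    levins_breadth,
    shannon,
)


def brute_shannon(v):
    total = sum(v)
    return -sum((x / total) * math.log(x / total) for x in v if x > 0)


def brute_levins(p):
    return 1.0 / sum(x * x for x in p)


class TestShannon:
    @pytest.mark.parametrize(
        "v, expected",
        [
            ([1, 1, 1, 1], math.log(4)),
            ([1, 0, 0], 0.0),
            ([2, 1, 1], -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))),
        ],
    )
    def test_known_values(self, v, expected):
        assert shannon(v) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_matches_bruteforce(self, rng):
        for _ in range(100):
            v = rng.uniform(0, 5, size=rng.integers(2, 20))
            v[rng.random(len(v)) < 0.2] = 0.0
            if v.sum() == 0:
                continue
            assert shannon(v) == pytest.approx(brute_shannon(v), abs=1e-12)


class TestLevinsBreadth:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.5, 0.5], 2.0),
            ([1.0, 0.0, 0.0], 1.0),
            ([0.5, 0.25, 0.25], 1 / 0.375),
        ],
    )
    def test_known_values(self, p, expected):
        assert levins_breadth(p) == pytest.approx(expected, abs=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            levins_breadth([0.5, 0.4])

    def test_matches_bruteforce_and_bounds(self, rng):
        for _ in range(100):
            n = rng.integers(2, 15)
            p = rng.dirichlet(np.ones(n))
            b = levins_breadth(p)
            assert b == pytest.approx(brute_levins(p), abs=1e-12)
            assert 1.0 - 1e-9 <= b <= n + 1e-9


class TestCommunityBreadth:
    def _table(self, cols):
        df = pd.DataFrame(cols)
        df.index = [f"s{i}" for i in range(len(df))]
        return CommunityTable(df, mode="counts")

    def test_single_member_equals_own_breadth(self):
        t = self._table({"a": [5, 5, 0, 0]})
        assert community_breadth(t, ["a"]) == pytest.approx(2.0)

    def test_equal_weight_mean(self):
        # taxon a: B=2 (two habitats), taxon b: B=4 (uniform over four);
        # equal totals -> weighted mean 3.0
        t = self._table({"a": [5, 5, 0, 0], "b": [2.5, 2.5, 2.5, 2.5]})
        assert community_breadth(t, ["a", "b"]) == pytest.approx(3.0)

    def test_zero_abundance_member_ignored(self):
        t = self._table({"a": [5, 5, 0, 0], "z": [0, 0, 0, 0]})
        assert community_breadth(t, ["a", "z"]) == pytest.approx(
            community_breadth(t, ["a"])
        )

    def test_empty_member_set_errors(self):
        t = self._table({"a": [1, 2]})
        with pytest.raises(ValueError):
            community_breadth(t, [])


class TestClassifyGeneralists:
    def _equal_depth_table(self, n_samples=20, depth=1000, seed=0):
        rng = np.random.default_rng(seed)
        filler = rng.multinomial(depth - 150, np.ones(30) / 30,
                                 size=n_samples)
        uniform = np.full((n_samples, 1), 100)  # same count everywhere
        single = np.zeros((n_samples, 1), dtype=int)
        single[0, 0] = 100  # present in exactly one sample
        rare = np.zeros((n_samples, 1), dtype=int)
        rare[0, 0] = 5  # below min_count
        counts = np.hstack([uniform, single, rare, filler[:, :-1],
                            (filler[:, -1:] - 50 + 100)])
        counts = np.clip(counts, 0, None)
        cols = ["uniform", "single", "rare"] + [f"f{j}" for j in range(30)]
        return CommunityTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(n_samples)],
                         columns=cols),
            mode="counts",
        )

    def test_uniform_taxon_is_generalist(self):
        t = self._equal_depth_table()
        labels = {l.taxon_id: l for l in classify_generalists(t, n_perm=499, seed=1)}
        assert labels["uniform"].label == "generalist"
        assert labels["uniform"].observed_b == pytest.approx(t.n_samples)

    def test_single_sample_taxon_is_specialist(self):
        t = self._equal_depth_table()
        labels = {l.taxon_id: l for l in classify_generalists(t, n_perm=499, seed=1)}
        assert labels["single"].label == "specialist"
        assert labels["single"].observed_b == pytest.approx(1.0)

    def test_low_count_taxon_flagged_neutral(self):
        t = self._equal_depth_table()
        labels = {l.taxon_id: l for l in classify_generalists(t, n_perm=499, seed=1)}
        assert labels["rare"].label == "neutral"
        assert labels["rare"].low_power

    def test_reproducible_given_seed(self):
        t = self._equal_depth_table()
        a = classify_generalists(t, n_perm=199, seed=9)
        b = classify_generalists(t, n_perm=199, seed=9)
        assert [(l.taxon_id, l.label) for l in a] == [
            (l.taxon_id, l.label) for l in b
        ]

    def test_single_sample_table_rejected(self):
        t = CommunityTable(pd.DataFrame([[5, 5]], index=["s1"]), mode="counts")
        with pytest.raises(ValueError):
            classify_generalists(t, n_perm=199)


class TestGroupProportions:
    def _ann(self, mapping):
        return pd.DataFrame(
            {
                "domain": ["bacteria"] * len(mapping),
                "group": list(mapping.values()),
                "body_size_um": [1.0] * len(mapping),
            },
            index=pd.Index(list(mapping), name="taxon_id"),
        )

    def test_mixed_labels(self):
        labels = [
            GSLabel("a", "generalist", 3, 1, 2),
            GSLabel("b", "generalist", 3, 1, 2),
            GSLabel("c", "specialist", 1, 1.5, 2.5),
            GSLabel("d", "neutral", 2, 1, 3),
        ]
        ann = self._ann({"a": "G", "b": "G", "c": "G", "d": "G"})
        props = group_gs_proportions(labels, ann)
        assert props.at["G", "prop_generalists"] == pytest.approx(0.5)
        assert props.at["G", "prop_specialists"] == pytest.approx(0.25)

    def test_all_neutral(self):
        labels = [GSLabel(t, "neutral", 2, 1, 3) for t in "ab"]
        props = group_gs_proportions(labels, self._ann({"a": "G", "b": "G"}))
        assert props.at["G", "prop_generalists"] == 0.0
        assert props.at["G", "prop_specialists"] == 0.0

    def test_taxa_weighted_group_mean_matches_global(self, rng):
        taxa = [f"t{i}" for i in range(40)]
        mapping = {t: f"G{i % 4}" for i, t in enumerate(taxa)}
        labs = [
            GSLabel(t, rng.choice(["generalist", "specialist", "neutral"]), 2, 1, 3)
            for t in taxa
        ]
        props = group_gs_proportions(labs, self._ann(mapping))
        weighted = (props["prop_generalists"] * props["n_taxa"]).sum() / props[
            "n_taxa"
        ].sum()
        global_rate = np.mean([l.label == "generalist" for l in labs])
        assert weighted == pytest.approx(global_rate)
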