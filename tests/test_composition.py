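import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from nichevar.composition import (
    bray_curtis,
    dispersion_homogeneity,
    nmds,
    pairwise_bray_curtis,
    permanova,
    permanova_two_way,
    simper,
    stress1,
)
from nichevar.resource_data import ExperimentDesign, ValidationError

# Reference values computed with vegan 2.7 on the toy_compositions
# fixture: adonis2(dist ~ comp*pred, by="terms"), betadisper(...,
# type="centroid"), simper(x, comp).
VEGAN_ADONIS2 = {
    "competition": {"ss": 0.114596, "r2": 0.194642, "f": 2.535340},
    "predation": {"ss": -0.002975, "r2": -0.005053, "f": -0.065822},
    "competition:predation": {"ss": 0.070338, "r2": 0.119469, "f": 1.556166},
    "residual": {"ss": 0.406797, "r2": 0.690943},
}
VEGAN_BETADISPER_DISTS = [
    0.1606604, 0.1739055, 0.1027108, 0.1078029, 0.1298306, 0.2001687,
    0.1469146, 0.1562554, 0.1746097, 0.3240101, 0.1003583, 0.1368787,
    0.2477278,
]
VEGAN_BETADISPER_F = 0.4128383
VEGAN_SIMPER_AVERAGE = {
    "a": 0.05599256, "b": 0.07546393, "c": 0.05619121,
    "d": 0.07027479, "e": 0.05629031,
}


def _euclid_frame(y: np.ndarray) -> pd.DataFrame:
    d = np.abs(y[:, None] - y[None, :])
    return pd.DataFrame(d, index=range(len(y)), columns=range(len(y)))


def _toy_factors(toy_compositions) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "competition": toy_compositions.attrs["comp"],
            "predation": toy_compositions.attrs["pred"],
        },
        index=toy_compositions.index,
    )


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 0], [0, 1], 1.0),
            ([2, 1], [1, 2], 1 / 3),
        ],
    )
    def test_values(self, x, y, expected):
        assert bray_curtis(x, y) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(ValidationError):
            bray_curtis([0, 0], [0, 0])

    def test_pairwise_matrix_properties(self, toy_compositions):
        d = pairwise_bray_curtis(toy_compositions)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        assert ((arr >= 0) & (arr <= 1)).all()


class TestPermanova:
    def test_pseudo_f_equals_classical_anova_f(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=12)
        g = np.repeat(["a", "b", "c"], 4)
        table = permanova(
            _euclid_frame(y),
            pd.DataFrame({"g": g}, index=range(12)),
            ["g"],
            n_perm=9,
            seed=0,
        )
        f_classic = stats.f_oneway(*[y[g == lab] for lab in "abc"]).statistic
        assert table.loc["g", "pseudo_f"] == pytest.approx(f_classic, abs=1e-9)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        from itertools import combinations

        y = np.array([0.3, 1.2, 0.7, 2.4, 2.0, 3.1])
        g = np.array(["x"] * 3 + ["y"] * 3)
        table = permanova(
            _euclid_frame(y), pd.DataFrame({"g": g}), ["g"], exhaustive=True
        )
        f_obs = stats.f_oneway(y[:3], y[3:]).statistic
        f_all = [
            stats.f_oneway(y[list(c)], np.delete(y, list(c))).statistic
            for c in combinations(range(6), 3)
        ]
        p_exact = np.mean(np.array(f_all) >= f_obs - 1e-12)
        assert table.loc["g", "p"] == pytest.approx(p_exact, abs=1e-12)

    def test_separated_identical_groups(self):
        # two tight clusters: group term explains everything
        y = np.array([0.0, 0.0, 0.0, 5.0, 5.0, 5.0])
        table = permanova(
            _euclid_frame(y), pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3}),
            ["g"], exhaustive=True,
        )
        assert table.loc["g", "r2"] == pytest.approx(1.0, abs=1e-9)
        # minimum attainable: only group-preserving relabellings tie
        assert table.loc["g", "p"] == pytest.approx(0.1)

    def test_matches_adonis2_sequential(self, toy_compositions):
        dist = pairwise_bray_curtis(toy_compositions)
        table = permanova(
            dist, _toy_factors(toy_compositions),
            ["competition", "predation", "competition:predation"],
            n_perm=99, seed=0,
        )
        for term, ref in VEGAN_ADONIS2.items():
            assert table.loc[term, "ss"] == pytest.approx(ref["ss"], abs=2e-6)
            assert table.loc[term, "r2"] == pytest.approx(ref["r2"], abs=2e-6)
            if "f" in ref:
                assert table.loc[term, "pseudo_f"] == pytest.approx(
                    ref["f"], abs=2e-5
                )

    def test_matches_skbio_one_way(self, toy_compositions):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        dist = pairwise_bray_curtis(toy_compositions)
        mine = permanova(
            dist, _toy_factors(toy_compositions), ["competition"],
            n_perm=9, seed=0,
        )
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dist.to_numpy(), ids=list(dist.index)),
            grouping=list(map(str, toy_compositions.attrs["comp"])),
            permutations=9,
        )
        assert mine.loc["competition", "pseudo_f"] == pytest.approx(
            ref["test statistic"], abs=1e-9
        )

    def test_r2_partition_sums_to_one(self, toy_compositions):
        dist = pairwise_bray_curtis(toy_compositions)
        table = permanova_two_way(
            dist, _toy_factors(toy_compositions), n_perm=9, seed=0
        )
        terms = ["competition", "predation", "competition:predation", "residual"]
        assert table.loc[terms, "r2"].sum() == pytest.approx(1.0, abs=1e-9)
        assert table["df"].iloc[:-1].sum() == len(toy_compositions) - 1

    def test_p_invariant_to_category_relabelling(self, toy_compositions):
        cols = list(toy_compositions.columns)
        shuffled = toy_compositions[cols[::-1]]
        a = permanova_two_way(
            pairwise_bray_curtis(toy_compositions),
            _toy_factors(toy_compositions), n_perm=49, seed=5,
        )
        b = permanova_two_way(
            pairwise_bray_curtis(shuffled),
            _toy_factors(toy_compositions), n_perm=49, seed=5,
        )
        assert a["p"].iloc[:3].tolist() == b["p"].iloc[:3].tolist()

    def test_unknown_tank_in_design_rejected(self, toy_compositions):
        design = ExperimentDesign({"other": (0, 0), "other2": (1, 1)})
        with pytest.raises(ValidationError, match="missing"):
            permanova_two_way(
                pairwise_bray_curtis(toy_compositions), design, n_perm=9
            )

    def test_constant_distance_matrix_rejected(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        with pytest.raises(ValidationError, match="constant"):
            permanova(d, pd.DataFrame({"g": list("aabb")}), ["g"], n_perm=9)


class TestDispersionHomogeneity:
    def test_matches_betadisper_centroid(self, toy_compositions):
        dist = pairwise_bray_curtis(toy_compositions)
        groups = pd.Series(
            [
                f"{c}.{p}"
                for c, p in zip(
                    toy_compositions.attrs["comp"], toy_compositions.attrs["pred"]
                )
            ],
            index=toy_compositions.index,
        )
        res = dispersion_homogeneity(dist, groups, n_perm=99, seed=0)
        assert res.distances.to_numpy() == pytest.approx(
            VEGAN_BETADISPER_DISTS, abs=1e-7
        )
        assert res.f == pytest.approx(VEGAN_BETADISPER_F, abs=1e-7)

    def test_one_dimensional_euclidean_oracle(self):
        y = np.array([0.0, 1.0, 5.0, 1.0, 2.0, 9.0])
        groups = pd.Series(list("aaabbb"), index=range(6))
        res = dispersion_homogeneity(_euclid_frame(y), groups, n_perm=9, seed=0)
        expected = np.abs(
            y - np.array([y[:3].mean()] * 3 + [y[3:].mean()] * 3)
        )
        assert res.distances.to_numpy() == pytest.approx(expected, abs=1e-9)

    def test_identical_points_have_zero_dispersion(self):
        pts = np.array([[0.0], [0.0], [0.0], [3.0], [4.0], [5.0]])
        d = pd.DataFrame(squareform(pdist(pts)))
        res = dispersion_homogeneity(
            d, pd.Series(list("aaabbb")), n_perm=9, seed=0
        )
        assert res.distances.iloc[:3].to_numpy() == pytest.approx(0.0, abs=1e-9)

    def test_identical_internal_geometry_not_rejected(self):
        pts = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        d = pd.DataFrame(squareform(pdist(pts)))
        res = dispersion_homogeneity(
            d, pd.Series(list("aaabbb")), n_perm=199, seed=0
        )
        assert res.f == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.9

    def test_translation_invariance(self, rng):
        pts = rng.normal(size=(8, 3))
        groups = pd.Series(list("aaaabbbb"))
        d1 = pd.DataFrame(squareform(pdist(pts)))
        d2 = pd.DataFrame(squareform(pdist(pts + 7.5)))
        r1 = dispersion_homogeneity(d1, groups, n_perm=9, seed=1)
        r2 = dispersion_homogeneity(d2, groups, n_perm=9, seed=1)
        assert r1.distances.to_numpy() == pytest.approx(
            r2.distances.to_numpy(), abs=1e-8
        )

    def test_singleton_group_rejected(self):
        d = pd.DataFrame(squareform(pdist(np.arange(5)[:, None] * 1.0)))
        with pytest.raises(ValidationError, match="fewer than 2"):
            dispersion_homogeneity(d, pd.Series(list("aaab" + "c")), n_perm=9)


class TestSimper:
    def test_single_pair_hand_computation(self):
        comps = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], columns=["x", "y"])
        table = simper(comps, pd.Series(["g1", "g2"]), n_perm=19, seed=0)
        assert table["contribution"].to_numpy() == pytest.approx([0.5, 0.5])
        assert table.attrs["mean_between_group_bc"] == pytest.approx(1.0)

    def test_contributions_sum_to_mean_between_group_bc(self, rng):
        for _ in range(25):
            n, k = int(rng.integers(4, 10)), int(rng.integers(2, 8))
            x = rng.dirichlet(np.ones(k), size=n)
            comps = pd.DataFrame(x)
            groups = pd.Series(rng.permutation(["a"] * (n // 2) + ["b"] * (n - n // 2)))
            table = simper(comps, groups, n_perm=1, seed=0)
            a = x[(groups == "a").to_numpy()]
            b = x[(groups == "b").to_numpy()]
            bc = np.mean(
                [
                    np.abs(u - v).sum() / (u + v).sum()
                    for u in a
                    for v in b
                ]
            )
            assert table["contribution"].sum() == pytest.approx(bc, abs=1e-10)

    def test_matches_vegan_average_contributions(self, toy_compositions):
        groups = pd.Series(
            np.where(toy_compositions.attrs["comp"] == 0, "g0", "g1"),
            index=toy_compositions.index,
        )
        table = simper(toy_compositions, groups, n_perm=9, seed=0)
        for cat, ref in VEGAN_SIMPER_AVERAGE.items():
            assert table.loc[cat, "contribution"] == pytest.approx(ref, abs=1e-7)

    def test_identical_groups_not_significant(self, rng):
        x = rng.dirichlet(np.ones(4), size=4)
        comps = pd.DataFrame(np.vstack([x, x]))
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        table = simper(comps, groups, n_perm=199, seed=0)
        assert (table["p"] > 0.2).all()

    def test_three_groups_rejected(self, toy_compositions):
        groups = pd.Series(
            ["a", "b", "c"] * 5, index=list(toy_compositions.index) + ["x", "y"]
        )
        with pytest.raises(ValidationError, match="two groups"):
            simper(toy_compositions, groups.iloc[:13], n_perm=9)


def pav_oracle(x, y):
    """Pool-adjacent-violators, ties in x averaged first (independent
    of sklearn's isotonic regression)."""
    order = np.argsort(x, kind="stable")
    xs, ys = np.asarray(x)[order], np.asarray(y)[order]
    ux, inv = np.unique(xs, return_inverse=True)
    vals = np.array([ys[inv == i].mean() for i in range(len(ux))])
    wts = np.array([(inv == i).sum() for i in range(len(ux))], dtype=float)
    blocks = [[v, w] for v, w in zip(vals, wts)]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0] + 1e-15:
            v = (
                blocks[i][0] * blocks[i][1] + blocks[i + 1][0] * blocks[i + 1][1]
            ) / (blocks[i][1] + blocks[i + 1][1])
            blocks[i] = [v, blocks[i][1] + blocks[i + 1][1]]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    fitted_unique = np.concatenate(
        [np.full(int(w), v) for v, w in blocks]
    )
    # expand back: fitted per unique x, then per original sample
    per_unique = []
    pos = 0
    for i in range(len(ux)):
        cnt = int(wts[i])
        per_unique.append(fitted_unique[pos])
        pos += cnt
    fitted = np.array(per_unique)[inv]
    out = np.empty_like(fitted)
    out[order] = fitted
    return out


class TestNmds:
    def test_recovers_embeddable_configuration(self, rng):
        pts = rng.normal(size=(10, 2))
        d = pd.DataFrame(squareform(pdist(pts)))
        res = nmds(d, k=2, n_starts=5, seed=0)
        assert res.stress < 0.01
        assert res.converged

    def test_stress_matches_pav_oracle(self, rng):
        pts = rng.normal(size=(8, 2))
        d = pd.DataFrame(squareform(pdist(rng.normal(size=(8, 3)))))
        diss = squareform(d.to_numpy(), checks=False)
        conf = pdist(pts)
        disp = pav_oracle(diss, conf)
        expected = np.sqrt(((conf - disp) ** 2).sum() / (conf**2).sum())
        assert stress1(d, pts) == pytest.approx(expected, abs=1e-12)

    def test_deterministic_given_seed(self, toy_compositions):
        d = pairwise_bray_curtis(toy_compositions)
        a = nmds(d, n_starts=3, seed=7)
        b = nmds(d, n_starts=3, seed=7)
        assert np.array_equal(a.coordinates.to_numpy(), b.coordinates.to_numpy())
        assert a.stress == b.stress

    def test_stress_scale_invariant(self, rng):
        pts = rng.normal(size=(9, 2))
        d = pd.DataFrame(squareform(pdist(rng.normal(size=(9, 4)))))
        s1 = stress1(d, pts)
        s2 = stress1(d * 3.7, pts)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_too_few_samples_rejected(self):
        d = pd.DataFrame(squareform(pdist(np.arange(3)[:, None] * 1.0)))
        with pytest.raises(ValidationError, match="at least"):
            nmds(d, k=2)
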