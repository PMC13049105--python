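"""Community structure: covers, biomass, classification, Bray-Curtis, PERMANOVA."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventflux.community import (
    CommunityError,
    SpeciesRecord,
    TileObservation,
    biomass_estimate,
    bray_curtis,
    classify_community,
    cover_from_grid,
    permanova,
    richness_change,
    standardize_to_t0,
)


def obs(counts, side="front", tile="t1", tp="T0"):
    return TileObservation(tile_id=tile, side=side, time_point=tp,
                           squares_occupied=counts)


def make_registry():
    return {
        "calc_alga": SpeciesRecord("calc_alga", "Rhodophyta",
                                   frozenset({"calcifier", "primary_producer"}), 0.5),
        "fleshy_alga": SpeciesRecord("fleshy_alga", "Phaeophyceae",
                                     frozenset({"primary_producer"}), 0.2),
        "sponge": SpeciesRecord("sponge", "Porifera",
                                frozenset({"filter_feeder"}), 0.3),
    }


class TestCoverFromGrid:
    def test_full_occupancy_is_100(self):
        assert cover_from_grid(obs({"a": 25})) == {"a": 100.0}

    def test_five_squares_is_20(self):
        assert cover_from_grid(obs({"a": 5}))["a"] == pytest.approx(20.0)

    def test_layered_covers_rescaled_to_100(self):
        covers = cover_from_grid(obs({"a": 20, "b": 10}))
        assert covers["a"] == pytest.approx(200.0 / 3)
        assert covers["b"] == pytest.approx(100.0 / 3)
        assert sum(covers.values()) == pytest.approx(100.0)

    def test_unlayered_covers_left_unscaled(self):
        covers = cover_from_grid(obs({"a": 10, "b": 5}))
        assert covers == {"a": 40.0, "b": 20.0}

    def test_count_over_25_rejected(self):
        with pytest.raises(CommunityError):
            obs({"a": 26})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.dictionaries(st.sampled_from(list("abcdef")),
                           st.integers(0, 25), min_size=1))
    def test_output_never_exceeds_100_per_side(self, counts):
        assert sum(cover_from_grid(obs(counts)).values()) <= 100.0 + 1e-9


class TestBiomass:
    def test_single_species_full_cover_hand_value(self):
        """100% cover at 0.5 g per 25 cm2 patch on a 225 cm2 side -> 4.5 g."""
        reg = make_registry()
        b = biomass_estimate({"front": {"calc_alga": 100.0}}, reg)
        assert b == pytest.approx(0.5 * 225 / 25)

    def test_zero_cover_gives_zero(self):
        assert biomass_estimate({"front": {}, "back": {}}, make_registry()) == 0.0

    def test_linear_in_cover(self):
        reg = make_registry()
        covers = {"front": {"calc_alga": 30.0, "fleshy_alga": 20.0}}
        doubled = {"front": {"calc_alga": 60.0, "fleshy_alga": 40.0}}
        assert biomass_estimate(doubled, reg) == pytest.approx(
            2 * biomass_estimate(covers, reg))

    def test_both_sides_summed(self):
        reg = make_registry()
        b = biomass_estimate(
            {"front": {"calc_alga": 50.0}, "back": {"sponge": 50.0}}, reg)
        assert b == pytest.approx((0.5 + 0.3) * 0.5 * 9)

    def test_missing_species_reported(self):
        with pytest.raises(CommunityError, match="mystery"):
            biomass_estimate({"front": {"mystery": 10.0}}, make_registry())


class TestClassification:
    def test_pure_calcifying(self):
        label, _ = classify_community({"calc_alga": 80.0}, make_registry())
        assert label == "calcifying"

    def test_pure_fleshy(self):
        label, _ = classify_community({"fleshy_alga": 80.0}, make_registry())
        assert label == "fleshy"

    def test_even_split_is_mixed(self):
        label, _ = classify_community(
            {"calc_alga": 40.0, "fleshy_alga": 40.0}, make_registry())
        assert label == "mixed"

    def test_invariant_to_uniform_rescaling(self):
        reg = make_registry()
        covers = {"calc_alga": 50.0, "fleshy_alga": 20.0}
        halved = {k: v / 2 for k, v in covers.items()}
        assert classify_community(covers, reg) == classify_community(halved, reg)

    def test_no_algae_flagged_mixed(self):
        label, flags = classify_community({"sponge": 60.0}, make_registry())
        assert label == "mixed" and "no_algae" in flags


class TestRichness:
    def test_identical_observations_zero_loss(self):
        o = [obs({"a": 3, "b": 2})]
        assert richness_change(o, o) == 0

    def test_loss_counted_over_both_sides(self):
        t0 = [obs({"a": 3, "b": 2}), obs({"c": 1}, side="back")]
        t1 = [obs({"a": 1}), obs({}, side="back")]
        assert richness_change(t1, t0) == 2

    def test_empty_tile_loses_initial_richness(self):
        t0 = [obs({"a": 3, "b": 2, "c": 1})]
        assert richness_change([obs({})], t0) == 3

    def test_colonization_warns(self):
        t0 = [obs({"a": 3})]
        t1 = [obs({"a": 3, "z": 1})]
        with pytest.warns(UserWarning, match="colonization"):
            assert richness_change(t1, t0) == -1


class TestStandardizeToT0:
    def test_identity_at_t0(self):
        assert standardize_to_t0([10.0], 10.0)[0] == pytest.approx(1.0)

    def test_biomass_collapse_ratio(self):
        assert standardize_to_t0([0.1], 10.0)[0] == pytest.approx(0.01)

    def test_sign_flip_preserved(self):
        assert standardize_to_t0([-5.0], 5.0)[0] == pytest.approx(-1.0)

    def test_zero_t0_ratio_rejected_with_hint(self):
        with pytest.raises(CommunityError, match="difference"):
            standardize_to_t0([1.0], 0.0)

    def test_difference_mode(self):
        out = standardize_to_t0([1.0, 3.0], 1.0, mode="difference")
        np.testing.assert_allclose(out, [0.0, 2.0])


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d, _ = bray_curtis([[1.0, 2.0], [1.0, 2.0]])
        assert d[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        d, _ = bray_curtis([[10.0, 0.0], [0.0, 5.0]])
        assert d[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        d, _ = bray_curtis([[10.0, 0.0], [5.0, 5.0]])
        assert d[0, 1] == pytest.approx(0.5)

    def test_all_zero_pair_flagged_zero(self):
        d, flags = bray_curtis([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        assert d[0, 1] == 0.0
        assert any(f.startswith("all_zero_pair") for f in flags)
        assert d[0, 2] == pytest.approx(1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.floats(0.0, 100.0), min_size=3, max_size=3),
                    min_size=2, max_size=6))
    def test_metric_properties(self, rows):
        d, _ = bray_curtis(rows)
        assert np.all(d >= -1e-12) and np.all(d <= 1 + 1e-12)
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert np.all(np.diag(d) == 0)


def _oracle_pseudo_f(d, labels):
    """Independent pseudo-F: direct double loop over the definition."""
    labels = list(labels)
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_within += sum(
            d[i][j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (len(groups) - 1)) / (ss_within / (n - len(groups)))


class TestPermanova:
    def _toy(self, rng, n_per=3, shift=0.0):
        x = np.vstack([
            rng.uniform(1, 10, (n_per, 4)),
            rng.uniform(1, 10, (n_per, 4)) + shift,
        ])
        labels = ["a"] * n_per + ["b"] * n_per
        d, _ = bray_curtis(x)
        return d, labels

    def test_exhaustive_matches_independent_enumeration(self, rng):
        """Exact p over all label orderings agrees with a brute-force oracle."""
        d, labels = self._toy(rng)
        res = permanova(d, labels, exhaustive=True)
        f_obs = _oracle_pseudo_f(d, labels)
        assert res.pseudo_f == pytest.approx(f_obs, rel=1e-10)
        perms = set(itertools.permutations(labels))
        f_all = [_oracle_pseudo_f(d, p) for p in perms]
        p_oracle = np.mean([f >= f_obs - 1e-12 for f in f_all])
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_maximal_separation_attains_minimum_p(self, rng):
        d, labels = self._toy(rng, shift=1000.0)
        res = permanova(d, labels, exhaustive=True)
        # 20 distinct orderings; only the 2 label-swapped ones tie the observed F
        assert res.p_value == pytest.approx(2.0 / 20.0)

    def test_r_squared_is_among_fraction(self, rng):
        d, labels = self._toy(rng, shift=5.0)
        res = permanova(d, labels, n_permutations=99, seed=1)
        assert 0.0 <= res.r_squared <= 1.0

    def test_matches_scikit_bio_pseudo_f(self, rng):
        """Independent cross-check of the statistic against scikit-bio."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix

        d, labels = self._toy(rng, n_per=4, shift=2.0)
        ours = permanova(d, labels, n_permutations=99, seed=0)
        theirs = skbio_stats.permanova(
            DistanceMatrix(d, ids=[str(i) for i in range(8)]), labels,
            permutations=99,
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_small_groups_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(CommunityError):
            permanova(d, ["a", "a", "b"], n_permutations=9, seed=0)

    def test_null_p_values_uniform_on_support(self, rng):
        """Under label exchange the p-value is ~uniform (mean ~0.5)."""
        ps = []
        for i in range(100):
            r = np.random.default_rng(i)
            d, labels = self._toy(r)
            ps.append(permanova(d, labels, n_permutations=99, seed=i).p_value)
        assert 0.40 < np.mean(ps) < 0.60
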