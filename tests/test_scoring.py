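"""Quintile-rank scoring and the Keys Score formula."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietcvd.catalog import CatalogError, FoodGroup, FoodGroupCatalog
from dietcvd.scoring import (
    assign_quintile_points,
    compute_apdqs,
    compute_keys_score,
    macronutrient_percent_energy,
    quintile_cut_points,
)


# ---------------------------------------------------------------------------
# independent brute-force oracle: manual percentile interpolation + scan
# ---------------------------------------------------------------------------

def _oracle_cuts(values):
    """20/40/60/80th percentiles by hand (linear interpolation on sorted order)."""
    v = sorted(x for x in values if not np.isnan(x))
    n = len(v)
    cuts = []
    for q in (0.2, 0.4, 0.6, 0.8):
        h = q * (n - 1)
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        cuts.append(v[lo] + (h - lo) * (v[hi] - v[lo]))
    return cuts


def _oracle_points(values, rating):
    cuts = _oracle_cuts(values)
    out = []
    for x in values:
        if np.isnan(x):
            out.append(np.nan)
            continue
        cat = sum(1 for c in cuts if x > c)
        out.append(4 - cat if rating == "adverse" else cat)
    return np.array(out, dtype=float)


class TestQuintilePoints:
    @pytest.mark.parametrize(
        "values,rating,expected",
        [
            (np.arange(1, 11), "beneficial", [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]),
            (np.arange(1, 11), "adverse", [4, 4, 3, 3, 2, 2, 1, 1, 0, 0]),
            (np.full(8, 2.5), "beneficial", [0] * 8),  # degenerate collapse
        ],
    )
    def test_known_rankings(self, values, rating, expected):
        np.testing.assert_array_equal(
            assign_quintile_points(values, rating), np.array(expected, dtype=float)
        )

    def test_zero_consumers_collapse_downward(self):
        # 40% zeros: the two lowest cut points coincide at 0, so zero intake
        # of a beneficial group scores 0 and of an adverse group scores 4
        values = np.array([0, 0, 0, 0, 1, 2, 3, 4, 5, 6], dtype=float)
        pts_b = assign_quintile_points(values, "beneficial")
        pts_a = assign_quintile_points(values, "adverse")
        assert np.all(pts_b[values == 0] == 0)
        assert np.all(pts_a[values == 0] == 4)

    def test_reverse_symmetry_and_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = rng.gamma(0.8, 1.5, size=rng.integers(5, 40))
            b = assign_quintile_points(values, "beneficial")
            a = assign_quintile_points(values, "adverse")
            np.testing.assert_array_equal(b + a, np.full(values.size, 4.0))
            np.testing.assert_array_equal(b, _oracle_points(values, "beneficial"))

    def test_rejects_neutral_and_all_missing(self):
        with pytest.raises(ValueError, match="neutral"):
            assign_quintile_points([1, 2, 3, 4, 5], "neutral")
        with pytest.raises(ValueError):
            assign_quintile_points([np.nan] * 6, "beneficial")
        with pytest.raises(ValueError, match="at least 5"):
            quintile_cut_points([1.0, 2.0, 3.0])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(0, 50, allow_nan=False), min_size=5, max_size=60),
        st.integers(0, 59),
        st.floats(0.1, 10),
    )
    def test_monotone_in_own_intake(self, values, idx, bump):
        """Raising one person's intake never lowers their beneficial points."""
        values = np.asarray(values)
        idx = idx % values.size
        before = assign_quintile_points(values, "beneficial")[idx]
        bumped = values.copy()
        bumped[idx] += bump
        after = assign_quintile_points(bumped, "beneficial")[idx]
        assert after >= before


class TestApdqs:
    def toy_intakes(self, rng, n, catalog):
        data = {g: rng.gamma(1.0, 1.0, n) for g in catalog.group_ids}
        return pd.DataFrame(data, index=pd.RangeIndex(n, name="participant_id"))

    def test_matches_brute_force_oracle(self, catalog):
        rng = np.random.default_rng(11)
        intakes = self.toy_intakes(rng, 23, catalog)
        got = compute_apdqs(intakes, catalog)
        expected = np.zeros(len(intakes))
        for g in catalog.group_ids:
            rating = catalog.rating_of(g)
            if rating == "neutral":
                continue
            expected += _oracle_points(intakes[g].to_numpy(), rating)
        np.testing.assert_array_equal(got["apdqs"].to_numpy(), expected)
        # score conservation: total equals sum of stored per-group points
        pts = got[[c for c in got.columns if c.startswith("points_")]]
        np.testing.assert_allclose(got["apdqs"], pts.sum(axis=1))
        assert got["apdqs"].between(0, 132).all()

    def test_extreme_cohorts_reach_bounds(self, catalog):
        """Top-quintile beneficial + bottom-quintile adverse intake scores 132;
        the reverse pattern scores 0."""
        n = 10
        hi = pd.DataFrame(index=pd.RangeIndex(n))
        for g in catalog.group_ids:
            rating = catalog.rating_of(g)
            base = np.linspace(1, 2, n)
            col = base.copy()
            if rating == "beneficial":
                col[0] = 100.0  # beyond every cut point
            elif rating == "adverse":
                col[0] = 0.0    # below every cut point
            hi[g] = col
        scored = compute_apdqs(hi, catalog)
        assert scored["apdqs"].iloc[0] == 132
        lo = pd.DataFrame(index=pd.RangeIndex(n))
        for g in catalog.group_ids:
            rating = catalog.rating_of(g)
            col = np.linspace(1, 2, n)
            if rating == "beneficial":
                col[0] = 0.0
            elif rating == "adverse":
                col[0] = 100.0
            lo[g] = col
        assert compute_apdqs(lo, catalog)["apdqs"].iloc[0] == 0

    def test_neutral_invariance(self, catalog):
        rng = np.random.default_rng(5)
        intakes = self.toy_intakes(rng, 15, catalog)
        before = compute_apdqs(intakes, catalog)["apdqs"]
        perturbed = intakes.copy()
        for g in catalog.groups_with_rating("neutral"):
            perturbed[g] = rng.gamma(1.0, 3.0, len(intakes))
        after = compute_apdqs(perturbed, catalog)["apdqs"]
        np.testing.assert_array_equal(before, after)

    def test_missing_group_value_gives_missing_score(self, catalog):
        rng = np.random.default_rng(6)
        intakes = self.toy_intakes(rng, 12, catalog)
        intakes.loc[3, "fruit"] = np.nan
        scored = compute_apdqs(intakes, catalog)
        assert np.isnan(scored.loc[3, "apdqs"])
        assert scored["apdqs"].drop(3).notna().all()

    def test_errors(self, catalog):
        rng = np.random.default_rng(7)
        intakes = self.toy_intakes(rng, 12, catalog)
        with pytest.raises(KeyError, match="fruit"):
            compute_apdqs(intakes.drop(columns=["fruit"]), catalog)
        with pytest.raises(ValueError, match="at least 5"):
            compute_apdqs(intakes.head(4), catalog)
        bad = intakes.copy()
        bad.loc[0, "fruit"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            compute_apdqs(bad, catalog)


class TestKeysScore:
    def test_printed_formula_on_quintile_means(self):
        # extreme-quintile nutrient means land inside the printed score ranges
        q5 = compute_keys_score(18.0, 6.10, 228.0)
        q1 = compute_keys_score(10.5, 7.70, 113.0)
        assert q5 == pytest.approx(63.01, abs=0.01)
        assert q1 == pytest.approx(33.90, abs=0.01)
        assert q5 >= 57 and q1 <= 39

    def test_zero_inputs_vanish(self):
        assert compute_keys_score(0.0, 0.0, 0.0) == 0.0

    def test_monotone_directions(self):
        base = compute_keys_score(14.0, 7.0, 160.0)
        assert compute_keys_score(15.0, 7.0, 160.0) > base
        assert compute_keys_score(14.0, 8.0, 160.0) < base
        assert compute_keys_score(14.0, 7.0, 200.0) > base

    def test_missing_and_negative(self):
        assert np.isnan(compute_keys_score(np.nan, 7.0, 160.0))
        with pytest.raises(ValueError):
            compute_keys_score(14.0, 7.0, -5.0)


class TestPercentEnergy:
    def test_hand_arithmetic(self):
        out = macronutrient_percent_energy(
            fat_g=80, carbohydrate_g=300, protein_g=75, alcohol_g=0, energy_kcal_d=2220
        )
        assert out["pct_energy_fat"] == pytest.approx(32.4, abs=0.05)
        assert out["pct_energy_carbohydrate"] == pytest.approx(54.1, abs=0.05)
        assert out["pct_energy_protein"] == pytest.approx(13.5, abs=0.05)
        assert out["pct_energy_alcohol"] == 0.0
        simple = macronutrient_percent_energy(fat_g=100, energy_kcal_d=2250)
        assert simple["pct_energy_fat"] == pytest.approx(40.0)

    def test_guards(self):
        with pytest.raises(ValueError):
            macronutrient_percent_energy(fat_g=10, energy_kcal_d=0)
        with pytest.raises(ValueError):
            macronutrient_percent_energy(fat_g=-1, energy_kcal_d=2000)


class TestCatalog:
    def test_default_composition(self, catalog):
        counts = catalog.rating_counts()
        assert len(catalog.entries) == 46
        assert counts == {"beneficial": 20, "adverse": 13, "neutral": 13}
        assert len(set(catalog.group_ids)) == 46

    def test_invariant_violations_rejected(self):
        entries = [FoodGroup(f"g{i}", f"G{i}", "beneficial") for i in range(45)]
        with pytest.raises(CatalogError, match="46"):
            FoodGroupCatalog(entries=entries)
        dup = [FoodGroup("a", "A", "beneficial"), FoodGroup("a", "B", "adverse")]
        with pytest.raises(CatalogError, match="duplicate"):
            FoodGroupCatalog(entries=dup, strict=False)
        with pytest.raises(CatalogError, match="rating"):
            FoodGroupCatalog(entries=[FoodGroup("a", "A", "great")], strict=False)
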