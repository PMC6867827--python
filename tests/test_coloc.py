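import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from transcoloc import (
    CriterionSpec,
    SpotAssociation,
    association_fractions,
    association_test,
    circle_intersection,
    expected_pair_count,
    expected_triple_count,
    match_pairs,
    match_triples,
    simulate_spot_field,
)


def lens_area_numeric(d, r):
    """Numerical-integration oracle for the two-disc intersection area."""
    if d >= 2 * r:
        return 0.0
    # twice the area between the chord at x = d/2 and the circle edge
    val, _ = quad(lambda x: 2.0 * np.sqrt(r**2 - x**2), d / 2.0, r,
                  epsabs=1e-12, epsrel=1e-12)
    return 2.0 * val


class TestCircleIntersection:
    def test_touching_discs_have_zero_overlap(self):
        assert circle_intersection(2.0, 1.0) == 0.0
        assert circle_intersection(5.0, 1.0) == 0.0  # disjoint

    def test_coincident_discs_full_area(self):
        assert circle_intersection(0.0, 1.5) == pytest.approx(np.pi * 1.5**2)

    def test_half_radius_closed_form(self):
        # d = r, r = 1: I = 2*pi/3 - sqrt(3)/2
        assert circle_intersection(1.0, 1.0) == pytest.approx(
            2 * np.pi / 3 - np.sqrt(3) / 2, abs=1e-12
        )

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            circle_intersection(-0.1, 1.0)

    def test_matches_numeric_integration_on_grid(self):
        for r in (0.5, 1.0, 200.0):
            for frac in np.linspace(0.0, 2.0, 9):
                d = frac * r
                assert circle_intersection(d, r) == pytest.approx(
                    lens_area_numeric(d, r), abs=1e-6 * r**2
                )


class TestExpectedCounts:
    def test_zero_population_zero_expectation(self):
        assert expected_pair_count(0, 50, 200.0, 100.0, 1e9) == 0.0
        assert expected_triple_count(0, 3.0, 200.0, 100.0, 1e9) == 0.0

    def test_touching_criterion_reduces_to_union_of_discs(self):
        # d = 2r makes I = 0, so E_m = N1 N2 2 pi r^2 / A
        e = expected_pair_count(10, 20, 150.0, 300.0, 5e8)
        assert e == pytest.approx(10 * 20 * 2 * np.pi * 150.0**2 / 5e8)

    def test_direct_evaluation_cross_checked(self):
        # independent re-implementation of the printed formulas
        n1 = n2 = 100
        r, d, area = 200.0, 212.6, 2e9
        lens = lens_area_numeric(d, r)
        assert expected_pair_count(n1, n2, r, d, area) == pytest.approx(
            n1 * n2 * (2 * np.pi * r**2 - lens) / area, rel=1e-9
        )
        e_m = expected_pair_count(n1, n2, r, d, area)
        assert expected_triple_count(50, e_m, r, d, area) == pytest.approx(
            50 * e_m * (np.pi * r**2 - lens) / area, rel=1e-9
        )

    def test_coincident_triple_factor_vanishes(self):
        # d = 0: (pi r^2 - I) = 0
        assert expected_triple_count(50, 3.0, 200.0, 0.0, 2e9) == 0.0

    def test_expected_pairs_strictly_increasing_in_distance(self):
        r = 180.0
        d = np.linspace(0.0, 2 * r, 60)
        e = expected_pair_count(40, 60, r, d, 1e9)
        assert np.all(np.diff(e) > 0)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            expected_pair_count(1, 1, 100.0, 50.0, 0.0)


def _table(points, cell=0):
    pts = np.asarray(points, dtype=float)
    return pd.DataFrame(
        {"cell_id": cell, "x_nm": pts[:, 0], "y_nm": pts[:, 1]}
    )


class TestMatching:
    def test_coincident_spots_pair_once(self):
        crit = CriterionSpec(2.0)
        pairs, counts = match_pairs(_table([(0, 0)]), _table([(0, 0)]), crit)
        assert len(pairs) == 1 and counts[0] == 1

    def test_greedy_nearest_one_to_one(self):
        # A at origin; B1 at 1.0 px, B2 at 1.5 px -> A pairs with B1 only
        crit = CriterionSpec(2.0)
        pairs, counts = match_pairs(
            _table([(0, 0)]),
            _table([(1.0 * 106.3, 0), (1.5 * 106.3, 0)]),
            crit,
        )
        assert counts[0] == 1
        assert pairs["distance_nm"].iloc[0] == pytest.approx(106.3)

    def test_symmetric_in_channel_order(self, geometry):
        spots, _ = simulate_spot_field(
            geometry, {"A": 80, "B": 60}, coloc_fraction=0.2, seed=41
        )
        a = spots[spots["channel"] == "A"]
        b = spots[spots["channel"] == "B"]
        crit = CriterionSpec(2.0)
        _, ab = match_pairs(a, b, crit)
        _, ba = match_pairs(b, a, crit)
        assert ab.sum() == ba.sum()

    def test_mixed_pixel_sizes_rejected(self):
        a, b = _table([(0, 0)]), _table([(0, 0)])
        a.attrs["pixel_size_nm"] = 106.3
        b.attrs["pixel_size_nm"] = 65.0
        with pytest.raises(ValueError):
            match_pairs(a, b, CriterionSpec(2.0))

    def test_greedy_equals_exhaustive_matching_count(self):
        # brute-force oracle: maximum-cardinality matching on the
        # within-criterion graph (networkx), instances <= 8 spots/channel
        import networkx as nx

        rng = np.random.default_rng(42)
        crit = CriterionSpec(2.0)
        for _ in range(50):
            na, nb = rng.integers(2, 9), rng.integers(2, 9)
            xa = rng.uniform(0, 20 * 106.3, (na, 2))
            xb = rng.uniform(0, 20 * 106.3, (nb, 2))
            pairs, _ = match_pairs(_table(xa), _table(xb), crit)
            g = nx.Graph()
            for i in range(na):
                for j in range(nb):
                    if np.hypot(*(xa[i] - xb[j])) <= crit.distance_nm:
                        g.add_edge(("a", i), ("b", j))
            opt = len(nx.max_weight_matching(g, maxcardinality=True))
            assert len(pairs) == opt


class TestTriples:
    def test_coincident_triple_found(self):
        crit = CriterionSpec(2.0)
        triples, counts = match_triples(
            _table([(0, 0)]), _table([(0, 0)]), _table([(0, 0)]), crit
        )
        assert len(triples) == 1 and counts[0] == 1

    def test_distant_protein_breaks_triple(self):
        crit = CriterionSpec(2.0)
        triples, _ = match_triples(
            _table([(0, 0)]), _table([(50.0, 0)]), _table([(3 * 106.3, 0)]), crit
        )
        assert len(triples) == 0

    def test_planted_triples_all_recovered(self, geometry):
        spots, truth = simulate_spot_field(
            geometry, {"A": 40, "B": 40, "P": 30}, coloc_fraction=0.5,
            protein_species="P", triple_fraction=1.0, seed=5,
        )
        a = spots[spots["channel"] == "A"]
        b = spots[spots["channel"] == "B"]
        p = spots[spots["channel"] == "P"]
        crit = CriterionSpec(2.0)
        triples, counts = match_triples(a, b, p, crit)
        assert counts.sum() >= len(truth.true_triples)
        found = set(zip(triples["spot_id_a"], triples["spot_id_b"]))
        planted = {(ta, tb) for ta, tb, _ in truth.true_triples}
        assert planted <= found


class TestAssociationStats:
    def test_identical_observed_expected_gives_null_result(self):
        t, p, p_adj = association_test([3, 4, 5, 6], [3, 4, 5, 6])
        assert t == 0.0 and p == 1.0 and p_adj == 1.0

    def test_constant_shift_is_certain(self):
        obs = np.arange(10) + 5.0
        t, p, _ = association_test(obs, np.arange(10).astype(float))
        assert np.isinf(t) and p == 0.0

    def test_minimum_cells_enforced(self):
        with pytest.raises(ValueError):
            association_test([1, 2], [1, 2])

    def test_bonferroni_capped_at_one(self):
        rng = np.random.default_rng(0)
        obs = rng.poisson(5, 20).astype(float)
        _, p, p_adj = association_test(obs, obs + rng.normal(0, 0.1, 20), 4)
        assert p_adj == min(1.0, p * 4)

    def test_fraction_arithmetic(self):
        assert association_fractions(25, 100, 100) == (25.0, 25.0)
        assert association_fractions(0, 50, 80) == (0.0, 0.0)
        with pytest.raises(ValueError):
            association_fractions(1, 0, 10)


class TestSpotAssociationModel:
    def test_planted_fraction_recovered(self, geometry):
        spots, _ = simulate_spot_field(
            geometry, {"A": 100, "B": 100}, coloc_fraction=0.25,
            n_cells=20, seed=43,
        )
        a = spots[spots["channel"] == "A"]
        b = spots[spots["channel"] == "B"]
        res = SpotAssociation(
            a, b, areas_nm2=geometry.cytoplasm_area_nm2, r_nm=125.0,
            criteria_px=[1],
        ).fit()
        assert res.tests["frac_a_pct"].iloc[0] == pytest.approx(25.0, abs=3.0)
        assert res.tests["frac_b_pct"].iloc[0] == pytest.approx(25.0, abs=3.0)
        assert res.tests["p_bonferroni"].iloc[0] < 0.05

    def test_verbatim_null_exceeds_classical(self, geometry):
        # the union-area chance model is more conservative than the
        # encounter-area null at sub-diameter criteria
        spots, _ = simulate_spot_field(
            geometry, {"A": 50, "B": 50}, n_cells=5, seed=47
        )
        a = spots[spots["channel"] == "A"]
        b = spots[spots["channel"] == "B"]
        kw = dict(areas_nm2=geometry.cytoplasm_area_nm2, r_nm=125.0,
                  criteria_px=[1])
        union = SpotAssociation(a, b, null="union", **kw).fit()
        classical = SpotAssociation(a, b, null="classical", **kw).fit()
        assert (
            union.tests["mean_expected"].iloc[0]
            > classical.tests["mean_expected"].iloc[0]
        )

    def test_triple_analysis_reports_translated_fractions(self, geometry):
        spots, _ = simulate_spot_field(
            geometry, {"A": 60, "B": 60, "P": 40}, coloc_fraction=0.4,
            protein_species="P", triple_fraction=0.8, n_cells=6, seed=51,
        )
        res = SpotAssociation(
            spots[spots["channel"] == "A"],
            spots[spots["channel"] == "B"],
            areas_nm2=geometry.cytoplasm_area_nm2,
            r_nm=125.0,
            protein=spots[spots["channel"] == "P"],
        ).fit()
        tr = res.triples
        assert tr is not None
        assert tr.per_cell["observed_triples"].sum() > 0
        assert 0.0 <= tr.frac_a_with_protein_pct <= 100.0
        assert tr.p_raw < 0.05  # planted triples beat chance
        assert "triples" in res.summary()

    def test_puromycin_contrast_removes_signal(self, geometry):
        # with planted triples removed the triple count falls to chance and
        # the test is no longer significant (ribosome-release control logic)
        kw = dict(coloc_fraction=0.0, protein_species="P", n_cells=12)
        spots, _ = simulate_spot_field(
            geometry, {"A": 60, "B": 60, "P": 40}, triple_fraction=0.0,
            seed=53, **kw,
        )
        res = SpotAssociation(
            spots[spots["channel"] == "A"],
            spots[spots["channel"] == "B"],
            areas_nm2=geometry.cytoplasm_area_nm2,
            r_nm=125.0,
            protein=spots[spots["channel"] == "P"],
            null="classical",
        ).fit()
        assert res.triples.p_raw > 0.05
        assert res.triples.per_cell["observed_triples"].mean() <= 1.0
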