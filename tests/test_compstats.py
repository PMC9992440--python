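"""Compositional transforms, aggregation, nested PERMANOVA and dispersion test."""

import datetime
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sargasso.compstats import (
    aggregate_date_then_month,
    dispersion_homogeneity,
    ilr_bivariate,
    ilr_inverse,
    permanova_nested,
    ternary_coords,
    to_relative_abundance,
)
from sargasso.permanova import pseudo_f_oneway, squared_euclidean
from sargasso.synthetic_data import MorphotypeSample


class TestRelativeAbundance:
    def test_january_anchor_volumes(self):
        # 8/67/25 mL -> 8%/67%/25%
        assert np.allclose(to_relative_abundance(np.array([8.0, 67.0, 25.0])), (0.08, 0.67, 0.25))

    def test_equal_volumes(self):
        assert np.allclose(to_relative_abundance(np.array([5.0, 5.0, 5.0])), 1 / 3)

    def test_single_part_sample(self):
        assert np.allclose(to_relative_abundance(np.array([0.0, 0.0, 10.0])), (0, 0, 1))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            to_relative_abundance(np.array([0.0, 0.0, 0.0]))


class TestAggregation:
    def make(self, date, vols, clump=0):
        return MorphotypeSample(date, clump, *vols)

    def test_single_sample_passthrough(self):
        s = [self.make(datetime.date(2021, 5, 3), (10, 20, 70))]
        out = aggregate_date_then_month(s)
        assert np.allclose(out.iloc[0], (0.1, 0.2, 0.7))

    def test_dates_weigh_equally_regardless_of_sample_count(self):
        d1, d2 = datetime.date(2021, 5, 3), datetime.date(2021, 5, 20)
        s = [self.make(d1, (100, 0, 0))]
        s += [self.make(d2, (0, 100, 0), c) for c in range(3)]
        out = aggregate_date_then_month(s)
        assert np.allclose(out.iloc[0], (0.5, 0.5, 0.0))

    def test_matches_hand_computed_toy_table(self):
        # three dates in one month, hand-averaged two-stage means
        d = [datetime.date(2021, 7, k) for k in (1, 10, 20)]
        s = [
            self.make(d[0], (10, 10, 80)),
            self.make(d[0], (30, 10, 60), 1),  # date 1 mean: (0.2, 0.1, 0.7)
            self.make(d[1], (50, 25, 25)),     # date 2: (0.5, 0.25, 0.25)
            self.make(d[2], (0, 50, 50)),      # date 3: (0.0, 0.5, 0.5)
        ]
        out = aggregate_date_then_month(s)
        expected = np.array([(0.2 + 0.5 + 0.0) / 3, (0.1 + 0.25 + 0.5) / 3, (0.7 + 0.25 + 0.5) / 3])
        assert np.allclose(out.iloc[0], expected, atol=1e-12)

    def test_months_kept_separate(self):
        s = [self.make(datetime.date(2021, 5, 3), (100, 0, 0)), self.make(datetime.date(2021, 6, 3), (0, 100, 0))]
        out = aggregate_date_then_month(s)
        assert len(out) == 2


class TestIlr:
    def test_neutral_composition_maps_to_origin(self):
        assert np.allclose(ilr_bivariate(np.array([1, 1, 1]) / 3), (0.0, 0.0), atol=1e-12)

    def test_worked_example(self):
        z = ilr_bivariate(np.array([0.5, 0.25, 0.25]))
        assert z[0] == pytest.approx(np.log(2) / np.sqrt(2), abs=1e-9)
        assert z[0] == pytest.approx(0.4901, abs=1e-4)
        assert z[1] == pytest.approx(np.sqrt(2 / 3) * np.log(np.sqrt(0.125) / 0.25), abs=1e-9)
        assert z[1] == pytest.approx(0.28298, abs=1e-5)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet((2, 3, 4), size=200)
        back = ilr_inverse(ilr_bivariate(p))
        assert np.allclose(back, p, atol=1e-9)

    def test_zero_replacement_keeps_coords_finite(self):
        z = ilr_bivariate(np.array([0.0, 0.3, 0.7]))
        assert np.all(np.isfinite(z))

    def test_isometry_preserves_distances(self):
        # the ilr is an isometry from the Aitchison simplex: permuting parts
        # via the basis convention changes coordinates but not distances
        rng = np.random.default_rng(1)
        p = rng.dirichlet((5, 5, 5), size=50)
        z = ilr_bivariate(p)
        zp = ilr_bivariate(p[:, [1, 0, 2]])
        d1 = squared_euclidean(z)
        d2 = squared_euclidean(zp)
        assert np.allclose(d1, d2, atol=1e-9)


class TestTernary:
    def test_vertices_form_unit_equilateral_triangle(self):
        v = ternary_coords(np.eye(3))
        assert np.allclose(v[0], (0, 0))
        assert np.allclose(v[1], (1, 0))
        assert np.allclose(v[2], (0.5, np.sqrt(3) / 2))
        for i, j in combinations(range(3), 2):
            assert np.hypot(*(v[i] - v[j])) == pytest.approx(1.0, abs=1e-12)

    def test_centroid(self):
        assert np.allclose(ternary_coords(np.full(3, 1 / 3)), (0.5, np.sqrt(3) / 6), atol=1e-12)


def simulate_nested(rng, n_dates=6, clumps=3, alpha_a=(3, 3, 3), alpha_b=(3, 3, 3)):
    """Clump-level ilr responses for n_dates/2 dates per group."""
    half = n_dates // 2
    rows, dates, groups = [], [], []
    for d in range(n_dates):
        grp = "A" if d < half else "B"
        alpha = alpha_a if grp == "A" else alpha_b
        for _ in range(clumps):
            rows.append(rng.dirichlet(alpha))
            dates.append(f"d{d}")
            groups.append(grp)
    return ilr_bivariate(np.array(rows)), np.array(dates), np.array(groups)


class TestPermanovaNested:
    def test_identical_rows_give_f_zero_p_one(self):
        z = np.tile([0.3, -0.2], (12, 1))
        dates = np.repeat([f"d{i}" for i in range(4)], 3)
        groups = np.repeat(["A", "A", "B", "B"], 3)
        res = permanova_nested(z, groups, dates, n_perm=99, seed=0)
        assert res.pseudo_f == 0.0
        assert res.p_value == 1.0

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        # 6 dates, 3 per group: 20 distinct assignments
        rng = np.random.default_rng(7)
        z, dates, groups = simulate_nested(rng, n_dates=6, alpha_a=(6, 2, 2), alpha_b=(2, 6, 2))
        exact = permanova_nested(z, groups, dates, exhaustive=True)
        assert exact.n_perm == 20
        n_mc = 100_000
        mc = permanova_nested(z, groups, dates, n_perm=n_mc, seed=11)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / n_mc)
        assert abs(mc.p_value - exact.p_value) < 3 * se + 2 / n_mc

    def test_exhaustive_p_agrees_with_brute_force_oracle(self):
        # independent oracle: enumerate assignments and recompute F from raw
        # group sums of squares on the coordinates
        rng = np.random.default_rng(3)
        z, dates, groups = simulate_nested(rng, n_dates=6, alpha_a=(8, 2, 2), alpha_b=(2, 8, 2))
        res = permanova_nested(z, groups, dates, exhaustive=True)

        def f_of(labels):
            grand = z.mean(axis=0)
            ssb = sum(
                (labels == g).sum() * ((z[labels == g].mean(axis=0) - grand) ** 2).sum()
                for g in ("A", "B")
            )
            ssw = sum(((z[labels == g] - z[labels == g].mean(axis=0)) ** 2).sum() for g in ("A", "B"))
            return (ssb / 1) / (ssw / (len(z) - 2))

        f_obs = f_of(groups)
        assert res.pseudo_f == pytest.approx(f_obs, rel=1e-9)
        uniq = [f"d{i}" for i in range(6)]
        count = 0
        total = 0
        for comb in combinations(range(6), 3):
            labels = np.array(["A" if d in {f"d{i}" for i in comb} else "B" for d in dates])
            total += 1
            if f_of(labels) >= f_obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_free_scheme_matches_skbio_permanova(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        z, dates, groups = simulate_nested(rng, n_dates=8, alpha_a=(5, 2, 3), alpha_b=(2, 5, 3))
        res = permanova_nested(z, groups, dates, scheme="free", n_perm=999, seed=0)
        dm = skbio_stats.DistanceMatrix(np.sqrt(squared_euclidean(z)))
        ref = skbio_stats.permanova(dm, grouping=list(groups), permutations=999)
        assert res.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)
        assert abs(res.p_value - ref["p-value"]) < 0.05  # same F, independent permutation streams

    def test_insufficient_replication_rejected(self):
        z = np.zeros((6, 2))
        dates = np.array(["d0", "d0", "d0", "d1", "d1", "d1"])
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        with pytest.raises(ValueError):
            permanova_nested(z, groups, dates, n_perm=9)

    def test_rotation_invariance_of_f(self):
        rng = np.random.default_rng(13)
        z, dates, groups = simulate_nested(rng, n_dates=8, alpha_a=(6, 2, 2), alpha_b=(2, 6, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        r1 = permanova_nested(z, groups, dates, n_perm=99, seed=1)
        r2 = permanova_nested(z @ rot.T, groups, dates, n_perm=99, seed=1)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f, rel=1e-9)
        assert r1.p_value == r2.p_value


class TestDispersionHomogeneity:
    def test_translated_groups_have_equal_dispersion(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(15, 2))
        shifted = base + np.array([5.0, -3.0])
        resp = np.vstack([base, shifted])
        groups = np.array(["A"] * 15 + ["B"] * 15)
        res = dispersion_homogeneity(resp, groups, n_perm=199, seed=0)
        assert res.group_mean_distance["A"] == pytest.approx(res.group_mean_distance["B"], rel=1e-9)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-18)
        assert res.p_value > 0.9

    def test_scaled_group_detected(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(20, 2))
        resp = np.vstack([base, 5.0 * rng.normal(size=(20, 2))])
        groups = np.array(["A"] * 20 + ["B"] * 20)
        res = dispersion_homogeneity(resp, groups, n_perm=499, seed=0)
        assert res.f_statistic > 10
        assert res.p_value < 0.05

    def test_euclidean_distances_match_direct_centroid_computation(self):
        rng = np.random.default_rng(6)
        resp = rng.normal(size=(12, 2))
        groups = np.repeat(["A", "B"], 6)
        res = dispersion_homogeneity(resp, groups, n_perm=99, seed=0)
        for g in ("A", "B"):
            pts = resp[groups == g]
            direct = np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean()
            assert res.group_mean_distance[g] == pytest.approx(direct, rel=1e-9)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            dispersion_homogeneity(np.zeros((3, 2)), np.array(["A", "B", "B"]), n_perm=9)
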