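"""Direction classification, directional summaries and index regressions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from reefdrift.connectivity import ConnectivityMatrix
from reefdrift.enso import (
    classify_direction,
    default_excluded_regions,
    direction_class_matrix,
    directional_summary,
    fit_mean_vs_cv_decay,
    regress_on_index,
    yearly_mean_index,
)
from reefdrift.ocean import DomainConfig, Region, generate_domain, load_or_generate_index


def reg(rid, band, rank, sector="central"):
    return Region(region_id=rid, name=f"r{rid}", sector=sector, band=band,
                  latitude_rank=rank, reef_ids=(rid,))


class TestYearlyIndex:
    def test_observed_endpoints(self):
        idx = load_or_generate_index("bom")
        assert yearly_mean_index(idx, 2010) == pytest.approx(20.425)
        assert round(yearly_mean_index(idx, 2010)) == 20
        assert yearly_mean_index(idx, 2015) == pytest.approx(-13.575)
        assert round(yearly_mean_index(idx, 2015)) == -14

    def test_constant_months(self):
        import pandas as pd
        from reefdrift.ocean import ClimateIndexSeries
        tbl = pd.DataFrame({"year": [2000], "october": [3.0], "november": [3.0],
                            "december": [3.0], "january_next": [3.0]})
        assert ClimateIndexSeries(tbl).yearly_mean(2000) == 3.0


class TestDirectionClassification:
    def test_retention(self):
        a = reg(1, "inshore", 1)
        assert classify_direction(a, a) == "retention"

    def test_across_shelf_is_offshore_to_inshore(self):
        assert classify_direction(reg(1, "offshore", 2), reg(2, "inshore", 5)) == "across_shelf"
        assert classify_direction(reg(1, "offshore", 5), reg(2, "inshore", 2)) == "across_shelf"
        assert classify_direction(reg(1, "inshore", 2), reg(2, "offshore", 5)) == "inshore_to_offshore"

    def test_alongshelf_by_latitude_rank(self):
        # higher rank = further south; southward transport is poleward
        assert classify_direction(reg(1, "inshore", 3), reg(2, "inshore", 5)) == "poleward"
        assert classify_direction(reg(1, "inshore", 5), reg(2, "inshore", 3)) == "equatorward"
        assert classify_direction(reg(1, "offshore", 2), reg(2, "offshore", 4)) == "poleward"

    def test_antisymmetry_along_shelf(self, default_domain):
        regions = default_domain.regions_by_rank()
        for a in regions:
            for b in regions:
                if a.region_id != b.region_id and a.band == b.band:
                    fwd = classify_direction(a, b)
                    rev = classify_direction(b, a)
                    assert {fwd, rev} == {"poleward", "equatorward"}


@pytest.fixture(scope="module")
def four_region_domain():
    cfg = DomainConfig(n_sectors=1, rows_per_sector=2, n_regions=4, n_reefs_total=4)
    dom = generate_domain(cfg, seed=1)
    # single northern sector: include it as a source for the toy summaries
    return dom


class TestDirectionalSummary:
    def summary(self, dom, values, **kw):
        mat = ConnectivityMatrix(
            year=2010, values=np.asarray(values, float),
            region_ids=[r.region_id for r in dom.regions_by_rank()],
        )
        kw.setdefault("source_sectors", ("northern",))
        kw.setdefault("excluded_regions", set())
        return directional_summary(mat, dom, **kw)

    def test_means_match_hand_enumeration(self, four_region_domain):
        dom = four_region_domain
        rng = np.random.default_rng(2)
        C = rng.uniform(0, 0.1, (4, 4))
        s = self.summary(dom, C)
        classes = direction_class_matrix(dom)
        regions = dom.regions_by_rank()
        # brute-force oracle: loop over ordered pairs
        for name, got in [("poleward", s.mean_poleward),
                          ("equatorward", s.mean_equatorward),
                          ("across_shelf", s.mean_across_shelf)]:
            vals = [
                C[i, j]
                for i in range(4)
                for j in range(4)
                if classify_direction(regions[i], regions[j]) == name
            ]
            assert got == pytest.approx(np.mean(vals))
        assert classes.shape == (4, 4)

    def test_only_poleward_cells_gives_full_share(self, four_region_domain):
        dom = four_region_domain
        classes = direction_class_matrix(dom)
        C = np.zeros((4, 4))
        C[classes == 1] = 0.05  # poleward class index
        s = self.summary(dom, C)
        assert s.poleward_fraction_pct == 100.0
        assert s.equatorward_fraction_pct == 0.0

    def test_all_zero_matrix_masks_fractions(self, four_region_domain):
        s = self.summary(four_region_domain, np.zeros((4, 4)))
        assert s.mean_poleward == 0.0 and s.mean_equatorward == 0.0
        assert np.isnan(s.poleward_fraction_pct)

    def test_shares_sum_to_hundred(self, four_region_domain):
        rng = np.random.default_rng(4)
        s = self.summary(four_region_domain, rng.uniform(0, 1, (4, 4)))
        assert s.poleward_fraction_pct + s.equatorward_fraction_pct == pytest.approx(100.0)

    def test_default_exclusions_are_southernmost(self, default_domain):
        excl = default_excluded_regions(default_domain, 2)
        ranks = {r.latitude_rank for r in default_domain.regions if r.region_id in excl}
        assert ranks == {28, 29}

    def test_unknown_exclusion_rejected(self, four_region_domain):
        with pytest.raises(KeyError):
            self.summary(four_region_domain, np.zeros((4, 4)), excluded_regions={99})


class TestRegression:
    def test_exact_linear_relation(self):
        x = np.array([-14.0, -8, -0.2, 5, 7, 13, 20, 21])
        y = 3.0 - 0.5 * x
        r = regress_on_index(y, x, form="linear")
        assert r.r2 == pytest.approx(1.0)
        assert r.coefficients[1] == pytest.approx(-0.5)
        assert r.p_value < 1e-10

    def test_constant_response(self):
        x = np.arange(8.0)
        r = regress_on_index(np.full(8, 2.0), x)
        assert r.r2 == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(-20, 20, 8)
        y = rng.uniform(0, 1, 8)
        for form, order in (("linear", 1), ("quadratic", 2)):
            r = regress_on_index(y, x, form=form)
            X = np.vander(x, order + 1, increasing=True)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose(r.coefficients, beta, rtol=1e-8)
            resid = y - X @ beta
            r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
            assert r.r2 == pytest.approx(r2)

    def test_r2_invariant_to_affine_index_rescaling(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(-20, 20, 8)
        y = rng.uniform(0, 1, 8)
        r1 = regress_on_index(y, x)
        r2_ = regress_on_index(y, 3.0 * x - 7.0)
        assert r1.r2 == pytest.approx(r2_.r2)
        assert r1.p_value == pytest.approx(r2_.p_value)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            regress_on_index([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            regress_on_index([1.0, 2.0], [0.0, 1.0], form="linear")


class TestDecayFit:
    def test_exact_model_recovered(self):
        cv = np.linspace(0.3, 2.8, 20)
        mean = 2.0 * np.exp(-cv)
        r = fit_mean_vs_cv_decay(mean, cv)
        assert r.coefficients[0] == pytest.approx(2.0, rel=1e-6)
        assert r.coefficients[1] == pytest.approx(1.0, rel=1e-6)
        assert r.r2 == pytest.approx(1.0)

    def test_constant_means_give_zero_decay(self):
        cv = np.linspace(0.5, 2.0, 10)
        r = fit_mean_vs_cv_decay(np.full(10, 0.3), cv)
        assert r.coefficients[1] == pytest.approx(0.0, abs=1e-8)

    def test_beats_grid_search_oracle(self):
        rng = np.random.default_rng(13)
        cv = rng.uniform(0.3, 2.8, 40)
        mean = 0.8 * np.exp(-1.4 * cv) * np.exp(rng.normal(0, 0.1, 40))
        r = fit_mean_vs_cv_decay(mean, cv)

        def sse(a, b):
            return float(((mean - a * np.exp(-b * cv)) ** 2).sum())

        best = min(
            (sse(a, b), a, b)
            for a in np.linspace(0.4, 1.2, 60)
            for b in np.linspace(0.7, 2.1, 60)
        )
        assert sse(*r.coefficients) <= best[0] + 1e-12
        assert abs(r.coefficients[0] - best[1]) < 0.05
        assert abs(r.coefficients[1] - best[2]) < 0.05

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_mean_vs_cv_decay([0.1, 0.2], [1.0, 2.0])
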