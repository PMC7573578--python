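"""Genomic-offset computation, multi-model maps and the yield validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import climoffset as co
from climoffset import vulnerability as vu
from climoffset.climate import ClimateMetricTable

from conftest import step_model


def one_predictor_table(values, lat=None, lon=None):
    frame = pd.DataFrame({"x": np.asarray(values, float)})
    frame.insert(0, "lat", lat if lat is not None else np.zeros(len(frame)))
    frame.insert(1, "lon", lon if lon is not None else np.arange(len(frame), dtype=float))
    return ClimateMetricTable(frame)


class TestOffset:
    def test_identity_offset_zero(self, tiny_model):
        x = tiny_model.training_max
        assert vu.offset(tiny_model, x, x) == 0.0

    def test_three_four_five_triangle(self):
        # transforms (0.1, 0.2) -> (0.4, 0.6): Euclidean distance 0.5
        m = step_model(["a", "b"],
                       edges=[[0, 1, 2], [0, 1, 2]],
                       cums=[[0.1, 0.4], [0.2, 0.6]])
        x_cur = pd.Series({"a": 1.0, "b": 1.0})
        x_fut = pd.Series({"a": 2.0, "b": 2.0})
        np.testing.assert_allclose(m.transform(x_cur), [0.1, 0.2])
        np.testing.assert_allclose(m.transform(x_fut), [0.4, 0.6])
        assert vu.offset(m, x_cur, x_fut) == pytest.approx(0.5)

    def test_offset_is_a_metric(self, tiny_model):
        rng = np.random.default_rng(1)
        lo = tiny_model.training_min.to_numpy()
        hi = tiny_model.training_max.to_numpy()
        a = pd.Series(lo + rng.random(lo.size) * (hi - lo), index=tiny_model.predictors)
        b = pd.Series(lo + rng.random(lo.size) * (hi - lo), index=tiny_model.predictors)
        assert vu.offset(tiny_model, a, b) >= 0
        assert vu.offset(tiny_model, a, b) == pytest.approx(vu.offset(tiny_model, b, a))

    def test_offset_nondecreasing_in_onset_shift(self):
        # larger monsoon delays must not reduce the median pixel offset
        medians = []
        for shift in (0, 10, 20):
            sc = co.SyntheticScenario(lat_range=(10.0, 12.0), lon_range=(-3.0, 0.0),
                                      n_landraces=40, n_adaptive_snps=6,
                                      n_neutral_snps=20, onset_shift_days=shift,
                                      precip_scale=1.0, warming_c=0.0, seed=4)
            cur, fut = co.generate_climate(sc)
            cm_ = co.compute_metrics(cur)
            fm_ = co.compute_metrics(fut)
            common = cm_.frame.index.intersection(fm_.frame.index)
            cm_ = ClimateMetricTable(cm_.frame.loc[common])
            fm_ = ClimateMetricTable(fm_.frame.loc[common])
            lr = co.generate_landraces(sc, cur)
            lrm = cm_.at_sites(lr["lat"], lr["lon"], ids=lr.index)
            freqs, _ = co.generate_allele_freqs(sc, lr, lrm)
            kept = co.filter_maf(freqs, 0.10)
            preds = co.select_uncorrelated(lrm, 0.7)
            model = co.fit(kept, lrm.subset_metrics(preds), n_trees=50, seed=4)
            off = vu.offset_profile(model, cm_.subset_metrics(preds),
                                    fm_.subset_metrics(preds))
            medians.append(np.median(off))
        assert medians[0] <= medians[1] + 1e-9
        assert medians[1] <= medians[2] + 1e-9


class TestMapOffsets:
    def make_ensemble(self, offsets):
        """Per-model tuples engineered so the single pixel's offset is exact."""
        per_model = {}
        for i, v in enumerate(offsets):
            m = step_model(["x"], edges=[[0, 1, 2]], cums=[[0.0, v]])
            cur = one_predictor_table([1.0, 0.0], lat=[5.0, 5.0], lon=[0.0, 1.0])
            fut = one_predictor_table([2.0, 0.0], lat=[5.0, 5.0], lon=[0.0, 1.0])
            per_model[f"m{i}"] = (m, cur, fut)
        return per_model

    def test_identical_models_all_stippled(self):
        vmap = vu.map_offsets(self.make_ensemble([3.0, 3.0, 3.0]))
        row = vmap.iloc[0]
        assert row["sd"] == 0.0 and row["cv"] == 0.0 and bool(row["stipple"])

    def test_hand_computed_moments(self):
        vmap = vu.map_offsets(self.make_ensemble([2.0, 4.0, 6.0]))
        row = vmap.iloc[0]
        assert row["mean"] == pytest.approx(4.0)
        assert row["sd"] == pytest.approx(1.6329931618, abs=1e-6)  # population SD
        assert row["cv"] == pytest.approx(0.4082482904, abs=1e-6)
        assert bool(row["stipple"])  # mean > 2 SD

    def test_mean_invariant_to_model_ordering(self):
        a = vu.map_offsets(self.make_ensemble([2.0, 4.0, 6.0]))
        ens = self.make_ensemble([2.0, 4.0, 6.0])
        b = vu.map_offsets(dict(reversed(list(ens.items()))))
        np.testing.assert_allclose(a["mean"], b["mean"])
        np.testing.assert_allclose(a["cv"], b["cv"])

    def test_hull_excludes_exterior_pixel(self):
        m = step_model(["x"], edges=[[0, 1, 2]], cums=[[0.0, 1.0]])
        cur = one_predictor_table([1.0, 1.0, 1.0], lat=[0.0, 1.0, 10.0],
                                  lon=[0.0, 1.0, 10.0])
        fut = one_predictor_table([2.0, 2.0, 2.0], lat=[0.0, 1.0, 10.0],
                                  lon=[0.0, 1.0, 10.0])
        hull = vu.cultivation_hull([0.0, 0.0, 2.0, 2.0], [0.0, 2.0, 0.0, 2.0])
        vmap = vu.map_offsets({"m": (m, cur, fut)}, hull=hull)
        assert len(vmap) == 2
        assert vmap["lat"].max() <= 2.0

    def test_requires_a_model(self):
        with pytest.raises(ValueError):
            vu.map_offsets({})


class TestLandraceVulnerability:
    def test_landrace_at_site_pixel_has_zero_vulnerability(self, tiny_model, tiny_world):
        lrm = tiny_world["lr_metrics"]
        preds = tiny_model.predictors
        origins = ClimateMetricTable(lrm.frame[["lat", "lon"] + preds].iloc[:5])
        site = origins.frame.iloc[2]
        v = vu.landrace_site_vulnerability(tiny_model, origins, site)
        assert v.iloc[2] == pytest.approx(0.0, abs=1e-12)
        assert (v >= 0).all()

    def test_rank_correlates_with_mismatch_ground_truth(self, tiny_model, tiny_world):
        w = tiny_world
        preds = tiny_model.predictors
        lrm = ClimateMetricTable(w["lr_metrics"].frame[["lat", "lon"] + preds])
        garden = w["truth"].common_garden
        site = w["cur_metrics"].at_sites([garden[0]], [garden[1]]).frame.iloc[0]
        v = vu.landrace_site_vulnerability(tiny_model, lrm, site[["lat", "lon"] + preds])
        rho = stats.spearmanr(v, w["truth"].climate_mismatch.loc[v.index]).statistic
        assert rho > 0.8


class TestCorrelateYield:
    def test_perfect_anticorrelation(self):
        v = pd.Series([0.1, 0.4, 0.2, 0.9], index=list("abcd"))
        traits = pd.DataFrame({"t": -v})
        out = vu.correlate_yield(v, traits)
        assert out.loc["t", "r"] == pytest.approx(-1.0)

    def test_zero_variance_trait_error(self):
        v = pd.Series([0.1, 0.4, 0.2], index=list("abc"))
        with pytest.raises(ValueError, match="zero variance"):
            vu.correlate_yield(v, pd.DataFrame({"t": [1.0, 1.0, 1.0]}, index=list("abc")))

    def test_missing_pairs_dropped_and_counted(self):
        v = pd.Series([0.1, 0.4, 0.2, 0.9], index=list("abcd"))
        traits = pd.DataFrame({"t": [1.0, 2.0, np.nan, 0.5]}, index=list("abcd"))
        out = vu.correlate_yield(v, traits)
        assert out.loc["t", "n"] == 3

    def test_null_correlation_small(self):
        # independent trait: |r| < 0.25 in at least 95 of 100 replicates at n=100
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            v = pd.Series(rng.random(100))
            t = pd.DataFrame({"t": rng.normal(size=100)})
            out = vu.correlate_yield(v, t)
            hits += abs(out.loc["t", "r"]) < 0.25
        assert hits >= 95
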