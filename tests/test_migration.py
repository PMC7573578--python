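"""Vulnerable-pixel clustering, donor search and migration summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from climoffset import migration as mg
from climoffset.climate import ClimateMetricTable

from conftest import step_model


def brute_force_dbscan(D, eps, min_pts):
    """O(n^2) neighbourhood-expansion DBSCAN (neighbourhood includes self)."""
    n = D.shape[0]
    labels = np.full(n, -2)  # -2 unvisited, -1 noise
    cid = -1
    neighbors = [set(np.flatnonzero(D[i] <= eps)) for i in range(n)]
    core = [len(neighbors[i]) >= min_pts for i in range(n)]
    for i in range(n):
        if labels[i] != -2:
            continue
        if not core[i]:
            labels[i] = -1
            continue
        cid += 1
        labels[i] = cid
        frontier = list(neighbors[i])
        while frontier:
            j = frontier.pop()
            if labels[j] == -1:
                labels[j] = cid
            if labels[j] != -2:
                continue
            labels[j] = cid
            if core[j]:
                frontier.extend(neighbors[j])
    labels[labels == -2] = -1
    return labels


def vmap_from(lat, lon, offsets):
    return pd.DataFrame({"lat": lat, "lon": lon, "off": offsets})


class TestGeodesic:
    def test_identical_points(self):
        assert mg.geodesic_km((12.0, -3.0), (12.0, -3.0)) == 0.0

    def test_one_degree_at_equator(self):
        # spherical law of cosines: R * acos(cos(1 deg)) = 111.195 km
        expected = mg.EARTH_RADIUS_KM * math.acos(math.cos(math.radians(1.0)))
        assert mg.geodesic_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(expected, abs=0.01)
        assert abs(mg.geodesic_km((0.0, 0.0), (0.0, 1.0)) - 111.195) < 0.01

    def test_invalid_latitude_rejected(self):
        with pytest.raises(ValueError, match="latitude"):
            mg.geodesic_km((95.0, 0.0), (0.0, 0.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        lat1=st.floats(-90, 90), lon1=st.floats(-180, 180),
        lat2=st.floats(-90, 90), lon2=st.floats(-180, 180),
    )
    def test_symmetry(self, lat1, lon1, lat2, lon2):
        d1 = mg.geodesic_km((lat1, lon1), (lat2, lon2))
        d2 = mg.geodesic_km((lat2, lon2), (lat1, lon1))
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(0)
        lat = rng.uniform(-60, 60, 8)
        lon = rng.uniform(-180, 180, 8)
        D = mg.geodesic_matrix(lat, lon)
        for i in range(8):
            for j in range(8):
                assert D[i, j] == pytest.approx(
                    mg.geodesic_km((lat[i], lon[i]), (lat[j], lon[j])), abs=1e-6)


class TestClusters:
    def test_single_blob_is_one_cluster(self):
        lat = np.concatenate([np.full(6, 10.0) + np.arange(6) * 0.1, np.linspace(0, 5, 6)])
        lon = np.concatenate([np.full(6, 0.0), np.linspace(20, 40, 6)])
        off = np.concatenate([np.full(6, 9.0), np.zeros(6)])
        clusters = mg.vulnerable_clusters(vmap_from(lat, lon, off), "off",
                                          q=0.5, eps_km=200.0)
        assert len(clusters) == 1
        assert set(clusters[0]) == set(range(6))

    def test_isolated_pixels_are_noise(self):
        lat = np.array([0.0, 30.0, -30.0] + [5.0] * 7)
        lon = np.array([0.0, 60.0, -60.0] + list(np.linspace(100, 160, 7)))
        off = np.array([9.0, 9.0, 9.0] + [0.0] * 7)
        clusters = mg.vulnerable_clusters(vmap_from(lat, lon, off), "off",
                                          q=0.7, eps_km=200.0)
        assert clusters == []

    def test_invalid_eps_rejected(self):
        v = vmap_from(np.zeros(12), np.arange(12.0), np.arange(12.0))
        with pytest.raises(ValueError):
            mg.vulnerable_clusters(v, "off", eps_km=0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_dbscan(self, seed):
        rng = np.random.default_rng(seed)
        lat = rng.uniform(8, 16, 25)
        lon = rng.uniform(-10, 5, 25)
        v = vmap_from(lat, lon, np.full(25, 1.0))
        eps, min_pts = 250.0, 3
        clusters = mg.vulnerable_clusters(v, "off", q=0.0, min_pts=min_pts,
                                          eps_km=eps, merge_km=0.0)
        D = mg.geodesic_matrix(lat, lon)
        ref = brute_force_dbscan(D, eps, min_pts)
        ref_clusters = {frozenset(np.flatnonzero(ref == k))
                        for k in set(ref) if k != -1}
        ref_clusters = {c for c in ref_clusters if len(c) >= min_pts}
        assert {frozenset(c) for c in clusters} == ref_clusters

    def test_labels_invariant_under_pixel_permutation(self):
        rng = np.random.default_rng(9)
        lat = rng.uniform(8, 16, 20)
        lon = rng.uniform(-10, 5, 20)
        off = rng.random(20)
        v = vmap_from(lat, lon, off)
        c1 = {frozenset((lat[i], lon[i]) for i in c)
              for c in mg.vulnerable_clusters(v, "off", q=0.0, eps_km=300.0, merge_km=0.0)}
        perm = rng.permutation(20)
        v2 = vmap_from(lat[perm], lon[perm], off[perm])
        c2 = {frozenset((v2["lat"][i], v2["lon"][i]) for i in c)
              for c in mg.vulnerable_clusters(v2, "off", q=0.0, eps_km=300.0, merge_km=0.0)}
        assert c1 == c2

    def test_close_clusters_merge(self):
        # two tight blobs 500 km apart merge under merge_km=1200, stay split at 100
        lat = np.concatenate([np.full(4, 10.0) + np.arange(4) * 0.05,
                              np.full(4, 14.5) + np.arange(4) * 0.05,
                              np.zeros(4)])
        lon = np.concatenate([np.zeros(4), np.zeros(4), np.linspace(50, 80, 4)])
        off = np.concatenate([np.full(8, 5.0), np.zeros(4)])
        v = vmap_from(lat, lon, off)
        merged = mg.vulnerable_clusters(v, "off", q=0.6, eps_km=100.0, merge_km=1200.0)
        split = mg.vulnerable_clusters(v, "off", q=0.6, eps_km=100.0, merge_km=100.0)
        assert len(merged) == 1 and len(split) == 2


class TestFocalPixel:
    def test_argmax(self):
        v = vmap_from([0.0, 1.0, 2.0], [0.0, 0.0, 0.0], [0.1, 0.5, 0.3])
        assert mg.focal_pixel(np.array([0, 1, 2]), v, "off") == 1

    def test_tie_breaks_lexicographically(self):
        v = vmap_from([2.0, 1.0, 1.0], [0.0, 5.0, -5.0], [0.7, 0.7, 0.7])
        assert mg.focal_pixel(np.array([0, 1, 2]), v, "off") == 2  # (1, -5) smallest

    def test_singleton(self):
        v = vmap_from([0.0], [0.0], [0.4])
        assert mg.focal_pixel(np.array([0]), v, "off") == 0


def toy_candidates(n=30, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({
        "lat": rng.uniform(8, 16, n),
        "lon": rng.uniform(-10, 5, n),
        "x": rng.uniform(0, 10, n),
    })
    return ClimateMetricTable(frame)


class TestDonorSearch:
    model = None

    @classmethod
    def setup_class(cls):
        # identity-like turnover on x over [0, 10]: fine steps so ED tracks |dx|
        edges = np.linspace(0, 10, 201)
        cls.model = step_model(["x"], edges=[edges], cums=[np.linspace(0.05, 10, 200)])

    def test_self_donor_identity(self):
        cand = toy_candidates()
        focal = cand.frame.iloc[4]
        row = mg.donor_search(self.model, focal, cand, "optimal",
                              (focal["lat"], focal["lon"]))
        assert row["donor_index"] == 4
        assert row["distance_km"] == 0.0
        assert row["load"] == pytest.approx(0.0)

    @pytest.mark.parametrize("strategy", ["optimal", "near_optimal", "sub_optimal"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle(self, strategy, seed):
        cand = toy_candidates(seed=seed)
        focal = pd.Series({"lat": 12.0, "lon": -2.0, "x": 7.3})
        row = mg.donor_search(self.model, focal, cand, strategy, (12.0, -2.0))

        # oracle: compute every ED and distance, apply the rules by hand
        t_f = self.model.transform(focal)
        eds = np.array([np.linalg.norm(self.model.transform(r) - t_f)
                        for _, r in cand.frame.iterrows()])
        dists = np.array([mg.geodesic_km((12.0, -2.0), (r["lat"], r["lon"]))
                          for _, r in cand.frame.iterrows()])
        if strategy == "optimal":
            best = np.flatnonzero(eds == eds.min())
            expect = min(best, key=lambda i: (dists[i], cand.frame["lat"].iloc[i],
                                              cand.frame["lon"].iloc[i]))
        else:
            q = 0.01 if strategy == "near_optimal" else 0.05
            k = max(1, math.ceil(len(cand) * q))
            pool = np.argsort(eds, kind="stable")[:k]
            expect = min(pool, key=lambda i: (dists[i], cand.frame["lat"].iloc[i],
                                              cand.frame["lon"].iloc[i]))
        assert row["donor_index"] == expect
        assert row["load"] == pytest.approx(eds[expect])

    def test_candidate_pool_orderings(self):
        # sub-optimal pools contain near-optimal pools contain the optimum
        cand = toy_candidates(n=40, seed=7)
        focal = pd.Series({"lat": 10.0, "lon": 0.0, "x": 3.0})
        rows = {s: mg.donor_search(self.model, focal, cand, s, (10.0, 0.0))
                for s in mg.STRATEGIES}
        assert rows["sub_optimal"]["distance_km"] <= rows["near_optimal"]["distance_km"] + 1e-9
        assert rows["near_optimal"]["distance_km"] <= rows["optimal"]["distance_km"] + 1e-9
        assert rows["optimal"]["load"] <= rows["near_optimal"]["load"] + 1e-12
        assert rows["optimal"]["load"] <= rows["sub_optimal"]["load"] + 1e-12

    def test_optimal_donor_dominates_all_candidates(self):
        cand = toy_candidates(n=25, seed=3)
        focal = pd.Series({"lat": 14.0, "lon": 2.0, "x": 9.0})
        row = mg.donor_search(self.model, focal, cand, "optimal", (14.0, 2.0))
        t_f = self.model.transform(focal)
        eds = np.linalg.norm(self.model.transform(cand.frame) - t_f, axis=1)
        assert row["load"] <= eds.min() + 1e-12

    def test_too_few_candidates_error(self):
        cand = ClimateMetricTable(pd.DataFrame({"lat": [0.0], "lon": [0.0], "x": [1.0]}))
        with pytest.raises(ValueError):
            mg.donor_search(self.model, cand.frame.iloc[0], cand, "optimal", (0.0, 0.0))


class TestSummarize:
    def test_single_plan(self):
        plans = pd.DataFrame([{"strategy": "optimal", "distance_km": 100.0,
                               "load": 0.2, "transboundary": True}])
        s = mg.summarize(plans)
        assert s["optimal"]["distance_km"]["mean"] == 100.0
        assert s["optimal"]["distance_km"]["sd"] == 0.0
        assert s["optimal"]["transboundary_pct"] == 100.0

    def test_hand_built_table(self):
        plans = pd.DataFrame([
            {"strategy": "optimal", "distance_km": 100.0, "load": 0.1, "transboundary": True},
            {"strategy": "optimal", "distance_km": 300.0, "load": 0.3, "transboundary": False},
            {"strategy": "sub_optimal", "distance_km": 50.0, "load": 0.2, "transboundary": False},
            {"strategy": "sub_optimal", "distance_km": 150.0, "load": 0.4, "transboundary": False},
        ])
        s = mg.summarize(plans)
        assert s["optimal"]["n_areas"] == 2
        assert s["optimal"]["distance_km"]["mean"] == 200.0
        assert s["optimal"]["distance_km"]["sd"] == 100.0
        assert s["optimal"]["transboundary_pct"] == 50.0
        assert s["sub_optimal"]["load"]["mean"] == pytest.approx(0.3)
        assert s["sub_optimal"]["transboundary_pct"] == 0.0

    def test_empty_plans_error(self):
        with pytest.raises(ValueError):
            mg.summarize(pd.DataFrame())
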