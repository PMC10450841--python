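import math

import numpy as np
import pytest

from enmshift.geodata import GridHeader, Raster
from enmshift.rangeshift import (
    EARTH_RADIUS_KM,
    BinaryMap,
    Centroid,
    area_km2,
    binarize,
    cell_areas_km2,
    centroid,
    centroid_shift,
    change_map,
    threshold_stats,
)


@pytest.fixture
def header():
    return GridHeader(10, 8, xll=100.0, yll=30.0, cellsize=0.25)


def random_binary(header, rng, p=0.4):
    states = (rng.uniform(size=(header.nrows, header.ncols)) < p).astype(np.int8)
    return BinaryMap(header, states, np.ones_like(states, dtype=bool))


class TestThresholdStats:
    def test_constant_suitability_sigma_zero(self, header):
        r = Raster(header, np.full((8, 10), 0.6))
        ts = threshold_stats(r, [(0, 0), (1, 1), (2, 2)], [0.6, 0.7], [0.1, 0.2])
        assert ts.sigma == 0.0 and ts.quasi_threshold == 0.6
        assert ts.quasi_threshold == ts.mu - ts.sigma

    def test_perfect_separation_threshold_in_gap(self, header):
        r = Raster(header, np.full((8, 10), 0.5))
        pres = [0.8, 0.85, 0.9]
        bg = [0.1, 0.2, 0.3]
        ts = threshold_stats(r, [(0, 0), (1, 1)], pres, bg)
        # at the maxss threshold sensitivity = specificity = 1
        t = ts.maxss_threshold
        assert np.mean(np.array(pres) >= t) == 1.0
        assert np.mean(np.array(bg) < t) == 1.0

    def test_maxss_matches_exhaustive_search(self, header):
        rng = np.random.default_rng(3)
        r = Raster(header, np.full((8, 10), 0.5))
        pres = rng.beta(4, 2, 50)
        bg = rng.beta(2, 4, 500)
        ts = threshold_stats(r, [(0, 0), (1, 1)], pres, bg)
        best_ss = -np.inf
        best_t = None
        for t in np.unique(pres):
            ss = np.mean(pres >= t) + np.mean(bg < t)
            if ss > best_ss:
                best_ss, best_t = ss, t
        assert ts.maxss_threshold == best_t

    def test_all_occurrences_masked_errors(self, header):
        vals = np.full((8, 10), -9999.0)
        r = Raster(header, vals)
        with pytest.raises(ValueError):
            threshold_stats(r, [(0, 0), (1, 1)], [0.5], [0.2])


class TestBinarize:
    def test_threshold_above_max_empty(self, header):
        r = Raster(header, np.random.default_rng(0).uniform(0, 1, (8, 10)))
        bm = binarize(r, 2.0)
        assert bm.suitable.sum() == 0

    def test_threshold_below_min_all_suitable(self, header):
        r = Raster(header, np.random.default_rng(0).uniform(0, 1, (8, 10)))
        bm = binarize(r, -1.0)
        assert bm.suitable.sum() == r.mask.sum()

    def test_ties_are_suitable(self, header):
        r = Raster(header, np.full((8, 10), 0.42))
        assert binarize(r, 0.42).suitable.all()

    def test_monotone_in_threshold(self, header):
        rng = np.random.default_rng(1)
        r = Raster(header, rng.uniform(0, 1, (8, 10)))
        prev = None
        for t in sorted(rng.uniform(0, 1, 10)):
            cur = binarize(r, t).suitable
            if prev is not None:
                assert not (cur & ~prev).any()  # raising t never adds cells
            prev = cur


class TestChangeMap:
    def test_identity_scenario(self, header):
        bm = random_binary(header, np.random.default_rng(2))
        cm = change_map(bm, bm)
        c = cm.counts()
        assert c["gain"] == 0 and c["loss"] == 0
        assert c["retention"] == int(bm.suitable.sum())
        assert cm.areas_km2["retention"] == pytest.approx(area_km2(bm))

    def test_complement_scenario(self, header):
        bm = random_binary(header, np.random.default_rng(3))
        comp = BinaryMap(header, 1 - bm.states, bm.mask.copy())
        cm = change_map(bm, comp)
        assert cm.counts()["retention"] == 0

    def test_conservation_identities(self, header):
        """retention + loss = current suitable; retention + gain = future."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b = random_binary(header, rng), random_binary(header, rng)
            cm = change_map(a, b)
            c = cm.counts()
            assert c["retention"] + c["loss"] == int(a.suitable.sum())
            assert c["retention"] + c["gain"] == int(b.suitable.sum())
            # independent per-cell tally
            tally = {"retention": 0, "gain": 0, "loss": 0, "absent": 0}
            for i in range(header.nrows):
                for j in range(header.ncols):
                    key = {(1, 1): "retention", (0, 1): "gain",
                           (1, 0): "loss", (0, 0): "absent"}[
                        (int(a.states[i, j]), int(b.states[i, j]))]
                    tally[key] += 1
            assert tally == c

    def test_misaligned_maps_error(self, header):
        other = GridHeader(10, 8, xll=101.0, yll=30.0, cellsize=0.25)
        a = random_binary(header, np.random.default_rng(5))
        b = random_binary(other, np.random.default_rng(6))
        with pytest.raises(ValueError):
            change_map(a, b)


class TestArea:
    def test_zero_suitable_zero_area(self, header):
        bm = BinaryMap(header, np.zeros((8, 10), np.int8),
                       np.ones((8, 10), bool))
        assert area_km2(bm) == 0.0

    def test_equatorial_one_degree_cell_closed_form(self):
        hdr = GridHeader(1, 1, xll=0.0, yll=-0.5, cellsize=1.0)
        bm = BinaryMap(hdr, np.ones((1, 1), np.int8), np.ones((1, 1), bool))
        expected = (
            EARTH_RADIUS_KM**2
            * math.radians(1.0)
            * (math.sin(math.radians(0.5)) - math.sin(math.radians(-0.5)))
        )
        assert area_km2(bm) == pytest.approx(expected, rel=1e-12)

    def test_additivity_of_disjoint_sets(self, header):
        rng = np.random.default_rng(7)
        sel = rng.uniform(size=(8, 10)) < 0.5
        a = sel & (np.arange(10) < 5)
        b = sel & (np.arange(10) >= 5)
        assert area_km2(sel, header) == pytest.approx(
            area_km2(a, header) + area_km2(b, header)
        )

    def test_whole_grid_approaches_spherical_zone(self):
        """Total valid-grid area converges to the closed-form zone area."""
        zone = lambda hdr: (
            EARTH_RADIUS_KM**2
            * math.radians(hdr.ncols * hdr.cellsize)
            * (math.sin(math.radians(hdr.yur)) - math.sin(math.radians(hdr.yll)))
        )
        for ncells, size in ((10, 1.0), (100, 0.1)):
            hdr = GridHeader(ncells, ncells, xll=0.0, yll=20.0, cellsize=size)
            total = cell_areas_km2(hdr).sum()
            assert total == pytest.approx(zone(hdr), rel=1e-10)


class TestCentroid:
    def test_single_cell_center(self, header):
        states = np.zeros((8, 10), np.int8)
        states[3, 4] = 1
        bm = BinaryMap(header, states, np.ones((8, 10), bool))
        cen = centroid(bm)
        lon, lat = header.cell_center(3, 4)
        assert cen.lon == pytest.approx(lon) and cen.lat == pytest.approx(lat)

    def test_symmetric_cells_centroid_on_meridian(self, header):
        states = np.zeros((8, 10), np.int8)
        states[2, 3] = 1
        states[2, 6] = 1  # same row, symmetric about col 4.5
        bm = BinaryMap(header, states, np.ones((8, 10), bool))
        cen = centroid(bm)
        mid_lon = (header.cell_center(2, 3)[0] + header.cell_center(2, 6)[0]) / 2
        assert cen.lon == pytest.approx(mid_lon, abs=1e-9)

    def test_empty_map_undefined(self, header):
        bm = BinaryMap(header, np.zeros((8, 10), np.int8), np.ones((8, 10), bool))
        assert not centroid(bm).defined

    def test_agreement_with_vector_average(self, header):
        rng = np.random.default_rng(8)
        for _ in range(10):
            bm = random_binary(header, rng)
            if not bm.suitable.any():
                continue
            cen = centroid(bm)
            lons, lats = header.cell_centers()
            w = cell_areas_km2(header)[bm.suitable]
            lam, phi = np.radians(lons[bm.suitable]), np.radians(lats[bm.suitable])
            v = np.array([
                (w * np.cos(phi) * np.cos(lam)).sum(),
                (w * np.cos(phi) * np.sin(lam)).sum(),
                (w * np.sin(phi)).sum(),
            ])
            v /= np.linalg.norm(v)
            assert cen.lat == pytest.approx(math.degrees(math.asin(v[2])), abs=1e-6)
            assert cen.lon == pytest.approx(
                math.degrees(math.atan2(v[1], v[0])), abs=1e-6
            )


class TestCentroidShift:
    def test_identical_centroids_zero(self):
        a = Centroid(110.0, 35.0, 100.0)
        d, _ = centroid_shift(a, a)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_one_degree_north(self):
        a = Centroid(110.0, 35.0, 1.0)
        b = Centroid(110.0, 36.0, 1.0)
        d, bearing = centroid_shift(a, b)
        assert d == pytest.approx(EARTH_RADIUS_KM * math.radians(1.0), rel=1e-9)
        assert bearing == pytest.approx(0.0, abs=1e-9)

    def test_distance_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = Centroid(rng.uniform(-180, 180), rng.uniform(-60, 60), 1.0)
            b = Centroid(rng.uniform(-180, 180), rng.uniform(-60, 60), 1.0)
            assert centroid_shift(a, b)[0] == pytest.approx(
                centroid_shift(b, a)[0], rel=1e-12
            )

    def test_undefined_centroid_errors(self):
        a = Centroid(110.0, 35.0, 1.0)
        bad = Centroid(math.nan, math.nan, 0.0, defined=False)
        with pytest.raises(ValueError):
            centroid_shift(a, bad)
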