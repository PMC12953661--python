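import numpy as np
import pandas as pd
import pytest

from lesionnet.connectome import (
    Connectome,
    LesionMask,
    Parcellation,
    Tractogram,
    assign_endpoints,
    build_connectome,
    disconnection_indices,
    intersect_lesions,
)
from lesionnet.errors import DataError
from lesionnet.synthetic import simulate_parcellation, simulate_tractogram


def make_parcellation():
    """4 nodes: 1,2 left (supra), 3 right supra, 4 right infratentorial."""
    labels = np.zeros((10, 10, 10), dtype=np.int32)
    labels[1:3, 1:3, 6:8] = 1
    labels[1:3, 6:8, 6:8] = 2
    labels[7:9, 1:3, 6:8] = 3
    labels[7:9, 6:8, 0:2] = 4
    node_table = pd.DataFrame(
        {
            "node_id": [1, 2, 3, 4],
            "hemisphere": ["L", "L", "R", "R"],
            "supratentorial": [True, True, True, False],
        }
    )
    return Parcellation(labels=labels, voxel_size=1.0, node_table=node_table)


def straight(p0, p1, n=10):
    t = np.linspace(0, 1, n)[:, None]
    return np.asarray(p0) * (1 - t) + np.asarray(p1) * t


def center(voxel):
    return np.asarray(voxel) + 0.5


class TestAssignEndpoints:
    def test_endpoint_inside_region(self):
        parc = make_parcellation()
        tract = Tractogram([straight(center((1, 1, 6)), center((7, 1, 6)))], [0.5])
        a = assign_endpoints(tract, parc)
        assert a.loc[0, "node_a"] == 1 and a.loc[0, "node_b"] == 3
        assert not a.loc[0, "excluded"]

    def test_search_radius(self):
        # endpoint in background, nearest labeled voxel center 1.2 mm away
        parc = make_parcellation()
        bg_point = center((2, 1, 6)) + np.array([1.2, 0.0, 0.0])  # x=3.7 -> voxel 3
        tract = Tractogram([straight(bg_point, center((7, 1, 6)))], [0.5])
        a2 = assign_endpoints(tract, parc, search_radius_mm=2.0)
        assert a2.loc[0, "node_a"] == 1 and not a2.loc[0, "excluded"]
        a1 = assign_endpoints(tract, parc, search_radius_mm=1.0)
        assert a1.loc[0, "excluded"]

    def test_self_loop_excluded(self):
        parc = make_parcellation()
        tract = Tractogram([straight(center((1, 1, 6)), center((2, 2, 7)))], [0.5])
        a = assign_endpoints(tract, parc)
        assert a.loc[0, "excluded"]

    def test_brute_force_nearest(self):
        # oracle: scan every labeled voxel for the nearest center
        parc = make_parcellation()
        rng = np.random.default_rng(0)
        labeled = np.argwhere(parc.labels > 0)
        for _ in range(20):
            p = rng.uniform(0, 10, 3)
            d = np.linalg.norm(labeled + 0.5 - p, axis=1)
            j = int(np.argmin(d))
            expected = (
                int(parc.labels[tuple(labeled[j])]) if d[j] <= 3.0 else 0
            )
            tract = Tractogram([straight(p, center((7, 1, 6)))], [0.5])
            a = assign_endpoints(tract, parc, search_radius_mm=3.0)
            got = 0 if a.loc[0, "excluded"] and a.loc[0, "node_a"] == 0 else a.loc[0, "node_a"]
            if expected == 0:
                assert a.loc[0, "node_a"] == 0
            else:
                assert got == expected


class TestBuildConnectome:
    def test_ten_streamlines_one_pair(self):
        parc = make_parcellation()
        sls = [straight(center((1, 1, 6)), center((1, 6, 6))) for _ in range(10)]
        tract = Tractogram(sls, [0.5] * 10)
        a = assign_endpoints(tract, parc)
        conn = build_connectome(a, tract, parc.node_table)
        assert conn.count[0, 1] == 10
        assert conn.fa[0, 1] == pytest.approx(0.5)
        assert conn.count[1, 0] == 10

    def test_empty(self):
        parc = make_parcellation()
        tract = Tractogram([], np.array([]))
        a = assign_endpoints(tract, parc)
        conn = build_connectome(a, tract, parc.node_table)
        assert conn.count.sum() == 0 and conn.fa.sum() == 0

    def test_row_sums_match_tally(self):
        parc = simulate_parcellation(8, (16, 16, 16), seed=2)
        tract = simulate_tractogram(parc, 150, 0.4, seed=3)
        a = assign_endpoints(tract, parc)
        conn = build_connectome(a, tract, parc.node_table)
        # independent tally over assignment rows
        n = len(parc.node_table)
        tally = np.zeros((n, n))
        for _, row in a[~a["excluded"]].iterrows():
            i, j = row["node_a"] - 1, row["node_b"] - 1
            tally[i, j] += 1
            tally[j, i] += 1
        np.testing.assert_array_equal(conn.count, tally)


class TestIntersectLesions:
    def test_hit_and_empty(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[5, 5, 5] = True
        lm = LesionMask(mask=mask, voxel_size=1.0)
        through = Tractogram([straight((0.5, 5.5, 5.5), (9.5, 5.5, 5.5))], [0.5])
        assert intersect_lesions(through, lm).tolist() == [True]
        empty = LesionMask(mask=np.zeros((10, 10, 10), dtype=bool), voxel_size=1.0)
        assert intersect_lesions(through, empty).tolist() == [False]

    def test_constructed_hits(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[5, 5, :] = True
        lm = LesionMask(mask=mask, voxel_size=1.0)
        sls, expected = [], []
        for k in range(10):
            if k < 3:  # passes through the lesion column
                sls.append(straight((0.5, 5.5, 2.5), (9.5, 5.5, 2.5)))
                expected.append(True)
            else:  # runs parallel, one row over
                sls.append(straight((0.5, 8.5, 2.5), (9.5, 8.5, 2.5)))
                expected.append(False)
        tract = Tractogram(sls, [0.5] * 10)
        assert intersect_lesions(tract, lm).tolist() == expected


class TestDisconnectionIndices:
    def build(self, n_intra_lesioned=3):
        parc = make_parcellation()
        sls, hits = [], []
        for k in range(10):  # intra left supra (1-2)
            sls.append(straight(center((1, 1, 6)), center((1, 6, 6))))
            hits.append(k < n_intra_lesioned)
        for _ in range(4):  # inter (1-3)
            sls.append(straight(center((1, 1, 6)), center((7, 1, 6))))
            hits.append(False)
        for _ in range(2):  # other: right intra with infratentorial node (3-4)
            sls.append(straight(center((7, 1, 6)), center((7, 6, 0))))
            hits.append(False)
        tract = Tractogram(sls, [0.5] * len(sls))
        a = assign_endpoints(tract, parc)
        return parc, tract, a, np.array(hits)

    def test_direct_ratios(self):
        parc, tract, a, hits = self.build()
        d = disconnection_indices(a, hits, parc.node_table)
        assert d.intra_disc_pct == pytest.approx(30.0)
        assert d.inter_disc_pct == pytest.approx(0.0)
        assert d.commissural_ratio == pytest.approx(4 / 16)
        assert d.class_counts == {"intra": 10, "inter": 4, "other": 2}

    def test_total_denominator_switch(self):
        parc, tract, a, hits = self.build()
        d = disconnection_indices(a, hits, parc.node_table, class_denominator=False)
        assert d.intra_disc_pct == pytest.approx(100 * 3 / 16)

    def test_empty_class_is_missing(self):
        parc = make_parcellation()
        sls = [straight(center((1, 1, 6)), center((7, 1, 6)))]  # inter only
        tract = Tractogram(sls, [0.5])
        a = assign_endpoints(tract, parc)
        d = disconnection_indices(a, np.array([True]), parc.node_table)
        assert np.isnan(d.intra_disc_pct)
        assert d.inter_disc_pct == pytest.approx(100.0)

    def test_conservation(self):
        parc, tract, a, hits = self.build()
        d = disconnection_indices(a, hits, parc.node_table)
        assert sum(d.class_counts.values()) == d.s_total
        for cls in d.class_counts:
            assert d.class_lesioned[cls] <= d.class_counts[cls]

    def test_monotone_under_lesion_growth(self):
        parc = simulate_parcellation(8, (16, 16, 16), seed=5)
        tract = simulate_tractogram(parc, 120, 0.3, seed=6)
        a = assign_endpoints(tract, parc)
        small = np.zeros((16, 16, 16), dtype=bool)
        small[7:9, 7:9, 7:9] = True
        big = small.copy()
        big[5:11, 5:11, 5:11] = True
        d_small = disconnection_indices(
            a, intersect_lesions(tract, LesionMask(small, 1.0)), parc.node_table
        )
        d_big = disconnection_indices(
            a, intersect_lesions(tract, LesionMask(big, 1.0)), parc.node_table
        )
        for attr in ("intra_disc_pct", "inter_disc_pct"):
            lo, hi = getattr(d_small, attr), getattr(d_big, attr)
            if not (np.isnan(lo) or np.isnan(hi)):
                assert hi >= lo


class TestBruteForceOracle:
    """Full independent reimplementation on a simulated tractogram."""

    def test_matrices_and_indices_match(self):
        parc = simulate_parcellation(10, (16, 16, 16), seed=8)
        tract = simulate_tractogram(parc, 200, 0.35, seed=9)
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[6:10, 6:10, 6:10] = True
        lm = LesionMask(mask, 1.0)

        a = assign_endpoints(tract, parc)
        conn = build_connectome(a, tract, parc.node_table)
        hits = intersect_lesions(tract, lm)
        d = disconnection_indices(a, hits, parc.node_table)

        # oracle: endpoints at voxel centers -> direct label lookup
        hemi = dict(zip(parc.node_table["node_id"], parc.node_table["hemisphere"]))
        supra = dict(zip(parc.node_table["node_id"], parc.node_table["supratentorial"]))
        n = len(parc.node_table)
        count = np.zeros((n, n))
        fa_sum = np.zeros((n, n))
        cls_counts = {"intra": 0, "inter": 0, "other": 0}
        cls_les = {"intra": 0, "inter": 0, "other": 0}
        s_assigned = 0
        for s, f in zip(tract.streamlines, tract.fa):
            na = int(parc.labels[tuple(np.floor(s[0]).astype(int))])
            nb = int(parc.labels[tuple(np.floor(s[-1]).astype(int))])
            if na == 0 or nb == 0 or na == nb:
                continue
            s_assigned += 1
            count[na - 1, nb - 1] += 1
            count[nb - 1, na - 1] += 1
            fa_sum[na - 1, nb - 1] += f
            fa_sum[nb - 1, na - 1] += f
            # brute-force lesion check at fine sampling
            hit = False
            for p, q in zip(s[:-1], s[1:]):
                for t in np.linspace(0, 1, 50):
                    v = np.floor(p * (1 - t) + q * t).astype(int)
                    if (v >= 0).all() and (v < 16).all() and mask[tuple(v)]:
                        hit = True
                        break
                if hit:
                    break
            if {hemi[na], hemi[nb]} == {"L", "R"}:
                key = "inter"
            elif hemi[na] == hemi[nb] and supra[na] and supra[nb]:
                key = "intra"
            else:
                key = "other"
            cls_counts[key] += 1
            if hit:
                cls_les[key] += 1

        np.testing.assert_array_equal(conn.count, count)
        np.testing.assert_allclose(
            conn.fa, np.where(count > 0, fa_sum / np.maximum(count, 1), 0.0)
        )
        assert d.class_counts == cls_counts
        assert d.class_lesioned == cls_les
        assert d.s_total == s_assigned
        assert d.commissural_ratio == pytest.approx(cls_counts["inter"] / s_assigned)


class TestTypeInvariants:
    def test_connectome_validation(self):
        nt = pd.DataFrame({"node_id": [1, 2], "hemisphere": ["L", "R"], "supratentorial": [True, True]})
        with pytest.raises(DataError):
            Connectome(count=np.array([[0, 1], [2, 0]]), fa=np.zeros((2, 2)), node_table=nt)
        with pytest.raises(DataError):
            Connectome(count=np.zeros((2, 2)), fa=np.array([[0, 0.5], [0.5, 0]]), node_table=nt)

    def test_tractogram_validation(self):
        with pytest.raises(DataError):
            Tractogram([np.zeros((1, 3))], [0.5])
        with pytest.raises(DataError):
            Tractogram([np.zeros((3, 3))], [np.inf])

    def test_parcellation_contiguous_ids(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0, 0, 0] = 5
        nt = pd.DataFrame({"node_id": [5], "hemisphere": ["L"], "supratentorial": [True]})
        with pytest.raises(DataError):
            Parcellation(labels=labels, voxel_size=1.0, node_table=nt)
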