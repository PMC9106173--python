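import numpy as np
import pandas as pd
import pytest

from topogait.embedding import EmbedConfig, PointCloud
from topogait.features import (
    EDSS_THRESHOLDS,
    Partition,
    SingletonGroupError,
    edss_table,
    experiment_tables,
    hs_ms_table,
    longitudinal_table,
    msd,
    sd,
    silhouette_group,
    silhouette_point,
)
from topogait.signal import InvalidInputError, TrialRecord


def col(*xs):
    """Collinear points on the x-axis."""
    return np.array([[x, 0.0] for x in xs])


class TestSilhouettePoint:
    def test_hand_computed_collinear_example(self):
        # a = 1, b = (10 + 11)/2 = 10.5 -> (10.5 - 1)/10.5
        got = silhouette_point(np.array([0.0, 0.0]), col(0, 1), col(10, 11))
        assert got == pytest.approx(9.5 / 10.5, abs=1e-9)

    def test_mirror_symmetric_groups_score_zero(self):
        # Cj is the mirror image about x of x's own group-mates: a = b
        x = np.array([0.0, 0.0])
        assert silhouette_point(x, col(0, 2, 5), col(-2, -5)) == pytest.approx(0.0)

    def test_point_closer_to_other_group_is_negative(self):
        assert silhouette_point(np.array([9.0, 0.0]), col(0, 9), col(10, 11)) < 0

    def test_singleton_own_group_rejected(self):
        with pytest.raises(SingletonGroupError):
            silhouette_point(np.array([0.0, 0.0]), col(0), col(1, 2))


class TestSilhouetteGroup:
    def test_hand_computed_collinear_example(self):
        want = (9.5 / 10.5 + 8.5 / 9.5) / 2
        assert silhouette_group(col(0, 1), col(10, 11)) == pytest.approx(
            want, abs=1e-9
        )

    def test_mirror_configuration_is_symmetric(self):
        a = silhouette_group(col(0, 1), col(10, 11))
        b = silhouette_group(col(10, 11), col(0, 1))
        assert a == pytest.approx(b, abs=1e-9)

    def test_asymmetric_in_general(self):
        Ci, Cj = col(0, 1), col(2, 50)
        assert silhouette_group(Ci, Cj) != pytest.approx(silhouette_group(Cj, Ci))

    def test_coincident_groups_nonpositive(self):
        # a averages over n-1 points, b over n (including the zero distance)
        pts = col(0, 1, 3)
        assert silhouette_group(pts, pts) <= 0

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            Ci = rng.standard_normal((int(rng.integers(2, 8)), 2))
            Cj = rng.standard_normal((int(rng.integers(1, 8)), 2))
            assert -1 <= silhouette_group(Ci, Cj) <= 1

    def test_separation_monotonicity(self):
        """Translating Cj away from Ci never decreases Sil(Ci, Cj)."""
        rng = np.random.default_rng(1)
        direction = np.array([1.0, 0.5]) / np.linalg.norm([1.0, 0.5])
        Ci = rng.standard_normal((6, 2))
        # Cj starts strictly on the far side of Ci along the direction, so
        # further translation increases every cross-group distance
        Cj = rng.standard_normal((5, 2)) + 8 * direction
        scores = [silhouette_group(Ci, Cj + t * direction) for t in
                  (0, 1, 2, 5, 10, 50)]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_rigid_motion_invariance_and_scale_behaviour(self):
        rng = np.random.default_rng(2)
        Ci = rng.standard_normal((5, 2))
        Cj = rng.standard_normal((4, 2)) + 3
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        base = silhouette_group(Ci, Cj)
        assert silhouette_group(Ci @ R.T + 5, Cj @ R.T + 5) == pytest.approx(base)
        assert silhouette_group(3 * Ci, 3 * Cj) == pytest.approx(base)


class TestMsdSd:
    def test_two_point_group(self):
        pts = np.array([[0, 0], [3, 4.0]])
        assert msd(pts) == pytest.approx(25.0)
        assert sd(pts) == pytest.approx(25.0)

    def test_three_collinear_points(self):
        pts = col(0, 1, 2)
        assert msd(pts) == pytest.approx(2.0)   # (1 + 1 + 4) / 3
        assert sd(pts) == pytest.approx(4.0)

    def test_scale_quadratically(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((6, 2))
        assert msd(4 * pts) == pytest.approx(16 * msd(pts))
        assert sd(4 * pts) == pytest.approx(16 * sd(pts))

    def test_sd_dominates_msd(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            pts = rng.standard_normal((int(rng.integers(2, 10)), 2))
            assert sd(pts) >= msd(pts)

    def test_msd_equals_unordered_pair_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            pts = rng.standard_normal((int(rng.integers(2, 8)), 2))
            n = pts.shape[0]
            acc = [np.sum((pts[i] - pts[j]) ** 2)
                   for i in range(n) for j in range(i + 1, n)]
            assert msd(pts) == pytest.approx(np.mean(acc), abs=1e-9)

    def test_singletons(self):
        with pytest.raises(SingletonGroupError):
            msd(col(0))
        assert sd(col(0)) == 0.0
        with pytest.raises(InvalidInputError):
            sd(np.empty((0, 2)))


def _cloud(coords, ids):
    frame = pd.DataFrame(coords, index=ids, columns=["x", "y"])
    frame.index.name = "trial_id"
    return PointCloud(coords=frame, config=EmbedConfig())


def _records(spec):
    """spec: list of (trial_id, subject, group, edss, session)."""
    return [TrialRecord(trial_id=t, subject_id=s, group=g, edss=e, session=sess)
            for t, s, g, e, sess in spec]


class TestExperimentTables:
    def setup_method(self):
        # two tight planted clusters: healthy near origin, patients far away
        rng = np.random.default_rng(6)
        hs = rng.normal(0, 0.3, size=(6, 2))
        ms = rng.normal(8, 0.3, size=(6, 2))
        ids = [f"h{i}" for i in range(6)] + [f"m{i}" for i in range(6)]
        self.pc = _cloud(np.vstack([hs, ms]), ids)
        spec = [(f"h{i}", f"HS{i % 3}", "HS", 0.0, "M0" if i % 2 else "M6")
                for i in range(6)]
        spec += [(f"m{i}", f"MS{i % 3}", "MS", 4.0, "M0" if i % 2 else "M6")
                 for i in range(6)]
        self.meta = _records(spec)

    def test_hs_ms_table_recovers_planted_separation(self):
        table = hs_ms_table(self.pc, self.meta)
        assert table.loc[0, "Sil(HS,MS)"] > 0
        assert table.loc[0, "Sil(MS,HS)"] > 0
        assert set(table.columns) == {
            "Sil(HS,MS)", "Sil(MS,HS)", "MSD(HS)", "MSD(MS)", "SD(HS)", "SD(MS)",
        }

    def test_edss_table_iterates_both_orientations(self):
        table = edss_table(self.pc, self.meta)
        assert list(table["i"]) == list(EDSS_THRESHOLDS)
        # thresholds below 4 separate the two planted clusters
        sub = table[table["i"] < 4.0]
        assert (sub["Sil(<=i,>i)"] > 0).all()
        assert (sub["Sil(>i,<=i)"] > 0).all()
        # thresholds >= 4 leave the > i side empty -> silhouettes unavailable
        top = table[table["i"] >= 4.0]
        assert top["Sil(<=i,>i)"].isna().all()

    def test_longitudinal_one_row_per_subject(self):
        table = longitudinal_table(self.pc, self.meta)
        assert sorted(table["subject"]) == sorted(
            {r.subject_id for r in self.meta}
        )

    def test_single_session_point_marks_silhouette_unavailable(self):
        ids = ["a", "b", "c", "d"]
        pc = _cloud(np.array([[0, 0], [1, 0], [0, 1], [5, 5.0]]), ids)
        meta = _records([
            ("a", "S1", "MS", 3.0, "M0"), ("b", "S1", "MS", 3.0, "M0"),
            ("c", "S1", "MS", 3.0, "M0"), ("d", "S1", "MS", 3.0, "M6"),
        ])
        row = longitudinal_table(pc, meta).iloc[0]
        assert np.isnan(row["Sil(M6,M0)"])     # singleton M6 group
        assert np.isnan(row["MSD(M6)"])
        assert row["SD(M6)"] == 0.0
        assert np.isfinite(row["Sil(M0,M6)"])

    def test_planted_outlier_inflates_sd_not_msd_elsewhere(self):
        """A far-away corrupted trial maximises its session's SD."""
        rng = np.random.default_rng(8)
        coords = rng.normal(0, 0.5, size=(12, 2))
        coords[0] = [40, 40]                     # the corrupted trial
        ids = [f"t{i}" for i in range(12)]
        pc = _cloud(coords, ids)
        meta = _records([
            (f"t{i}", f"S{i // 4}", "MS", 3.0, "M0") for i in range(12)
        ])
        table = longitudinal_table(pc, meta).set_index("subject")
        assert table["SD(M0)"].idxmax() == "S0"
        others = table.drop("S0")
        assert table.loc["S0", "SD(M0)"] > 50 * others["SD(M0)"].max()

    def test_experiment_dispatch(self):
        tables = experiment_tables(self.pc, self.meta)
        assert set(tables) == {"HS_MS", "EDSS", "longitudinal"}
        with pytest.raises(InvalidInputError):
            experiment_tables(self.pc, self.meta, ("bogus",))


class TestPartition:
    def test_overlapping_groups_rejected(self):
        with pytest.raises(InvalidInputError):
            Partition(groups={"a": ("x", "y"), "b": ("y",)})

    def test_disjoint_groups_accepted(self):
        p = Partition(groups={"a": ("x",), "b": ("y", "z")}, name="demo")
        assert p.groups["b"] == ("y", "z")
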