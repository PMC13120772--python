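"""Threshold calibration: F1 sweep, percentile estimator, max-rule harmonization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ghannot.calibrate import (
    CalibrationPoint,
    ThresholdCalibrator,
    cluster_percentile_threshold,
    compute_calibration_points,
    f1_score,
    harmonize_thresholds,
    sweep_family_threshold,
)
from ghannot.io import ReferenceBundle, ThresholdSet, validate_threshold_hierarchy
from ghannot.synthetic import SyntheticDesign, generate_reference_db

from _oracle import dp_align, percentile_oracle


class TestF1Score:
    def test_perfect(self):
        assert f1_score(1.0, 1.0) == 1.0

    def test_degenerate_zero_by_convention(self):
        assert f1_score(0.0, 0.0) == 0.0

    def test_headline_arithmetic(self):
        # precision 0.959 at full recall gives F1 ~ 0.9791
        assert f1_score(0.959, 1.0) == pytest.approx(2 * 0.959 / 1.959)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_harmonic_mean_bounds(self, p, r):
        f1 = f1_score(p, r)
        assert 0.0 <= f1 <= 1.0
        assert f1 <= max(p, r) + 1e-12
        if p > 0 and r > 0:
            assert f1 == pytest.approx(2 * p * r / (p + r))


class TestCalibrationPoints:
    def test_identical_twin_gives_intra_100(self, small_bundle):
        # every generated cluster has >= 2 members; each member's best
        # intra hit exists and sits in the within-cluster band
        points = compute_calibration_points(small_bundle)
        assert len(points) == len(small_bundle.sequences)
        for p in points:
            assert p.best_intra_identity is not None
            assert p.best_intra_identity > 70.0

    def test_single_family_database_rejected(self, small_bundle):
        fam = small_bundle.families[0]
        seqs = [s for s in small_bundle.sequences if s.family == fam]
        clusters = [c for c in small_bundle.clusters if c.family == fam]
        db = ReferenceBundle(seqs, clusters, small_bundle.thresholds)
        with pytest.raises(ValueError, match="families"):
            compute_calibration_points(db)

    def test_points_match_allvsall_dp_oracle(self):
        design = SyntheticDesign(n_families=3, clusters_per_family=1,
                                 members_per_cluster=3, sequence_length=100,
                                 seed=3)
        bundle, _ = generate_reference_db(design)
        points = {p.seq_id: p for p in compute_calibration_points(bundle)}
        for s in bundle.sequences:
            best = {}
            for t in bundle.sequences:
                if t.seq_id == s.seq_id:
                    continue
                res = dp_align(s.sequence, t.sequence)
                if res is None:
                    continue
                raw, qs, qe, aln_len, n_ident = res
                if (qe - qs + 1) / len(s.sequence) < 0.5:
                    continue
                key = (-raw, -(100 * n_ident / aln_len), t.seq_id)
                if t.family not in best or key < best[t.family][0]:
                    best[t.family] = (key, 100 * n_ident / aln_len)
            p = points[s.seq_id]
            expected_intra = best.get(s.family)
            if expected_intra is None:
                assert p.best_intra_identity is None
            else:
                assert p.best_intra_identity == pytest.approx(expected_intra[1])
            for fam, (_, ident) in best.items():
                if fam != s.family:
                    assert p.cross_family_identity[fam] == pytest.approx(ident)


def _point(family, intra=None, cross=None):
    cross = cross or {}
    return CalibrationPoint(
        seq_id=f"s{id(object())}",
        family=family,
        best_intra_identity=intra,
        best_inter_identity=max(cross.values()) if cross else None,
        cross_family_identity=cross,
    )


class TestFamilySweep:
    def test_separable_case_picks_largest_f1_maximizing_threshold(self):
        points = [_point("A", intra=90.0) for _ in range(5)]
        points += [_point("B", intra=95.0, cross={"A": 40.0}) for _ in range(5)]
        grid = list(np.arange(30.0, 101.0, 5.0))
        thr, row = sweep_family_threshold(points, "A", grid)
        assert thr == 90.0  # any t in (40, 90] has F1=1; tie -> largest
        assert row.f1 == 1.0

    def test_single_value_grid(self):
        points = [_point("A", intra=90.0), _point("B", intra=80.0, cross={"A": 40.0})]
        thr, _ = sweep_family_threshold(points, "A", [75.0])
        assert thr == 75.0

    def test_planted_overlap_matches_counting_oracle(self):
        rng = np.random.default_rng(8)
        members = [_point("A", intra=float(v)) for v in rng.uniform(78, 95, size=40)]
        cross_vals = list(rng.uniform(40, 70, size=36)) + list(rng.uniform(76, 82, size=4))
        others = [_point("B", intra=90.0, cross={"A": float(v)}) for v in cross_vals]
        grid = [30.0 + 0.5 * i for i in range(141)]
        thr, row = sweep_family_threshold(members + others, "A", grid)

        def counts(t):
            tp = sum(1 for p in members if p.best_intra_identity >= t)
            fn = len(members) - tp
            fp = sum(1 for p in others if p.cross_family_identity["A"] >= t)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            return 2 * prec * rec / (prec + rec) if prec + rec else 0.0

        best_f1 = max(counts(t) for t in grid)
        assert row.f1 == pytest.approx(best_f1)
        assert counts(thr) == pytest.approx(best_f1)
        assert all(counts(t) <= best_f1 + 1e-12 for t in grid)
        # ties resolved toward the larger threshold
        assert thr == max(t for t in grid if counts(t) == pytest.approx(best_f1))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            sweep_family_threshold([_point("A", intra=90.0)], "Z", [50.0])


class TestClusterPercentile:
    def test_uniform_identities_return_that_value(self, rng):
        # all members pairwise-identical: every best intra identity is 100
        from ghannot.io import ClusterRecord, ReferenceSequence
        from ghannot.synthetic import random_sequence

        seq = random_sequence(80, rng)
        seqs = [ReferenceSequence(f"s{i}", "g", "GH2", seq, "c1") for i in range(4)]
        cluster = ClusterRecord("c1", "GH2", "e", "putative", "yes", "intracellular", 4, 80.0)
        db = ReferenceBundle(seqs, [cluster], ThresholdSet({"GH2": 50.0}, {"c1": 80.0}))
        assert cluster_percentile_threshold(db, "c1") == 100.0

    def test_matches_sort_and_interpolate_oracle(self, small_bundle):
        from ghannot.calibrate import _intra_cluster_best_identities

        for c in small_bundle.clusters:
            members = small_bundle.sequences_of_cluster(c.cluster_id)
            identities = _intra_cluster_best_identities(members, None, 0.5)
            got = cluster_percentile_threshold(small_bundle, c.cluster_id)
            assert got == pytest.approx(percentile_oracle(identities, 0.10))

    def test_percentile_zero_is_minimum(self, small_bundle):
        from ghannot.calibrate import _intra_cluster_best_identities

        c = small_bundle.clusters[0]
        members = small_bundle.sequences_of_cluster(c.cluster_id)
        identities = _intra_cluster_best_identities(members, None, 0.5)
        got = cluster_percentile_threshold(small_bundle, c.cluster_id, percentile=0.0)
        assert got == pytest.approx(min(identities))

    def test_singleton_cluster_rejected(self, small_bundle):
        import dataclasses

        seqs = list(small_bundle.sequences)
        lonely = dataclasses.replace(seqs[0], seq_id="lonely", cluster_id="solo")
        clusters = list(small_bundle.clusters) + [
            dataclasses.replace(small_bundle.clusters[0], cluster_id="solo", member_count=1)
        ]
        db = ReferenceBundle(seqs + [lonely], clusters, small_bundle.thresholds)
        with pytest.raises(ValueError, match="singleton|< 2 members"):
            cluster_percentile_threshold(db, "solo")

    @given(st.lists(st.floats(0, 95), min_size=2, max_size=30),
           st.floats(0.5, 5.0))
    def test_percentile_is_shift_monotone(self, values, delta):
        base = percentile_oracle(values, 0.10)
        shifted = percentile_oracle([v + delta for v in values], 0.10)
        assert shifted == pytest.approx(base + delta, abs=1e-9)


class TestHarmonize:
    @pytest.mark.parametrize("raw,expected", [(65.0, 70.0), (82.0, 82.0)])
    def test_max_rule(self, raw, expected):
        ts = harmonize_thresholds({"GH95": 70.0}, {"c1": raw}, {"c1": "GH95"})
        assert ts.cluster_thresholds["c1"] == expected

    def test_empty_cluster_map_keeps_family_thresholds(self):
        ts = harmonize_thresholds({"GH95": 70.0}, {}, {})
        assert ts.family_thresholds == {"GH95": 70.0}
        assert ts.cluster_thresholds == {}

    def test_singleton_inherits_family_threshold(self):
        ts = harmonize_thresholds({"GH95": 70.0}, {}, {"c1": "GH95"})
        assert ts.cluster_thresholds["c1"] == 70.0

    def test_dangling_family_rejected(self):
        with pytest.raises(KeyError):
            harmonize_thresholds({"GH95": 70.0}, {"c1": 80.0}, {"c1": "GH2"})


class TestCalibratorEstimator:
    def test_fit_produces_consistent_hierarchy_and_f1_one(self, small_bundle):
        calibrator = ThresholdCalibrator().fit(small_bundle)
        assert validate_threshold_hierarchy(calibrator.thresholds_, small_bundle.clusters) == []
        # separable design: every family sweep reaches F1 = 1 on training points
        for row in calibrator.report_.family_rows.values():
            assert row.f1 == 1.0
        # parameter recovery: swept threshold between the cross and within bands
        for fam, thr in calibrator.thresholds_.family_thresholds.items():
            assert 45.0 < thr <= 100.0

    def test_chosen_threshold_is_grid_optimal(self, small_bundle):
        calibrator = ThresholdCalibrator().fit(small_bundle)
        for row in calibrator.report_.family_rows.values():
            table = row.sweep_table
            assert row.f1 == table["f1"].max()
            top = table[table["f1"] == table["f1"].max()]
            assert row.threshold == top["threshold"].max()

    def test_report_written_as_tsvs(self, small_bundle, tmp_path):
        calibrator = ThresholdCalibrator().fit(small_bundle)
        calibrator.write_report(tmp_path)
        assert (tmp_path / "calibration_families.tsv").exists()
        assert (tmp_path / "calibration_clusters.tsv").exists()
        assert (tmp_path / "calibration_sweep.tsv").exists()
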