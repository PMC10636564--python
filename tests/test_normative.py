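"""Normative maps, contact assignment and abnormality Z-scoring."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from abnmap import (NormativeMap, NormativeZScore, Parcellation,
                    abnormality_map, aggregate_contacts_to_rois,
                    assign_contacts, build_normative_map,
                    synthetic_parcellation)
from abnmap.bands import BAND_NAMES

BANDS = list(BAND_NAMES)


def bp_table(rows, index=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if index is None:
        index = [f"roi{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=pd.Index(index, name="roi"), columns=BANDS)


class TestBuildNormativeMap:
    def test_two_controls_closed_form(self):
        tables = {
            "c1": bp_table([[0.2, 0.2, 0.2, 0.2, 0.2]], ["roiA"]),
            "c2": bp_table([[0.4, 0.15, 0.15, 0.15, 0.15]], ["roiA"]),
        }
        norm = build_normative_map(tables)
        assert norm.mean.loc["roiA", "delta"] == pytest.approx(0.3)
        # sample SD convention (n-1 denominator)
        assert norm.sd.loc["roiA", "delta"] == pytest.approx(
            np.std([0.2, 0.4], ddof=1))
        assert norm.sd.loc["roiA", "delta"] == pytest.approx(0.141421356, abs=1e-8)
        assert norm.n.loc["roiA", "delta"] == 2

    def test_identical_controls_sd_floored(self, caplog):
        row = [0.3, 0.25, 0.2, 0.15, 0.1]
        tables = {f"c{i}": bp_table([row], ["roiA"]) for i in range(5)}
        with caplog.at_level("WARNING", logger="abnmap.normative"):
            norm = build_normative_map(tables)
        assert "degenerate" in caplog.text
        np.testing.assert_allclose(norm.sd.loc["roiA"].to_numpy(),
                                   1e-6 * np.asarray(row))

    def test_within_subject_contact_average(self):
        # a subject with two contacts in one region contributes their mean
        tables = {
            "c1": bp_table([[0.1, 0.3, 0.2, 0.2, 0.2],
                            [0.3, 0.1, 0.2, 0.2, 0.2]], ["k1", "k2"]),
            "c2": bp_table([[0.4, 0.2, 0.2, 0.1, 0.1]], ["k3"]),
        }
        norm = build_normative_map(
            tables, roi_of_entity={"k1": "roiA", "k2": "roiA", "k3": "roiA"})
        assert norm.mean.loc["roiA", "delta"] == pytest.approx(
            np.mean([0.2, 0.4]))
        assert norm.n.loc["roiA", "delta"] == 2

    def test_single_contributor_excluded(self):
        tables = {
            "c1": bp_table([[0.2] * 5, [0.2] * 5], ["roiA", "roiB"]),
            "c2": bp_table([[0.25, 0.25, 0.2, 0.15, 0.15]], ["roiA"]),
        }
        norm = build_normative_map(tables)
        assert np.isnan(norm.sd.loc["roiB", "delta"])
        assert norm.n.loc["roiB", "delta"] == 1
        assert norm.n.loc["roiA", "delta"] == 2

    def test_tidy_round_trip(self, small_report):
        norm = small_report["meg_norm"]
        back = NormativeMap.from_tidy(norm.to_tidy(), norm.modality)
        pd.testing.assert_frame_equal(back.mean, norm.mean)
        pd.testing.assert_frame_equal(back.sd, norm.sd)


class TestAbnormalityMap:
    def test_single_band_z(self):
        norm = build_normative_map({
            "c1": bp_table([[0.15, 0.25, 0.2, 0.2, 0.2]], ["roiA"]),
            "c2": bp_table([[0.25, 0.15, 0.2, 0.2, 0.2]], ["roiA"]),
        })
        # mean 0.2, sample SD 0.0707...; patient at 0.3 -> z = 0.1/sd
        patient = bp_table([[0.3, 0.2, 0.2, 0.15, 0.15]], ["roiA"])
        abn = abnormality_map(patient, norm)
        assert abn.loc["roiA", "delta"] == pytest.approx(
            0.1 / np.std([0.15, 0.25], ddof=1))

    def test_mean_sd_fixture_z(self):
        tidy = pd.DataFrame({"roi": ["roiA"] * 5, "band": BANDS,
                             "mean": [0.2] * 5, "sd": [0.05] * 5,
                             "n": [10] * 5})
        norm = NormativeMap.from_tidy(tidy, "MEG")
        patient = bp_table([[0.3, 0.2, 0.2, 0.2, 0.2]], ["roiA"])
        abn = abnormality_map(patient, norm)
        assert abn.loc["roiA", "delta"] == pytest.approx(2.0)
        assert abn.loc["roiA", "max_abs_z"] == pytest.approx(2.0)

    def test_max_abs_z_is_max_over_bands(self):
        tidy = pd.DataFrame({"roi": ["r"] * 5, "band": BANDS,
                             "mean": [0.0] * 5, "sd": [1.0] * 5, "n": [5] * 5})
        norm = NormativeMap.from_tidy(tidy, "MEG")
        patient = bp_table([[1.0, -3.0, 2.0, 0.0, 0.5]], ["r"])
        abn = abnormality_map(patient, norm)
        assert abn.loc["r", "max_abs_z"] == pytest.approx(3.0)
        assert abn.loc["r", "theta"] == pytest.approx(-3.0)  # sign retained

    def test_patient_at_normative_mean_is_zero(self, small_cohort,
                                               small_report):
        norm = small_report["meg_norm"]
        patient = norm.mean.copy()
        abn = abnormality_map(patient, norm)
        assert abn["max_abs_z"].abs().max() < 1e-12

    def test_missing_regions_dropped(self, small_report):
        norm = small_report["meg_norm"]
        patient = bp_table([[0.2] * 5, [0.2] * 5],
                           [norm.roi_labels[0], "not_a_region"])
        abn = abnormality_map(patient, norm)
        assert "not_a_region" not in abn.index

    def test_monotone_in_deviation(self, small_report):
        norm = small_report["meg_norm"]
        patient = norm.mean.copy()
        roi = norm.roi_labels[3]
        z_prev = 0.0
        for bump in (0.01, 0.02, 0.05):
            p = patient.copy()
            p.loc[roi, "alpha"] += bump
            z = abnormality_map(p, norm).loc[roi, "max_abs_z"]
            assert z >= z_prev
            z_prev = z


class TestControlSelfNormalization:
    def test_control_z_mean_zero_sd_one(self, small_cohort, small_report):
        norm = small_report["meg_norm"]
        zs = np.stack([abnormality_map(tbl, norm)[BANDS].to_numpy()
                       for tbl in small_cohort.control_meg.values()])
        assert np.abs(zs.mean(axis=0)).max() < 0.05
        assert np.abs(zs.std(axis=0, ddof=1) - 1.0).max() < 0.05


class TestAssignContacts:
    def contacts(self, xyz):
        xyz = np.atleast_2d(xyz)
        return pd.DataFrame(xyz, columns=["x", "y", "z"],
                            index=[f"c{i}" for i in range(len(xyz))])

    def test_contact_at_centroid(self, parcellation):
        out = assign_contacts(self.contacts(parcellation.roi_centroids[7]),
                              parcellation)
        assert out["roi"].iloc[0] == parcellation.roi_labels[7]

    def test_equidistant_tie_breaks_to_earlier_label(self):
        parc = Parcellation(("first", "second"),
                            [[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
        out = assign_contacts(self.contacts([0.0, 0.0, 0.0]), parc)
        assert out["roi"].iloc[0] == "first"

    def test_nearest_by_brute_force(self):
        parc = Parcellation(("a", "b"), [[1.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        out = assign_contacts(self.contacts([0.0, 0.0, 0.0]), parc)
        assert out["roi"].iloc[0] == "a"

    def test_matches_exhaustive_search(self, parcellation, rng):
        pts = rng.uniform(-70, 70, size=(40, 3))
        out = assign_contacts(self.contacts(pts), parcellation)
        for p, got in zip(pts, out["roi"]):
            d = np.linalg.norm(parcellation.roi_centroids - p, axis=1)
            assert got == parcellation.roi_labels[int(np.argmin(d))]

    def test_permutation_and_translation_invariance(self, parcellation, rng):
        pts = rng.uniform(-70, 70, size=(25, 3))
        base = assign_contacts(self.contacts(pts), parcellation)
        perm = rng.permutation(25)
        shuffled = assign_contacts(self.contacts(pts[perm]), parcellation)
        assert list(shuffled["roi"]) == [base["roi"].iloc[i] for i in perm]
        shift = np.array([12.3, -4.5, 100.0])
        moved = Parcellation(parcellation.roi_labels,
                             parcellation.roi_centroids + shift)
        translated = assign_contacts(self.contacts(pts + shift), moved)
        assert list(translated["roi"]) == list(base["roi"])

    def test_empty_parcellation_rejected(self):
        empty = Parcellation((), np.empty((0, 3)))
        with pytest.raises(ValueError, match="empty parcellation"):
            assign_contacts(self.contacts([0.0, 0.0, 0.0]), empty)

    def test_aggregate_requires_columns(self):
        with pytest.raises(ValueError, match="missing columns"):
            aggregate_contacts_to_rois(pd.DataFrame({"roi": ["a"]}))


class TestNormativeZScoreEstimator:
    def test_sklearn_api(self, rng):
        X = rng.normal(size=(20, 6))
        est = NormativeZScore()
        est2 = clone(est).fit(X)
        assert est.get_params()["sd_floor_rel"] == 1e-6
        Z = est2.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_nan_features_excluded(self, rng):
        X = rng.normal(size=(10, 3))
        X[:9, 2] = np.nan  # single contributor
        est = NormativeZScore().fit(X)
        assert est.n_contributors_[2] == 1
        assert np.isnan(est.mean_[2])
        Z = est.transform(X[:1])
        assert np.isnan(Z[0, 2]) and np.isfinite(Z[0, :2]).all()

    def test_synthetic_parcellation_shape(self, parcellation):
        assert parcellation.n_rois == 114
        assert len(set(parcellation.roi_labels)) == 114
        assert np.isfinite(parcellation.roi_centroids).all()
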