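"""Sequence building, encoding, clustering, group naming, gap times,
survival comparisons and the baseline-feature group predictor."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lesiondyn.data_model import DEFAULT_ORGAN_CATALOG
from lesiondyn.sequences import (
    ProgressionGroupClassifier,
    ProgressionSequenceClusterer,
    build_sequences,
    cluster_patients,
    compare_gaps,
    compare_survival,
    dunn_test,
    encode_sequences,
    interprogression_gaps,
    label_groups,
    select_k,
)
from lesiondyn.simulate import simulate_sequence_archetypes


def events_frame(rows):
    """rows: (patient, lesion, organ, prog_time, prog_event)"""
    return pd.DataFrame(
        [
            dict(
                patient_id=p, lesion_id=l, organ=o, lesion_class="target",
                response_time=np.nan, response_event=False,
                progression_time=t, progression_event=e,
            )
            for p, l, o, t, e in rows
        ]
    )


class TestBuildSequences:
    def test_min_per_organ_rule(self):
        ev = events_frame(
            [
                ("P1", "L1", "liver", 140.0, True),
                ("P1", "L2", "liver", 100.0, True),
                ("P1", "L3", "lung", 150.0, True),
            ]
        )
        seq = build_sequences(ev)
        assert seq[["organ", "time", "rank"]].values.tolist() == [
            ["liver", 100.0, 1],
            ["lung", 150.0, 2],
        ]

    def test_no_events_empty(self):
        seq = build_sequences(events_frame([("P1", "L1", "liver", 100.0, False)]))
        assert seq.empty

    def test_same_day_tie_is_lexicographic(self):
        ev = events_frame(
            [("P1", "L1", "lung", 100.0, True), ("P1", "L2", "liver", 100.0, True)]
        )
        seq = build_sequences(ev)
        assert seq["organ"].tolist() == ["liver", "lung"]


class TestEncodeSequences:
    def test_rank_and_sentinel(self):
        seq = pd.DataFrame(
            {"patient_id": ["A", "A"], "organ": ["liver", "lung"], "time": [100.0, 150.0], "rank": [1, 2]}
        )
        X = encode_sequences(seq, ["liver", "lung", "LN"], standardize=False)
        assert X.loc["A"].tolist() == [1.0, 2.0, 3.0]  # sentinel = max rank + 1

    def test_empty_sequence_all_sentinel(self):
        seq = pd.DataFrame(
            {"patient_id": ["A"], "organ": ["liver"], "time": [100.0], "rank": [1]}
        )
        X = encode_sequences(seq, ["liver", "lung"], patient_ids=["A", "B"], standardize=False)
        assert X.loc["B"].tolist() == [2.0, 2.0]

    def test_identical_sequences_identical_rows(self):
        seq = pd.DataFrame(
            {
                "patient_id": ["A", "A", "B", "B"],
                "organ": ["liver", "lung"] * 2,
                "time": [100, 150, 30, 60],
                "rank": [1, 2, 1, 2],
            }
        )
        X = encode_sequences(seq, ["liver", "lung", "LN"])
        assert (X.loc["A"] == X.loc["B"]).all()

    def test_unknown_organ_rejected(self):
        seq = pd.DataFrame({"patient_id": ["A"], "organ": ["gill"], "time": [1.0], "rank": [1]})
        with pytest.raises(ValueError, match="catalog"):
            encode_sequences(seq, ["liver"])


class TestSelectK:
    def test_wss_non_increasing_and_planted_k(self):
        seqs, truth = simulate_sequence_archetypes(400, seed=1)
        X = encode_sequences(seqs, DEFAULT_ORGAN_CATALOG, patient_ids=truth.index)
        metrics, k = select_k(X, range(2, 11))
        wss = metrics["wss"].to_numpy()
        assert (np.diff(wss) <= 1e-6).all()
        assert k == 5

    def test_single_archetype_low_silhouette(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 6))  # one diffuse cloud
        metrics, _ = select_k(X, range(2, 8))
        assert (metrics["silhouette"] < 0.3).all()

    def test_k_range_truncated_to_distinct_rows(self):
        X = np.repeat(np.eye(3), 10, axis=0)
        metrics, _ = select_k(X, range(2, 9))
        assert metrics["k"].max() == 3


class TestClusterPatients:
    def test_duplication_invariance(self):
        seqs, truth = simulate_sequence_archetypes(200, seed=2)
        X = encode_sequences(seqs, DEFAULT_ORGAN_CATALOG, patient_ids=truth.index)
        km1 = cluster_patients(X, 5, seed=0)
        X2 = pd.concat([X, X])
        km2 = cluster_patients(X2, 5, seed=0)
        c1 = np.sort(km1.cluster_centers_, axis=0)
        c2 = np.sort(km2.cluster_centers_, axis=0)
        np.testing.assert_allclose(c1, c2, atol=1e-8)

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            cluster_patients(np.eye(4), 1)

    def test_k_exceeding_distinct_rows_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            cluster_patients(np.repeat(np.eye(2), 5, axis=0), 3)


class TestLabelGroups:
    def test_mono_and_first_organ_rules(self):
        seq = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c", "d", "e", "f"],
                "organ": ["liver", "lung", "liver", "liver", "liver", "LN"],
                "time": [100] * 6,
                "rank": [1] * 6,
            }
        )
        # second organ for d/e/f so they are not mono
        seq2 = pd.DataFrame(
            {
                "patient_id": ["d", "e", "f"],
                "organ": ["lung", "LN", "lung"],
                "time": [200] * 3,
                "rank": [2] * 3,
            }
        )
        seqs = pd.concat([seq, seq2], ignore_index=True)
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=["a", "b", "c", "d", "e", "f"])
        names, comp = label_groups(labels, seqs)
        assert names[0] == "Mono-Organ"  # a, b, c progress in exactly one organ
        assert names[1] == "Liver-First"  # d, e liver-first majority

    def test_planted_cohort_gets_all_five_names(self):
        seqs, truth = simulate_sequence_archetypes(600, seed=3)
        c = ProgressionSequenceClusterer(k=5, organ_catalog=DEFAULT_ORGAN_CATALOG, seed=3)
        c.fit(seqs, patient_ids=truth.index)
        assert set(c.group_names_.values()) == set(truth.unique())
        ari = adjusted_rand_score(truth.reindex(c.patient_groups_.index), c.patient_groups_)
        assert ari >= 0.9


class TestGaps:
    def test_gap_arithmetic(self):
        seq = pd.DataFrame(
            {
                "patient_id": ["A"] * 3,
                "organ": ["liver", "lung", "LN"],
                "time": [100.0, 150.0, 250.0],
                "rank": [1, 2, 3],
            }
        )
        g = interprogression_gaps(seq).iloc[0]
        assert g["gap_1st"] == 100.0
        assert g["gap_2-1"] == 50.0
        assert g["gap_3-2"] == 100.0
        assert g["gap_mean"] == pytest.approx(250.0 / 3)

    def test_single_event_only_first_defined(self):
        seq = pd.DataFrame(
            {"patient_id": ["A"], "organ": ["liver"], "time": [80.0], "rank": [1]}
        )
        g = interprogression_gaps(seq).iloc[0]
        assert g["gap_1st"] == 80.0 and np.isnan(g["gap_2-1"])

    def test_planted_faster_liver_first_gaps(self):
        """Shorter follow-up gaps in the Liver-First group reach Dunn-adjusted
        significance at n ~ 500/group."""
        seqs, truth = simulate_sequence_archetypes(
            2500, seed=4, weights=(0.0, 0.0, 0.34, 0.33, 0.33), liver_first_gap_scale=0.5
        )
        gaps = interprogression_gaps(seqs)
        kw, dunn = compare_gaps(gaps, truth, column="gap_2-1")
        assert kw.pvalue < 0.001
        liver_rows = dunn[(dunn["group1"] == "Liver-First") | (dunn["group2"] == "Liver-First")]
        assert (liver_rows["p_adj"] < 0.05).all()

    def test_dunn_null_is_calibrated(self):
        rng = np.random.default_rng(9)
        vals = pd.Series(rng.standard_normal(300))
        grp = pd.Series(rng.choice(["a", "b", "c"], 300))
        d = dunn_test(vals, grp)
        assert (d["p_adj"] >= d["p"] - 1e-12).all()
        assert (d["p_adj"] > 0.05).all()


def survival_patients(times, events, ids=None):
    ids = ids or [f"P{i}" for i in range(len(times))]
    return pd.DataFrame(
        {"patient_id": ids, "os_time": times, "os_event": events, "pfs_time": times, "pfs_event": events}
    )


class TestCompareSurvival:
    def test_km_matches_hand_product_limit(self):
        # times 1..5, deaths at 1, 2, 4; censored at 3, 5
        pats = survival_patients([1, 2, 3, 4, 5], [True, True, False, True, False])
        groups = pd.Series(["g"] * 5, index=pats["patient_id"])
        out = compare_survival(groups, pats)
        sf = out["km"]["g"].survival_function_.iloc[:, 0]
        assert sf.loc[1.0] == pytest.approx(4 / 5)
        assert sf.loc[2.0] == pytest.approx(4 / 5 * 3 / 4)
        assert sf.loc[4.0] == pytest.approx(4 / 5 * 3 / 4 * 1 / 2)

    def test_all_censored_group_median_not_reached(self):
        pats = survival_patients([100, 200, 300], [False, False, False])
        groups = pd.Series(["g"] * 3, index=pats["patient_id"])
        out = compare_survival(groups, pats)
        assert math.isinf(out["medians"]["g"])

    def test_planted_hazard_ratio_detected(self):
        rng = np.random.default_rng(12)
        hits = 0
        for rep in range(10):
            t1 = rng.exponential(500, 300)
            t2 = rng.exponential(250, 300)
            pats = survival_patients(
                np.concatenate([t1, t2]), [True] * 600,
                ids=[f"P{i}" for i in range(600)],
            )
            groups = pd.Series(["slow"] * 300 + ["fast"] * 300, index=pats["patient_id"])
            out = compare_survival(groups, pats)
            hits += out["logrank_p"] < 0.001
        assert hits >= 9


class TestPredictor:
    def _toy(self, n=300, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {
                "a": rng.standard_normal(n),
                "b": rng.standard_normal(n),
                "cat": rng.choice(["u", "v"], n),
            }
        )
        y = pd.Series(np.where(X["a"] + (X["cat"] == "u") > 0.5, "g1", "g2"))
        flip = rng.random(n) < noise
        y[flip] = np.where(y[flip] == "g1", "g2", "g1")
        return X, y

    def test_duplicated_feature_column_is_inert(self):
        X, y = self._toy()
        c1 = ProgressionGroupClassifier(seed=1, grid={"clf__n_estimators": [50]}).fit(X, y)
        X2 = X.copy()
        X2["a_dup"] = X["a"]
        c2 = ProgressionGroupClassifier(seed=1, grid={"clf__n_estimators": [50]}).fit(X2, y)
        assert c1.macro_auc_ == pytest.approx(c2.macro_auc_, abs=0.02)

    def test_small_class_merged(self, caplog):
        X, y = self._toy(n=200)
        y.iloc[:5] = "rare"
        with caplog.at_level("WARNING"):
            clf = ProgressionGroupClassifier(seed=0, grid={"clf__n_estimators": [50]}).fit(X, y)
        assert "rare" not in clf.classes_
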