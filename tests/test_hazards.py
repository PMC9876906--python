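"""Frailty Cox machinery: Efron oracle equivalence, lifelines cross-check,
planted-effect recovery, covariate screening, phenotype rules."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from lesiondyn.hazards import (
    FrailtyCoxPH,
    _EfronData,
    _efron_loglik_naive,
    classify_phenotypes,
    fit_frailty_cox,
    select_covariates,
    stratified_hazards,
)


def sim_lesion_events(
    seed,
    n_patients=120,
    lesions_per=6,
    beta_organ=None,
    frailty_sd=0.5,
    organs=("abdomen", "liver", "lung", "LN"),
    scale=200.0,
    censor_at=500.0,
    beta_treat=0.0,
):
    """Clustered exponential event times with organ effects and Gaussian frailty."""
    rng = np.random.default_rng(seed)
    n = n_patients * lesions_per
    pid = np.repeat([f"P{i}" for i in range(n_patients)], lesions_per)
    b = np.repeat(frailty_sd * rng.standard_normal(n_patients), lesions_per)
    organ = rng.choice(organs, size=n)
    treat = np.repeat(rng.choice(["TAR+Chemo", "Chemo Alone"], size=n_patients), lesions_per)
    lp = b + np.where(treat == "TAR+Chemo", beta_treat, 0.0)
    for o, coef in (beta_organ or {}).items():
        lp = lp + np.where(organ == o, coef, 0.0)
    T = rng.exponential(scale * np.exp(-lp))
    t = np.minimum(T, censor_at)
    events = pd.DataFrame(
        {
            "patient_id": pid,
            "lesion_id": [f"L{i}" for i in range(n)],
            "organ": organ,
            "lesion_class": "target",
            "response_time": t,
            "response_event": T <= censor_at,
            "progression_time": t,
            "progression_event": T <= censor_at,
        }
    )
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n_patients)],
            "treatment_group": pd.Series(treat).iloc[:: lesions_per].to_numpy(),
            "age": rng.normal(60, 10, n_patients),
        }
    )
    return events, patients


class TestEfronKernel:
    def test_matches_naive_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        n = 150
        Z = rng.standard_normal((n, 3))
        t = np.round(rng.exponential(1.0, n), 1) + 0.1  # heavy ties
        e = rng.random(n) < 0.7
        beta = np.array([0.5, -0.3, 0.1])
        d = _EfronData(t, e, Z)
        ll, g, H = d.loglik_grad_hess(beta)
        assert ll == pytest.approx(_efron_loglik_naive(t, e, Z, beta), rel=1e-10)
        eps = 1e-6
        for i in range(3):
            step = eps * np.eye(3)[i]
            gn = (
                _efron_loglik_naive(t, e, Z, beta + step)
                - _efron_loglik_naive(t, e, Z, beta - step)
            ) / (2 * eps)
            assert g[i] == pytest.approx(gn, rel=1e-4, abs=1e-4)

    def test_hessian_is_negative_definite_direction(self):
        rng = np.random.default_rng(4)
        n = 100
        Z = rng.standard_normal((n, 2))
        t = rng.exponential(1.0, n)
        e = rng.random(n) < 0.8
        _, _, Hn = _EfronData(t, e, Z).loglik_grad_hess(np.array([0.2, -0.1]))
        assert np.all(np.linalg.eigvalsh(Hn) > -1e-8)  # Hn is the NEGATIVE Hessian


class TestAgainstLifelines:
    def test_no_frailty_fit_matches_coxph(self):
        rng = np.random.default_rng(7)
        n = 300
        X = pd.DataFrame({"a": rng.standard_normal(n), "b": (rng.random(n) < 0.5).astype(float)})
        T = rng.exponential(np.exp(-(0.6 * X["a"] - 0.4 * X["b"])))
        C = rng.exponential(2.0, n)
        t, e = np.minimum(T, C), T <= C
        ours = FrailtyCoxPH(theta=0).fit(X, t, e)
        df = X.assign(T=t, E=e.astype(int))
        ll = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(ours.coef_, ll.params_, atol=1e-4)
        np.testing.assert_allclose(ours.se_, ll.standard_errors_, atol=1e-4)

    def test_frailty_free_data_small_loglik_gain(self):
        """On data without frailty, adding the random effect changes the
        log-likelihood by < 2 (median over null replicates)."""
        gains = []
        for seed in range(5):
            ev, pats = sim_lesion_events(seed, n_patients=80, frailty_sd=0.0)
            df = ev.rename(columns={"progression_time": "t", "progression_event": "e"})
            X = pd.DataFrame({"liver": (df["organ"] == "liver").astype(float)})
            plain = FrailtyCoxPH(theta=0).fit(X, df["t"], df["e"])
            fr = FrailtyCoxPH().fit(X, df["t"], df["e"], groups=df["patient_id"])
            gains.append(fr.integrated_loglik_ - plain.partial_loglik_)
        assert np.median(gains) < 2.0


class TestFrailtyCoxRecovery:
    def test_null_cis_cover_one(self):
        ev, pats = sim_lesion_events(11, n_patients=150)
        m = fit_frailty_cox(ev, pats, "progression")
        haz = m.organ_hazards_
        non_ref = haz[haz["organ"] != "abdomen"]
        assert ((non_ref["ci_low"] <= 1.0) & (1.0 <= non_ref["ci_high"])).all()
        ref = haz[haz["organ"] == "abdomen"].iloc[0]
        assert ref.hr == 1.0 and ref.ci_low == 1.0 and ref.ci_high == 1.0

    def test_planted_log_hr_recovered(self):
        covered = in_band = 0
        reps = 5
        for seed in range(reps):
            ev, pats = sim_lesion_events(
                100 + seed, n_patients=250, lesions_per=8, beta_organ={"liver": math.log(2)}
            )
            m = fit_frailty_cox(ev, pats, "progression")
            s = m.organ_hazards_.set_index("organ").loc["liver"]
            covered += s.ci_low <= 2.0 <= s.ci_high
            in_band += 1.7 <= s.hr <= 2.35
        assert covered >= reps - 1
        assert in_band >= reps - 1

    def test_zero_frailty_variance_detected(self):
        thetas = []
        for seed in range(3):
            ev, pats = sim_lesion_events(200 + seed, n_patients=150, frailty_sd=0.0)
            m = fit_frailty_cox(ev, pats, "progression")
            thetas.append(m.frailty_var_)
        assert np.median(thetas) <= 0.01

    def test_zero_event_organ_dropped(self, caplog):
        ev, pats = sim_lesion_events(5, n_patients=60)
        ev.loc[ev["organ"] == "LN", "progression_event"] = False
        with caplog.at_level("WARNING"):
            m = fit_frailty_cox(ev, pats, "progression")
        assert "LN" not in set(m.organ_hazards_["organ"])


class TestSelectCovariates:
    def test_planted_treatment_effect_selected(self):
        ev, pats = sim_lesion_events(31, n_patients=150, beta_treat=-0.8)
        sel = select_covariates(["treatment_group", "age"], ev, pats, "progression")
        assert "treatment_group" in sel

    def test_empty_candidates(self):
        ev, pats = sim_lesion_events(32, n_patients=40)
        assert select_covariates([], ev, pats, "progression") == []

    def test_null_covariate_type_one_error(self):
        """A pure-noise covariate should be selected at roughly the 5% level."""
        hits = 0
        reps = 60
        for seed in range(reps):
            ev, pats = sim_lesion_events(1000 + seed, n_patients=40, lesions_per=4)
            pats["noise"] = np.random.default_rng(seed).standard_normal(len(pats))
            hits += "noise" in select_covariates(["noise"], ev, pats, "progression")
        assert hits / reps < 0.15


class TestPhenotypes:
    def frame(self, endpoint, hrs):
        return pd.DataFrame(
            [dict(organ=o, endpoint=endpoint, hr=h, ci_low=h, ci_high=h, p=0.5) for o, h in hrs.items()]
        )

    def test_liver_like_high_high_and_lung_like_high_low(self):
        resp = self.frame("response", {"abdomen": 1.0, "liver": 1.5, "lung": 1.4, "bone": 0.5})
        prog = self.frame("progression", {"abdomen": 1.0, "liver": 1.6, "lung": 0.6, "bone": 1.8})
        ph = classify_phenotypes(resp, prog).set_index("organ")["phenotype"]
        assert ph["liver"] == "high-high"
        assert ph["lung"] == "high-low"
        assert ph["bone"] == "low-high"

    def test_all_unit_hazards_share_reference_label(self):
        resp = self.frame("response", {"abdomen": 1.0, "liver": 1.0, "lung": 1.0})
        prog = self.frame("progression", {"abdomen": 1.0, "liver": 1.0, "lung": 1.0})
        ph = classify_phenotypes(resp, prog)
        assert ph["phenotype"].nunique() == 1

    def test_reference_labelled_against_median(self):
        # most organs respond less than the reference -> reference is 'high'
        resp = self.frame("response", {"abdomen": 1.0, "a": 0.5, "b": 0.6, "c": 0.7})
        prog = self.frame("progression", {"abdomen": 1.0, "a": 2.0, "b": 1.8, "c": 1.5})
        ph = classify_phenotypes(resp, prog).set_index("organ")["phenotype"]
        assert ph["abdomen"] == "high-low"


class TestStratified:
    def test_interaction_only_in_progression(self):
        """Planted treatment x organ interaction on progression: progression
        HRs differ between strata, response HRs do not."""
        rng = np.random.default_rng(55)
        frames = []
        for stratum, beta_liver_prog in [("TAR+Chemo", 0.0), ("Chemo Alone", math.log(3))]:
            ev, pats = sim_lesion_events(
                int(rng.integers(1e6)), n_patients=200, lesions_per=6,
                beta_organ={"liver": math.log(2)},
            )
            # progression gets an extra stratum-specific liver effect,
            # redrawn from the same organ labels
            lp = np.where(ev["organ"] == "liver", math.log(2) + beta_liver_prog, 0.0)
            T = rng.exponential(200.0 * np.exp(-lp))
            ev["progression_time"] = np.minimum(T, 500.0)
            ev["progression_event"] = T <= 500.0
            ev["patient_id"] = stratum[:3] + ev["patient_id"]
            pats["patient_id"] = stratum[:3] + pats["patient_id"]
            pats["treatment_group"] = stratum
            frames.append((ev, pats))
        events = pd.concat([f[0] for f in frames], ignore_index=True)
        patients = pd.concat([f[1] for f in frames], ignore_index=True)

        prog = stratified_hazards(events, patients, "progression").set_index(["stratum", "organ"])
        resp = stratified_hazards(events, patients, "response").set_index(["stratum", "organ"])
        prog_gap = abs(
            math.log(prog.loc[("Chemo Alone", "liver"), "hr"])
            - math.log(prog.loc[("TAR+Chemo", "liver"), "hr"])
        )
        resp_gap = abs(
            math.log(resp.loc[("Chemo Alone", "liver"), "hr"])
            - math.log(resp.loc[("TAR+Chemo", "liver"), "hr"])
        )
        assert prog_gap > 0.6
        assert resp_gap < 0.4

    def test_single_stratum_with_warning(self, caplog):
        ev, pats = sim_lesion_events(77, n_patients=60)
        pats["treatment_group"] = "Chemo Alone"
        out = stratified_hazards(ev, pats, "progression")
        assert set(out["stratum"]) == {"Chemo Alone"}
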