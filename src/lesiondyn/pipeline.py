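"""End-to-end orchestration: simulate -> fit -> events -> hazards -> cluster
-> predict -> report, with YAML configuration and provenance stamping.

Every stage reads its inputs from and writes its outputs to one artifact
directory as plain CSV/JSON, so stages can be re-run individually and a
full run is reproducible bit-for-bit from the config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_model, events as events_mod, hazards as hazards_mod, sequences as seq_mod
from .population import PopulationEstimate, TumorGrowthMixedModel
from .simulate import CohortConfig, OrganProfile, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "report"]

ALL_STAGES = ("simulate", "fit", "events", "hazards", "cluster", "predict")

DEFAULT_COVARIATE_CANDIDATES = [
    "treatment_group",
    "line_of_therapy",
    "age",
    "gender",
    "race",
    "bmi",
    "prior_surgery",
]


class PipelineError(RuntimeError):
    """A stage failed or its inputs are missing."""


@dataclasses.dataclass
class PipelineConfig:
    """Flat pipeline configuration (one file governs all stages)."""

    outdir: str = "artifacts"
    seed: int = 0
    stages: tuple = ALL_STAGES
    # simulate
    n_patients: int = 300
    # external inputs when simulate is disabled
    measurements_path: str | None = None
    patients_path: str | None = None
    organ_catalog: list = dataclasses.field(default_factory=lambda: list(data_model.DEFAULT_ORGAN_CATALOG))
    # fit
    loq: float = 200.0
    n_explore: int = 300
    n_smooth: int = 200
    pin_v0: bool = False
    # events
    response_fraction: float = 0.20
    progression_rel: float = 0.30
    progression_abs_mm3: float = 200.0
    progression_rule: str = "or"
    # hazards
    reference_organ: str = "abdomen"
    covariate_candidates: list = dataclasses.field(
        default_factory=lambda: list(DEFAULT_COVARIATE_CANDIDATES)
    )
    covariate_alpha: float = 0.05
    stratify_on: str = "treatment_group"
    compute_lrt: bool = True
    # cluster
    k: int | None = 5
    k_range: tuple = (2, 10)
    hetero_threshold: int = 4
    # predict
    min_class_size: int = 10
    predict_grid: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["k_range"] = list(self.k_range)
        return d

    def digest(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _cohort_config(cfg: PipelineConfig) -> CohortConfig:
    return CohortConfig(n_patients=cfg.n_patients, seed=cfg.seed, loq=cfg.loq)


def _need(outdir: Path, name: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise PipelineError(f"required input {name!r} not found in {outdir}; enable the producing stage")
    return p


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the artifact index."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.digest(), "seed": cfg.seed, "stages": list(cfg.stages)}
    (outdir / "provenance.json").write_text(json.dumps(stamp, indent=2))
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    artifacts: dict = {"outdir": str(outdir)}

    measurements = patients = truth = None

    if "simulate" in cfg.stages:
        measurements, patients, truth = simulate_cohort(_cohort_config(cfg))
        data_model.write_measurements(measurements, outdir / "measurements.csv")
        data_model.write_patients(patients, outdir / "patients.csv")
        truth.lesions.to_csv(outdir / "truth_lesions.csv", index=False)
        truth.patients.to_csv(outdir / "truth_patients.csv", index=False)
        truth.sequences.to_csv(outdir / "truth_sequences.csv", index=False)
        logger.info("simulated %d patients / %d lesions", len(patients), len(truth.lesions))

    def _measurements():
        nonlocal measurements
        if measurements is None:
            path = cfg.measurements_path or _need(outdir, "measurements.csv")
            measurements = data_model.load_measurements(path, organ_catalog=cfg.organ_catalog)
        return measurements

    def _patients():
        nonlocal patients
        if patients is None:
            path = cfg.patients_path or _need(outdir, "patients.csv")
            patients = data_model.load_patients(path)
        return patients

    if "fit" in cfg.stages:
        model = TumorGrowthMixedModel(
            loq=cfg.loq,
            n_explore=cfg.n_explore,
            n_smooth=cfg.n_smooth,
            seed=cfg.seed,
            pin_v0=cfg.pin_v0,
            compute_loglik=False,
        ).fit(_measurements())
        est = model.population_estimate()
        (outdir / "population_estimate.json").write_text(
            json.dumps(
                {
                    "theta_kg": est.theta_kg,
                    "theta_kd": est.theta_kd,
                    "theta_f": est.theta_f,
                    "omega_kg": est.omega[0],
                    "omega_kd": est.omega[1],
                    "omega_f": est.omega[2],
                    "sigma": est.sigma,
                    "convergence": est.convergence,
                },
                indent=2,
                default=str,
            )
        )
        model.lesion_params_.to_csv(outdir / "lesion_params.csv", index=False)
        artifacts["population"] = est

    if "events" in cfg.stages:
        fits = pd.read_csv(_need(outdir, "lesion_params.csv"))
        pats = _patients()
        last_day = pats.set_index("patient_id")["os_time"]
        ev = events_mod.derive_all_events(
            fits,
            _measurements(),
            last_day,
            response_fraction=cfg.response_fraction,
            rel=cfg.progression_rel,
            abs_mm3=cfg.progression_abs_mm3,
            rule=cfg.progression_rule,
        )
        ev.to_csv(outdir / "lesion_events.csv", index=False)
        artifacts["events"] = ev

    if "hazards" in cfg.stages:
        ev = pd.read_csv(_need(outdir, "lesion_events.csv"))
        pats = _patients()
        haz_frames, phen_inputs = [], {}
        for endpoint in ("response", "progression"):
            selected = hazards_mod.select_covariates(
                cfg.covariate_candidates, ev, pats, endpoint,
                alpha=cfg.covariate_alpha, reference_organ=cfg.reference_organ,
            )
            logger.info("%s covariates selected: %s", endpoint, selected)
            m = hazards_mod.fit_frailty_cox(
                ev, pats, endpoint,
                covariates=selected,
                reference_organ=cfg.reference_organ,
                compute_lrt=cfg.compute_lrt,
            )
            haz = m.organ_hazards_.copy()
            haz["stratum"] = "all"
            haz["frailty_var"] = m.frailty_var_
            haz["covariates"] = ",".join(selected)
            haz_frames.append(haz)
            phen_inputs[endpoint] = m.organ_hazards_
            try:
                strat = hazards_mod.stratified_hazards(
                    ev, pats, endpoint,
                    stratum_col=cfg.stratify_on, reference_organ=cfg.reference_organ,
                )
                haz_frames.append(strat)
            except ValueError as err:
                logger.warning("stratified %s hazards skipped: %s", endpoint, err)
        organ_hazards = pd.concat(haz_frames, ignore_index=True)
        organ_hazards.to_csv(outdir / "organ_hazards.csv", index=False)
        phen = hazards_mod.classify_phenotypes(phen_inputs["response"], phen_inputs["progression"])
        phen.to_csv(outdir / "phenotypes.csv", index=False)
        artifacts["organ_hazards"] = organ_hazards
        artifacts["phenotypes"] = phen

    if "cluster" in cfg.stages:
        ev = pd.read_csv(_need(outdir, "lesion_events.csv"))
        pats = _patients()
        seqs = seq_mod.build_sequences(ev)
        seqs.to_csv(outdir / "sequences.csv", index=False)
        clus = seq_mod.ProgressionSequenceClusterer(
            k=cfg.k,
            k_range=cfg.k_range,
            organ_catalog=cfg.organ_catalog,
            seed=cfg.seed,
            hetero_threshold=cfg.hetero_threshold,
        ).fit(seqs, patient_ids=pats["patient_id"])
        out = pd.DataFrame(
            {
                "patient_id": clus.labels_.index,
                "cluster": clus.labels_.to_numpy(),
                "group": clus.patient_groups_.to_numpy(),
            }
        )
        out.to_csv(outdir / "clusters.csv", index=False)
        if clus.metrics_ is not None:
            clus.metrics_.to_csv(outdir / "cluster_metrics.csv", index=False)
        # composition heatmap table: log10(n + 1) of first-progressing organ per group
        firsts = seqs[seqs["rank"] == 1].set_index("patient_id")["organ"]
        comp = (
            pd.crosstab(clus.patient_groups_, firsts.reindex(clus.patient_groups_.index).fillna("none"))
            .apply(lambda c: np.log10(c + 1.0))
            .round(4)
        )
        comp.to_csv(outdir / "cluster_composition.csv")

        surv = seq_mod.compare_survival(clus.patient_groups_, pats)
        curves = []
        for name, km in surv["km"].items():
            sf = km.survival_function_
            curves.append(
                pd.DataFrame(
                    {"group": name, "time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
                )
            )
        pd.concat(curves, ignore_index=True).to_csv(outdir / "km_curves.csv", index=False)
        med = pd.DataFrame(
            {
                "group": list(surv["medians"]),
                "median_os": [surv["medians"][g] for g in surv["medians"]],
                "n": [surv["sizes"].get(g, 0) for g in surv["medians"]],
            }
        )
        med["logrank_p_overall"] = surv["logrank_p"]
        med.to_csv(outdir / "km_medians.csv", index=False)

        gaps = seq_mod.interprogression_gaps(seqs)
        gaps.to_csv(outdir / "gap_times.csv", index=False)
        gap_stats = []
        first_groups = clus.patient_groups_[
            clus.patient_groups_.str.contains("First", na=False)
        ]
        if first_groups.nunique() > 1:
            for col in [c for c in gaps.columns if c.startswith("gap")]:
                kw, dunn = seq_mod.compare_gaps(gaps, first_groups, column=col)
                if kw is not None:
                    for r in dunn.itertuples():
                        gap_stats.append(
                            dict(column=col, kruskal_p=kw.pvalue, group1=r.group1,
                                 group2=r.group2, dunn_p_adj=r.p_adj)
                        )
        pd.DataFrame(gap_stats).to_csv(outdir / "gap_stats.csv", index=False)
        artifacts["clusters"] = out
        artifacts["survival"] = surv

    if "predict" in cfg.stages:
        clusters = pd.read_csv(_need(outdir, "clusters.csv"))
        feats = seq_mod.baseline_features(_measurements(), _patients(), organ_catalog=cfg.organ_catalog)
        labels = clusters.set_index("patient_id")["group"]
        clf = seq_mod.predict_progression_group(
            feats, labels, seed=cfg.seed, min_class_size=cfg.min_class_size, grid=cfg.predict_grid
        )
        rep = clf.cv_report_.copy()
        rep["macro_auc_pooled"] = clf.macro_auc_
        rep["best_params"] = [str(p) for p in clf.best_params_]
        rep.to_csv(outdir / "classifier_report.csv", index=False)
        artifacts["classifier"] = clf

    return artifacts


# ---------------------------------------------------------------------------
# report


def _section(lines, title):
    lines.append(f"\n## {title}\n")


def report(artifact_dir) -> str:
    """Human-readable summary assembled from the artifact directory."""
    outdir = Path(artifact_dir)
    if not outdir.exists() or not any(outdir.iterdir()):
        raise PipelineError(f"artifact directory {outdir} is empty or missing")
    lines = ["# Lesion dynamics pipeline report"]
    prov = outdir / "provenance.json"
    if prov.exists():
        meta = json.loads(prov.read_text())
        lines.append(f"\nconfig hash `{meta['config_hash']}`, seed {meta['seed']}")

    pe = outdir / "population_estimate.json"
    _section(lines, "Population growth parameters")
    if pe.exists():
        est = json.loads(pe.read_text())
        lines.append(
            f"theta_Kg = {est['theta_kg']:.4g} /day, theta_Kd = {est['theta_kd']:.4g} /day, "
            f"theta_F = {est['theta_f']:.3f}; omega = ({est['omega_kg']:.2f}, "
            f"{est['omega_kd']:.2f}, {est['omega_f']:.2f}); sigma = {est['sigma']:.3f}"
        )
    else:
        lines.append("_absent_")

    _section(lines, "Organ hazard ratios")
    oh = outdir / "organ_hazards.csv"
    if oh.exists():
        df = pd.read_csv(oh)
        top = df[df["stratum"] == "all"]
        lines.append(top.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    else:
        lines.append("_absent_")

    _section(lines, "Organ phenotypes")
    ph = outdir / "phenotypes.csv"
    lines.append(pd.read_csv(ph).to_string(index=False) if ph.exists() else "_absent_")

    _section(lines, "Progression-sequence clusters")
    cl = outdir / "clusters.csv"
    if cl.exists():
        counts = pd.read_csv(cl)["group"].value_counts()
        lines.append(counts.to_string())
        comp = outdir / "cluster_composition.csv"
        if comp.exists():
            lines.append("\ncomposition (log10 patients + 1):\n" + pd.read_csv(comp).to_string(index=False))
    else:
        lines.append("_absent_")

    _section(lines, "Survival by group")
    km = outdir / "km_medians.csv"
    lines.append(pd.read_csv(km).to_string(index=False) if km.exists() else "_absent_")

    _section(lines, "Inter-progression gap times")
    gp = outdir / "gap_stats.csv"
    if gp.exists():
        df = pd.read_csv(gp)
        lines.append(df.to_string(index=False) if len(df) else "no multi-group contrasts available")
    else:
        lines.append("_absent_")

    _section(lines, "Progression-group prediction")
    cr = outdir / "classifier_report.csv"
    lines.append(pd.read_csv(cr).to_string(index=False) if cr.exists() else "_absent_")

    text = "\n".join(lines) + "\n"
    (outdir / "report.md").write_text(text)
    return text
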