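"""Organ progression sequences: construction, clustering, survival links.

A patient's progression sequence is the time-ordered list of organs in
which any lesion (target, non-target or new) first progressed.  Sequences
are embedded as per-organ progression ranks (sentinel rank for organs that
never progress), clustered with k-means, and the clusters are named after
the clinical grouping: Mono-Organ, Hetero-Organ, Liver-First, Lung-First,
Other-First.  Survival across groups is compared with Kaplan-Meier /
log-rank machinery, inter-progression gap times with Kruskal-Wallis and
Dunn's multiple-comparison adjustment, and a gradient-boosting classifier
predicts the group from baseline characteristics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score, silhouette_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "GROUP_NAMES",
    "build_sequences",
    "encode_sequences",
    "select_k",
    "cluster_patients",
    "ProgressionSequenceClusterer",
    "label_groups",
    "interprogression_gaps",
    "dunn_test",
    "compare_survival",
    "predict_progression_group",
    "ProgressionGroupClassifier",
]

GROUP_NAMES = ("Mono-Organ", "Hetero-Organ", "Liver-First", "Lung-First", "Other-First")


# ---------------------------------------------------------------------------
# sequence construction and encoding


def build_sequences(events: pd.DataFrame) -> pd.DataFrame:
    """Per-patient organ-level first-progression sequences (long format).

    The organ's progression time is the earliest progression event among
    its lesions of any class.  Ties on the same day are broken
    lexicographically by organ name (deterministic, logged).
    """
    prog = events[events["progression_event"].astype(bool)]
    if prog.empty:
        return pd.DataFrame(columns=["patient_id", "organ", "time", "rank"])
    first = (
        prog.groupby(["patient_id", "organ"])["progression_time"].min().reset_index(name="time")
    )
    ties = first.duplicated(subset=["patient_id", "time"], keep=False)
    if ties.any():
        logger.info(
            "breaking %d same-day organ progression ties lexicographically", int(ties.sum() / 2)
        )
    first = first.sort_values(["patient_id", "time", "organ"], kind="mergesort")
    first["rank"] = first.groupby("patient_id").cumcount() + 1
    return first.reset_index(drop=True)


def encode_sequences(
    sequences: pd.DataFrame,
    organ_catalog: list,
    patient_ids=None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Rank-based sequence embedding: one column per organ.

    The organ's coordinate is its progression rank (1 = first); organs that
    never progress get a sentinel rank of (max observed rank + 1).  Columns
    are standardized so no single organ dominates the metric.  ``patient_ids``
    fixes the row universe (patients with no progression get all-sentinel
    rows).
    """
    unknown = set(sequences["organ"]) - set(organ_catalog)
    if unknown:
        raise ValueError(f"organs outside catalog: {sorted(unknown)}")
    if patient_ids is None:
        patient_ids = sequences["patient_id"].unique()
    sentinel = float(sequences["rank"].max() + 1) if len(sequences) else 1.0
    wide = (
        sequences.pivot_table(index="patient_id", columns="organ", values="rank", aggfunc="min")
        .reindex(index=patient_ids, columns=organ_catalog)
        .fillna(sentinel)
        .astype(float)
    )
    wide.columns.name = None
    if standardize:
        sd = wide.std(ddof=0).replace(0.0, 1.0)
        wide = (wide - wide.mean()) / sd
    return wide


# ---------------------------------------------------------------------------
# k selection and clustering


def select_k(features: pd.DataFrame, k_range=range(2, 11), n_seeds: int = 10, seed: int = 0):
    """Per-k clustering metrics: WSS (elbow), silhouette, AIC, BIC.

    AIC = WSS + 2 k d and BIC = WSS + ln(n) k d with d the feature
    dimension.  The recommendation is the silhouette argmax; all four
    metrics are reported for human adjudication (survival separation is
    judged outside this function).
    """
    X = np.asarray(features, float)
    n, d = X.shape
    n_distinct = len(np.unique(X, axis=0))
    rows = []
    for k in k_range:
        if k > n_distinct:
            logger.warning("k=%d exceeds %d distinct rows; truncating k range", k, n_distinct)
            break
        km = KMeans(n_clusters=k, n_init=n_seeds, random_state=seed).fit(X)
        wss = float(km.inertia_)
        sil = float(silhouette_score(X, km.labels_)) if k > 1 else np.nan
        rows.append(
            dict(k=k, wss=wss, silhouette=sil, aic=wss + 2.0 * k * d, bic=wss + np.log(n) * k * d)
        )
    metrics = pd.DataFrame(rows)
    recommended = int(metrics.loc[metrics["silhouette"].idxmax(), "k"])
    return metrics, recommended


def cluster_patients(features: pd.DataFrame, k: int, seed: int = 0, n_init: int = 25) -> KMeans:
    """k-means with multiple restarts; deterministic given seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(features, float)
    if k > len(np.unique(X, axis=0)):
        raise ValueError("k exceeds the number of distinct feature rows")
    return KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)


class ProgressionSequenceClusterer(BaseEstimator):
    """Sequence embedding + k-means + clinical group naming (sklearn-style).

    Parameters
    ----------
    k : int or None
        Number of clusters; None selects k by silhouette over ``k_range``.
    organ_catalog : list
        Organ universe for the rank embedding.
    hetero_threshold : int
        Minimum progressing-organ count for the Hetero-Organ label.

    Attributes
    ----------
    k_, labels_, group_names_, metrics_, features_, composition_
    """

    def __init__(self, k=None, k_range=(2, 10), organ_catalog=None, seed=0,
                 n_init=25, hetero_threshold=4):
        self.k = k
        self.k_range = k_range
        self.organ_catalog = organ_catalog
        self.seed = seed
        self.n_init = n_init
        self.hetero_threshold = hetero_threshold

    def fit(self, sequences: pd.DataFrame, patient_ids=None):
        catalog = self.organ_catalog or sorted(sequences["organ"].unique())
        feats = encode_sequences(sequences, catalog, patient_ids=patient_ids)
        if self.k is None:
            lo, hi = self.k_range
            self.metrics_, k = select_k(feats, range(lo, hi + 1), seed=self.seed)
        else:
            k = self.k
            self.metrics_ = None
        km = cluster_patients(feats, k, seed=self.seed, n_init=self.n_init)
        self.k_ = k
        self.features_ = feats
        self.kmeans_ = km
        self.labels_ = pd.Series(km.labels_, index=feats.index, name="cluster")
        self.group_names_, self.composition_ = label_groups(
            self.labels_, sequences, hetero_threshold=self.hetero_threshold
        )
        self.patient_groups_ = self.labels_.map(self.group_names_).rename("group")
        return self

    def fit_predict(self, sequences, patient_ids=None):
        return self.fit(sequences, patient_ids=patient_ids).patient_groups_


def label_groups(labels: pd.Series, sequences: pd.DataFrame, hetero_threshold: int = 4):
    """Name clusters by majority composition.

    Mono-Organ if the majority of members progress in exactly one organ;
    Hetero-Organ if the majority progress in >= ``hetero_threshold``
    organs; otherwise Liver-First / Lung-First / Other-First by the
    modal (most common) first-progressing organ among members.  Ties
    follow the deterministic preference order Mono, Hetero, Liver-First,
    Lung-First, Other-First.  Duplicate names get a numeric suffix so the
    result is a partition.
    """
    nprog = sequences.groupby("patient_id").size()
    firsts = sequences[sequences["rank"] == 1].set_index("patient_id")["organ"]
    names, comp = {}, {}
    for cl, members in labels.groupby(labels):
        pids = members.index
        n = len(pids)
        frac_mono = float((nprog.reindex(pids).fillna(0) == 1).mean())
        frac_hetero = float((nprog.reindex(pids).fillna(0) >= hetero_threshold).mean())
        f = firsts.reindex(pids).dropna()
        frac_liver = float((f == "liver").mean()) if len(f) else 0.0
        frac_lung = float((f == "lung").mean()) if len(f) else 0.0
        frac_other = float(((f != "liver") & (f != "lung")).mean()) if len(f) else 0.0
        if frac_mono > 0.5:
            name = "Mono-Organ"
        elif frac_hetero > 0.5:
            name = "Hetero-Organ"
        elif len(f) == 0:
            name = "Other-First"
        else:
            counts = f.value_counts()
            modal = sorted(
                counts[counts == counts.max()].index,
                key=lambda o: (o != "liver", o != "lung", o),
            )[0]
            name = {"liver": "Liver-First", "lung": "Lung-First"}.get(modal, "Other-First")
        comp[cl] = dict(
            n=n, frac_mono=frac_mono, frac_hetero=frac_hetero,
            frac_liver_first=frac_liver, frac_lung_first=frac_lung, frac_other_first=frac_other,
        )
        names[cl] = name
    # enforce a partition: deduplicate names deterministically
    seen: dict[str, int] = {}
    for cl in sorted(names, key=lambda c: -comp[c]["n"]):
        base = names[cl]
        if base in seen:
            seen[base] += 1
            names[cl] = f"{base}-{seen[base]}"
        else:
            seen[base] = 1
    logger.info("cluster names: %s", names)
    return names, pd.DataFrame(comp).T


# ---------------------------------------------------------------------------
# gap times and statistics


def interprogression_gaps(sequences: pd.DataFrame, max_order: int = 4) -> pd.DataFrame:
    """Per-patient gap table: 1st progression time, 2nd-1st, ..., mean gap."""
    out = []
    for pid, grp in sequences.sort_values("rank").groupby("patient_id"):
        t = grp["time"].to_numpy(float)
        row = {"patient_id": pid}
        gaps = []
        for i in range(min(len(t), max_order)):
            g = t[i] - t[i - 1] if i else t[0]
            row["gap_1st" if i == 0 else f"gap_{i + 1}-{i}"] = g
            gaps.append(g)
        row["gap_mean"] = float(np.mean(gaps)) if gaps else np.nan
        out.append(row)
    cols = ["patient_id", "gap_1st"] + [f"gap_{i + 1}-{i}" for i in range(1, max_order)] + ["gap_mean"]
    return pd.DataFrame(out).reindex(columns=cols)


def dunn_test(values: pd.Series, groups: pd.Series, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based multiple-comparison test after Kruskal-Wallis.

    Pairwise z statistics on mean ranks with tie correction; two-sided
    p-values Bonferroni-adjusted over the comparison family.
    """
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    ranks = stats.rankdata(df["v"])
    n = len(df)
    ties = pd.Series(df["v"]).value_counts()
    tie_corr = float(((ties**3 - ties).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    levels = sorted(df["g"].unique())
    mean_rank = {g: ranks[(df["g"] == g).to_numpy()].mean() for g in levels}
    size = {g: int((df["g"] == g).sum()) for g in levels}
    m = len(levels) * (len(levels) - 1) // 2
    rows = []
    for i, gi in enumerate(levels):
        for gj in levels[i + 1:]:
            se = np.sqrt((n * (n + 1) / 12.0 - tie_corr) * (1.0 / size[gi] + 1.0 / size[gj]))
            z = (mean_rank[gi] - mean_rank[gj]) / se if se > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z))
            p_adj = min(p * m, 1.0) if adjust == "bonferroni" else p
            rows.append(dict(group1=gi, group2=gj, z=z, p=p, p_adj=p_adj))
    return pd.DataFrame(rows)


def compare_gaps(gaps: pd.DataFrame, groups: pd.Series, column: str = "gap_1st"):
    """Kruskal-Wallis across groups on one gap column, plus Dunn pairs."""
    df = gaps.set_index("patient_id")
    g = groups.reindex(df.index)
    mask = df[column].notna() & g.notna()
    vals, lab = df.loc[mask, column], g[mask]
    arrays = [vals[lab == lev].to_numpy() for lev in sorted(lab.unique())]
    kw = stats.kruskal(*arrays) if len(arrays) > 1 else None
    return kw, dunn_test(vals, lab)


# ---------------------------------------------------------------------------
# survival comparisons


def compare_survival(groups: pd.Series, patients: pd.DataFrame) -> dict:
    """KM estimates, medians, overall and pairwise log-rank across groups."""
    df = patients.set_index("patient_id").join(groups.rename("group"), how="inner")
    df = df[df["group"].notna()]
    sizes = df.groupby("group").size()
    empty = sizes[sizes == 0].index
    if len(empty):
        df = df[~df["group"].isin(empty)]
    km, medians = {}, {}
    for name, sub in df.groupby("group"):
        f = KaplanMeierFitter(label=str(name)).fit(sub["os_time"], sub["os_event"])
        km[name] = f
        medians[name] = float(f.median_survival_time_)
    overall = multivariate_logrank_test(df["os_time"], df["group"], df["os_event"])
    pairwise = {}
    names = sorted(km)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            da, db = df[df["group"] == a], df[df["group"] == b]
            r = logrank_test(da["os_time"], db["os_time"], da["os_event"], db["os_event"])
            pairwise[(a, b)] = float(r.p_value)
    return {
        "km": km,
        "medians": medians,
        "logrank_p": float(overall.p_value),
        "pairwise_p": pairwise,
        "sizes": sizes.to_dict(),
    }


# ---------------------------------------------------------------------------
# baseline-feature progression-group prediction


class ProgressionGroupClassifier(BaseEstimator):
    """Gradient-boosting prediction of the progression group from baseline.

    Continuous predictors are standardized, categorical ones one-hot
    encoded; hyperparameters come from an F1-macro grid search with 5-fold
    CV inside each of 5 outer folds (a 4:1 split with test-set rotation).
    Classes with fewer than ``min_class_size`` members are merged into the
    nearest group by feature centroid.

    Attributes
    ----------
    cv_report_ : per-fold test metrics (accuracy, macro F1, macro AUC)
    macro_auc_ : pooled one-vs-rest macro AUC over the outer test folds
    best_params_ : grid choices per outer fold
    model_ : pipeline refitted on all data with the modal grid choice
    """

    DEFAULT_GRID = {"clf__n_estimators": [100], "clf__max_depth": [2, 3], "clf__learning_rate": [0.1]}

    def __init__(self, grid=None, seed=0, min_class_size=10, n_outer=5, n_inner=5):
        self.grid = grid
        self.seed = seed
        self.min_class_size = min_class_size
        self.n_outer = n_outer
        self.n_inner = n_inner

    def _pipeline(self, X):
        num = [c for c in X.columns if pd.api.types.is_numeric_dtype(X[c]) and X[c].dtype != bool]
        cat = [c for c in X.columns if c not in num]
        pre = ColumnTransformer(
            [
                ("num", StandardScaler(), num),
                ("cat", OneHotEncoder(handle_unknown="ignore"), cat),
            ]
        )
        return Pipeline([("pre", pre), ("clf", GradientBoostingClassifier(random_state=self.seed))])

    def _merge_small(self, X, y):
        y = y.copy()
        counts = y.value_counts()
        small = counts[counts < self.min_class_size].index
        if not len(small):
            return y
        Xn = pd.get_dummies(X).astype(float)
        Xn = (Xn - Xn.mean()) / Xn.std(ddof=0).replace(0, 1)
        cents = Xn.groupby(y).mean()
        for cls in small:
            others = cents.drop(index=list(small), errors="ignore")
            if others.empty:
                continue
            dist = ((others - cents.loc[cls]) ** 2).sum(axis=1)
            target = dist.idxmin()
            logger.warning("merging class %r (n=%d) into nearest group %r", cls, counts[cls], target)
            y[y == cls] = target
        return y

    def fit(self, X: pd.DataFrame, y: pd.Series):
        X = X.reset_index(drop=True)
        y = pd.Series(y).reset_index(drop=True)
        y = self._merge_small(X, y)
        classes = np.array(sorted(y.unique()))
        grid = self.grid or self.DEFAULT_GRID
        outer = StratifiedKFold(n_splits=self.n_outer, shuffle=True, random_state=self.seed)
        rows, probs, truths, params = [], [], [], []
        for fold, (tr, te) in enumerate(outer.split(X, y)):
            gs = GridSearchCV(
                self._pipeline(X),
                grid,
                scoring="f1_macro",
                cv=StratifiedKFold(self.n_inner, shuffle=True, random_state=self.seed + fold),
                n_jobs=1,
            )
            gs.fit(X.iloc[tr], y.iloc[tr])
            proba = gs.predict_proba(X.iloc[te])
            pred = gs.predict(X.iloc[te])
            order = [list(gs.classes_).index(c) for c in classes]
            probs.append(proba[:, order])
            truths.append(y.iloc[te].to_numpy())
            params.append(gs.best_params_)
            from sklearn.metrics import accuracy_score, f1_score

            rows.append(
                dict(
                    fold=fold,
                    accuracy=accuracy_score(y.iloc[te], pred),
                    f1_macro=f1_score(y.iloc[te], pred, average="macro"),
                )
            )
        P = np.vstack(probs)
        T = np.concatenate(truths)
        if len(classes) > 2:
            self.macro_auc_ = float(
                roc_auc_score(T, P, multi_class="ovr", average="macro", labels=classes)
            )
        else:
            self.macro_auc_ = float(roc_auc_score((T == classes[1]).astype(int), P[:, 1]))
        self.cv_report_ = pd.DataFrame(rows)
        self.best_params_ = params
        self.classes_ = classes
        # final refit on everything with the modal grid choice
        modal = pd.Series([str(p) for p in params]).mode()[0]
        chosen = params[[str(p) for p in params].index(modal)]
        pipe = self._pipeline(X)
        pipe.set_params(**chosen)
        self.model_ = pipe.fit(X, y)
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def predict_proba(self, X):
        return self.model_.predict_proba(X)


def baseline_features(measurements: pd.DataFrame, patients: pd.DataFrame, organ_catalog=None) -> pd.DataFrame:
    """Baseline feature table: demographics + metastatic profile.

    Profile features per the clinical setup: organs involved (binary),
    metastatic lesion count, and total baseline target volume.
    """
    catalog = organ_catalog or sorted(measurements["organ"].unique())
    first_obs = measurements.sort_values("time").groupby(["patient_id", "lesion_id"]).first().reset_index()
    base = first_obs[first_obs["lesion_class"] != "new"]
    involved = (
        base.assign(flag=1.0)
        .pivot_table(index="patient_id", columns="organ", values="flag", aggfunc="max")
        .reindex(columns=catalog)
        .fillna(0.0)
        .add_prefix("organ_")
    )
    counts = base.groupby("patient_id").size().rename("n_lesions")
    tvol = (
        base[base["lesion_class"] == "target"]
        .groupby("patient_id")["volume"]
        .sum(min_count=1)
        .rename("baseline_target_volume")
    )
    demo = patients.set_index("patient_id")[
        [c for c in ("age", "gender", "race", "bmi", "prior_surgery", "line_of_therapy", "treatment_group") if c in patients.columns]
    ]
    X = demo.join([involved, counts, tvol])
    X["n_lesions"] = X["n_lesions"].fillna(0)
    X["baseline_target_volume"] = X["baseline_target_volume"].fillna(X["baseline_target_volume"].median())
    for c in X.columns:
        if X[c].dtype == bool:
            X[c] = X[c].astype(str)
    return X


def predict_progression_group(features: pd.DataFrame, labels: pd.Series, **options) -> ProgressionGroupClassifier:
    """Train/evaluate the baseline progression-group classifier."""
    common = features.index.intersection(labels.index)
    clf = ProgressionGroupClassifier(**options)
    return clf.fit(features.loc[common], labels.loc[common])
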