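"""Inference layer: PCA over displacement profiles, Welch group comparison,
and severe-sadness prediction.

The comparison battery mirrors a two-cohort mobility study: PCA is fitted
on the pooled daily-displacement-profile matrix (so component scores are
comparable across groups), and each of the first ten component scores, the
five circadian metrics and the seven daily phenotypes is compared between
groups with a Welch t-test.  The primary unit of analysis is the
participant (day-level values are averaged per participant first, avoiding
pseudo-replication); day-level pooling is available as a secondary view.

Prediction of severe sadness uses features recomputed over the 24 h leading
up to each self-report, restricted to participants with at least two severe
reports, with (a) a random-intercept logistic model whose AUROC is reported
on the population-level (marginal) linear predictor and (b) a random forest
evaluated with leave-one-participant-out cross-validation, reporting the
mean and SD of per-participant AUROC.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.stats.multitest import multipletests

from mobiphen.io_gps import GpsTrace, SadnessReport, SECONDS_PER_DAY, local_date, day_start_epoch
from mobiphen.displacement import ddp_table
from mobiphen.circadian import participant_circadian_metrics, DegenerateSeriesError
from mobiphen import phenotypes as ph

PHENOTYPE_NAMES = ["loc_var", "num_pls", "ent_pls", "perc_home", "total_dist", "max_dist", "routine_idx"]
CIRCADIAN_NAMES = ["IS", "IV", "M10", "L5", "RA"]


class DegenerateGroupsError(ValueError):
    """A statistical comparison or fit is undefined for these inputs."""


@dataclasses.dataclass
class PcaResult:
    """Centered (not scaled) PCA of a days × 47 displacement matrix."""

    loadings: np.ndarray  # (47, K) orthonormal columns
    explained_var_fraction: np.ndarray  # (K,) non-increasing
    scores: np.ndarray  # (n, K)
    center: np.ndarray  # (47,)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.center) @ self.loadings


@dataclasses.dataclass
class GroupComparison:
    metric_name: str
    mean_a: float
    mean_b: float
    t_stat: float
    dof: float
    p_value: float
    n_a: int
    n_b: int
    p_adjusted: float | None = None


@dataclasses.dataclass
class PredictionResult:
    model_name: str
    per_unit_auroc: pd.Series  # indexed by participant id
    mean_auroc: float
    sd_auroc: float
    n_participants_retained: int
    overall_auroc: float | None = None
    extras: dict = dataclasses.field(default_factory=dict)


def fit_pca(ddp_matrix: np.ndarray, n_components: int | None = None) -> PcaResult:
    """Centered PCA with a deterministic sign convention.

    Each loading column is flipped so its largest-magnitude entry is
    positive.  Rank-deficient inputs simply yield trailing zero-variance
    components.
    """
    x = np.asarray(ddp_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] <= x.shape[1]:
        raise ValueError("PCA needs more rows (days) than columns")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T.copy()
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return PcaResult(loadings, pca.explained_variance_ratio_.copy(), scores, pca.mean_.copy())


def welch_compare(values_a, values_b, metric_name: str = "") -> GroupComparison:
    """Welch two-sample t-test with Satterthwaite degrees of freedom.

    ``t_stat`` is signed as mean_a − mean_b; p is two-sided.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise DegenerateGroupsError("each group needs at least 2 finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise DegenerateGroupsError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        metric_name=metric_name,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_stat=float(res.statistic),
        dof=float(res.df),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
    )


# ---------------------------------------------------------------------------
# cohort feature extraction


@dataclasses.dataclass
class CohortFeatures:
    """Processed per-cohort features feeding the comparison battery."""

    ddp: pd.DataFrame  # participant_id, date, coverage, d01..d47
    circadian: pd.DataFrame  # participant_id, IS, IV, M10, L5, RA, n
    phenotypes: pd.DataFrame  # participant_id, date, seven features


def extract_cohort_features(
    traces: list[GpsTrace],
    utc_offset_h: float = -6.0,
    min_coverage: float = 0.5,
    circadian_bin_min: int = 15,
    **pheno_kwargs,
) -> CohortFeatures:
    """Run displacement, circadian and phenotype extraction over a cohort."""
    ddps, circ_rows, phenos = [], [], []
    for trace in traces:
        if len(trace) == 0:
            continue
        ddps.append(ddp_table(trace, utc_offset_h, min_coverage))
        try:
            m = participant_circadian_metrics(trace, circadian_bin_min, utc_offset_h)
            circ_rows.append(
                {"participant_id": trace.participant_id, "IS": m.IS, "IV": m.IV,
                 "M10": m.M10, "L5": m.L5, "RA": m.RA, "n": m.n}
            )
        except DegenerateSeriesError:
            pass
        phenos.append(ph.daily_phenotypes(trace, utc_offset_h, **pheno_kwargs))
    return CohortFeatures(
        ddp=pd.concat(ddps, ignore_index=True) if ddps else pd.DataFrame(),
        circadian=pd.DataFrame(circ_rows),
        phenotypes=pd.concat(phenos, ignore_index=True) if phenos else pd.DataFrame(),
    )


def _per_participant_means(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return df.groupby("participant_id", sort=True)[cols].mean()


def compare_groups(
    features_a: CohortFeatures,
    features_b: CohortFeatures,
    n_pcs: int = 10,
    unit: str = "participant",
    adjust: bool = True,
) -> pd.DataFrame:
    """Full two-cohort comparison: first ``n_pcs`` PCs, 5 circadian metrics,
    7 phenotypes — one Welch test per metric, Benjamini–Hochberg column.

    PCA is fitted on the pooled DDP matrix of both cohorts.  ``unit`` is
    "participant" (day values averaged per participant first; primary) or
    "day" (day-level pooling for PCs and phenotypes).
    """
    if unit not in ("participant", "day"):
        raise ValueError("unit must be 'participant' or 'day'")
    dcols = [f"d{i + 1:02d}" for i in range(47)]
    pooled = pd.concat([features_a.ddp, features_b.ddp], ignore_index=True)
    pca = fit_pca(pooled[dcols].to_numpy(), n_components=min(n_pcs, 47))
    rows: list[GroupComparison] = []
    n_a = len(features_a.ddp)
    score_frames = []
    for feats, lab in ((features_a, "a"), (features_b, "b")):
        scores = pca.transform(feats.ddp[dcols].to_numpy())
        sf = pd.DataFrame(scores[:, :n_pcs], columns=[f"PC{k + 1}" for k in range(n_pcs)])
        sf["participant_id"] = feats.ddp["participant_id"].to_numpy()
        score_frames.append(sf)
    pc_cols = [f"PC{k + 1}" for k in range(n_pcs)]
    for col in pc_cols:
        if unit == "participant":
            va = _per_participant_means(score_frames[0], [col])[col]
            vb = _per_participant_means(score_frames[1], [col])[col]
        else:
            va, vb = score_frames[0][col], score_frames[1][col]
        rows.append(welch_compare(va, vb, col))
    for col in CIRCADIAN_NAMES:
        rows.append(welch_compare(features_a.circadian[col], features_b.circadian[col], col))
    for col in PHENOTYPE_NAMES:
        if unit == "participant":
            va = _per_participant_means(features_a.phenotypes, [col])[col]
            vb = _per_participant_means(features_b.phenotypes, [col])[col]
        else:
            va, vb = features_a.phenotypes[col], features_b.phenotypes[col]
        rows.append(welch_compare(va, vb, col))
    out = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    if adjust:
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# prediction


def build_prediction_dataset(
    traces: list[GpsTrace],
    reports: list[SadnessReport],
    utc_offset_h: float = -6.0,
    min_severe: int = 2,
    slot_width_min: int = 30,
    **pheno_kwargs,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, dict]:
    """Feature rows for severe-sadness prediction.

    One row per retained report, with the seven phenotypes recomputed over
    the half-open 24-hour window ``[t_report − 24 h, t_report)``.  Only
    participants with at least ``min_severe`` severe reports are retained
    (all their reports enter, severe or not); rows with undefined features
    are dropped and counted.

    Returns ``(X, y, ids, info)`` where ``info`` records retention and
    dropped-row counts.
    """
    by_pid = {tr.participant_id: tr for tr in traces}
    rep = pd.DataFrame(
        {"participant_id": [r.participant_id for r in reports],
         "t": [r.t for r in reports],
         "severe": [r.severe for r in reports]}
    )
    if rep.empty:
        raise DegenerateGroupsError("no reports")
    n_sev = rep.groupby("participant_id")["severe"].sum()
    retained = set(n_sev[n_sev >= min_severe].index) & set(by_pid)
    if not retained:
        raise DegenerateGroupsError("no participants with enough severe reports")
    X_rows, y, ids = [], [], []
    n_dropped = 0
    for pid in sorted(retained):
        trace = by_pid[pid]
        _, stays, _ = ph.extract_places(
            trace,
            pheno_kwargs.get("d_thresh_m", ph.DEFAULT_D_THRESH_M),
            pheno_kwargs.get("t_min_s", ph.DEFAULT_T_MIN_S),
            pheno_kwargs.get("merge_thresh_m", ph.DEFAULT_MERGE_THRESH_M),
        )
        try:
            home_id = ph.identify_home(stays, utc_offset_h)
        except ph.UndefinedFeatureError:
            home_id = None
        # day-slot label matrix for the routine index of arbitrary windows
        dates = sorted(set(local_date(trace.t, utc_offset_h)))
        day_labels = np.vstack(
            [
                ph.slot_labels(
                    stays, day_start_epoch(d, utc_offset_h),
                    day_start_epoch(d, utc_offset_h) + SECONDS_PER_DAY, slot_width_min,
                )
                for d in dates
            ]
        )
        slots_per_day = day_labels.shape[1]
        for row in rep[rep["participant_id"] == pid].itertuples():
            t1 = row.t
            t0 = t1 - SECONDS_PER_DAY
            feats = ph.window_features(trace, stays, home_id, t0, t1,
                                       pheno_kwargs.get("denominator", "labeled"))
            # routine of the window: agreement with the participant's days
            # at the same time-of-day slots
            w_labels = ph.slot_labels(stays, t0, t1, slot_width_min)
            shift = utc_offset_h * 3600.0
            first_slot = int(np.floor((t0 + shift) / (slot_width_min * 60.0)))
            sod = (first_slot + np.arange(len(w_labels))) % slots_per_day
            feats["routine_idx"] = float((day_labels[:, sod] == w_labels[None, :]).mean())
            vec = [feats.get(k, np.nan) for k in PHENOTYPE_NAMES]
            if not np.all(np.isfinite(vec)):
                n_dropped += 1
                continue
            X_rows.append(vec)
            y.append(bool(row.severe))
            ids.append(pid)
    if not X_rows:
        raise DegenerateGroupsError("all feature rows undefined")
    X = pd.DataFrame(X_rows, columns=PHENOTYPE_NAMES)
    info = {"n_participants_retained": len(retained), "n_rows": len(X), "n_rows_dropped": n_dropped}
    return X, np.asarray(y, dtype=bool), np.asarray(ids), info


def _per_participant_auroc(y: np.ndarray, scores: np.ndarray, ids: np.ndarray) -> pd.Series:
    out = {}
    for pid in np.unique(ids):
        sel = ids == pid
        if len(np.unique(y[sel])) == 2:
            out[pid] = roc_auc_score(y[sel], scores[sel])
    return pd.Series(out, dtype=float)


def fit_mixed_logistic(X: pd.DataFrame, y: np.ndarray, ids: np.ndarray) -> PredictionResult:
    """Random-intercept-per-participant logistic regression (variational fit).

    The primary AUROC marginalizes the random effect (population-level
    linear predictor ``Xβ``); the conditional AUROC (adding each
    participant's posterior-mean intercept) is reported as an extra.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateGroupsError("both outcome classes must be present")
    if len(np.unique(ids)) < 2:
        raise DegenerateGroupsError("need at least 2 participants")
    Xv = np.asarray(X, dtype=float)
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (Xv - mu) / sd
    exog = np.column_stack([np.ones(len(Xz)), Xz])
    pids, idx = np.unique(ids, return_inverse=True)
    exog_vc = np.zeros((len(Xz), len(pids)))
    exog_vc[np.arange(len(Xz)), idx] = 1.0
    model = BinomialBayesMixedGLM(y, exog, exog_vc, ident=np.zeros(len(pids), dtype=int))
    try:
        fit = model.fit_vb()
    except Exception as err:  # pragma: no cover - surfaced, never silent
        raise DegenerateGroupsError(f"mixed logistic failed to converge: {err}") from err
    marginal = exog @ fit.fe_mean
    conditional = marginal + exog_vc @ fit.vc_mean
    per_unit = _per_participant_auroc(y.astype(bool), marginal, np.asarray(ids))
    return PredictionResult(
        model_name="mixed_logistic",
        per_unit_auroc=per_unit,
        mean_auroc=float(per_unit.mean()) if len(per_unit) else float("nan"),
        sd_auroc=float(per_unit.std(ddof=1)) if len(per_unit) > 1 else float("nan"),
        n_participants_retained=len(pids),
        overall_auroc=float(roc_auc_score(y.astype(bool), marginal)),
        extras={
            "conditional_auroc": float(roc_auc_score(y.astype(bool), conditional)),
            "fe_mean": fit.fe_mean.copy(),
            "vcp_mean": fit.vcp_mean.copy(),
        },
    )


def rf_loocv_auroc(
    X: pd.DataFrame,
    y: np.ndarray,
    ids: np.ndarray,
    seed: int = 0,
    n_estimators: int = 500,
) -> PredictionResult:
    """Random forest with leave-one-participant-out cross-validation.

    For each participant, a forest trained on everyone else scores the
    held-out rows; the per-participant AUROC is computed when the held-out
    participant has both classes (otherwise skipped and counted).  Mean and
    SD are across scoreable participants.  Deterministic given the seed.
    """
    y = np.asarray(y, dtype=bool)
    ids = np.asarray(ids)
    Xv = np.asarray(X, dtype=float)
    pids = np.unique(ids)
    if len(pids) < 3:
        raise DegenerateGroupsError("need at least 3 participants")
    aurocs, skipped = {}, 0
    for pid in pids:
        test = ids == pid
        if len(np.unique(y[test])) < 2:
            skipped += 1
            continue
        train = ~test
        if len(np.unique(y[train])) < 2:
            skipped += 1
            continue
        rf = RandomForestClassifier(
            n_estimators=n_estimators, max_features="sqrt", random_state=seed, n_jobs=1
        )
        rf.fit(Xv[train], y[train])
        scores = rf.predict_proba(Xv[test])[:, 1]
        aurocs[pid] = roc_auc_score(y[test], scores)
    if len(aurocs) < 2:
        raise DegenerateGroupsError("too few scoreable participants")
    per_unit = pd.Series(aurocs, dtype=float)
    return PredictionResult(
        model_name="rf_loocv",
        per_unit_auroc=per_unit,
        mean_auroc=float(per_unit.mean()),
        sd_auroc=float(per_unit.std(ddof=1)),
        n_participants_retained=len(per_unit),
        extras={"n_skipped": skipped},
    )
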