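"""The MESA multimodal classifier.

Four feature modalities (CGI methylation, DHS methylation, nucleosome
occupancy, WPS) each go through a Mann-Whitney prefilter and Boruta marker
selection, feed a per-modality base probability estimator, and a logistic
meta-classifier combines the four base probabilities. All selection and
fitting happen inside each cross-validation training fold; the meta-
classifier is trained on inner out-of-fold base probabilities so it never
sees resubstitution scores.

Defaults follow the published configuration: prefilter sizes
3000/2500/200/200 and Boruta marker targets 100/100/20/80 for
cgi_meth/dhs_meth/occupancy/wps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .differential import mwu_pvalues
from .io import FeatureMatrix

logger = logging.getLogger(__name__)

MODALITY_ORDER = ("cgi_meth", "dhs_meth", "occupancy", "wps")

DEFAULT_PREFILTER_K = {"cgi_meth": 3000, "dhs_meth": 2500, "occupancy": 200, "wps": 200}
DEFAULT_BORUTA_K = {"cgi_meth": 100, "dhs_meth": 100, "occupancy": 20, "wps": 80}

POSITIVE_GROUPS = ("sALS", "C9-ALS")


def _as_frame(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, FeatureMatrix) else matrix


def _binary_labels(labels: pd.Series) -> np.ndarray:
    """1 for disease groups, 0 for controls/carriers."""
    return labels.isin(POSITIVE_GROUPS).to_numpy().astype(int)


# ---------------------------------------------------------------------------
# ROC metrics
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Out-of-fold probabilities and ROC summary of one evaluation."""

    probabilities: pd.Series
    labels: pd.Series
    auc: float
    sensitivity_at_fpr0: float
    roc_points: pd.DataFrame
    auc_ci: Optional[tuple] = None
    markers: Optional[dict] = None


def roc_metrics(probabilities: np.ndarray, y: np.ndarray):
    """(AUC, ROC points, sensitivity at FPR 0).

    AUC is the rank statistic with ties counted half; sensitivity at FPR 0
    is the fraction of positives scoring strictly above every negative.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(probabilities)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    sens0 = float((probabilities[y == 1] > probabilities[y == 0].max()).mean())

    order = np.argsort(-probabilities, kind="mergesort")
    sorted_y = y[order]
    sorted_p = probabilities[order]
    distinct = np.r_[np.diff(sorted_p) != 0, True]
    tps = np.cumsum(sorted_y)[distinct]
    fps = np.cumsum(1 - sorted_y)[distinct]
    roc = pd.DataFrame(
        {
            "fpr": np.r_[0.0, fps / n_neg],
            "tpr": np.r_[0.0, tps / n_pos],
        }
    )
    return float(auc), roc, sens0


def bootstrap_auc_ci(
    probabilities: np.ndarray, y: np.ndarray, n_boot: int = 200, seed: int = 0,
    level: float = 0.95,
):
    """Percentile bootstrap CI for the AUC (resampling samples)."""
    rng = np.random.default_rng(seed)
    probabilities = np.asarray(probabilities, float)
    y = np.asarray(y, int)
    aucs = []
    n = len(y)
    while len(aucs) < n_boot:
        idx = rng.integers(0, n, size=n)
        if y[idx].sum() in (0, n):
            continue
        aucs.append(roc_metrics(probabilities[idx], y[idx])[0])
    lo, hi = np.quantile(aucs, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# prefilter
# ---------------------------------------------------------------------------

class MannWhitneyPrefilter(BaseEstimator):
    """Keep the top-k features by two-sided Mann-Whitney U p-value.

    Features with more than ``max_missing`` missing values are dropped
    first; the rest are mean-imputed with training-fold means. Ties in p
    break by |median difference| descending, then feature id.
    """

    def __init__(self, k: int = 200, max_missing: float = 0.20):
        self.k = k
        self.max_missing = max_missing

    def fit(self, X: pd.DataFrame, y) -> "MannWhitneyPrefilter":
        X = _as_frame(X)
        y = np.asarray(y, dtype=int)
        missing = X.isna().mean(axis=0)
        usable = X.loc[:, missing.to_numpy() <= self.max_missing + 1e-12]
        self.impute_means_ = usable.mean(axis=0)
        filled = usable.fillna(self.impute_means_)

        a = filled.to_numpy(dtype=float)[y == 1]
        b = filled.to_numpy(dtype=float)[y == 0]
        _, p = mwu_pvalues(a, b)
        med_diff = np.abs(np.median(a, axis=0) - np.median(b, axis=0))
        order = pd.DataFrame(
            {"p": p, "neg_med": -med_diff, "feature": usable.columns}
        ).sort_values(["p", "neg_med", "feature"], kind="mergesort")
        k = self.k
        if k >= len(order):
            if k > len(order):
                logger.warning(
                    "prefilter k=%d >= %d available features; keeping all",
                    k, len(order),
                )
            k = len(order)
        self.pvalues_ = pd.Series(p, index=usable.columns)
        self.selected_ids_ = list(order["feature"].head(k))
        self.ranking_ = list(order["feature"])
        return self

    def transform(self, X) -> pd.DataFrame:
        X = _as_frame(X)
        out = X.reindex(columns=self.selected_ids_)
        return out.fillna(self.impute_means_.reindex(self.selected_ids_))


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------

class BorutaSelector(BaseEstimator):
    """Boruta wrapper selection against permuted shadow features.

    Each iteration appends per-feature permutations (shadows), fits a
    random-forest importance ranker, and scores a hit for every real
    feature whose importance exceeds the best shadow importance. Features
    are confirmed/rejected by a BH-corrected two-sided binomial test of
    their hit counts against 0.5. Confirmed features are ranked by mean
    importance; tentative features and then the incoming ranking backfill
    to exactly ``min(k_target, n_features)`` markers.

    When the input already has at most ``k_target`` features, all are
    selected without running iterations.
    """

    def __init__(
        self,
        k_target: int = 100,
        max_iter: int = 50,
        alpha: float = 0.05,
        n_estimators: int = 50,
        random_state: int = 0,
    ):
        self.k_target = k_target
        self.max_iter = max_iter
        self.alpha = alpha
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "BorutaSelector":
        X = _as_frame(X)
        y = np.asarray(y, dtype=int)
        features = list(X.columns)
        n = len(features)
        if n <= self.k_target:
            if n < self.k_target:
                logger.warning(
                    "only %d features for k_target=%d; selecting all", n, self.k_target
                )
            self.selected_ids_ = features
            self.confirmed_ = []
            self.tentative_ = features
            self.n_iter_ = 0
            return self

        rng = np.random.default_rng(self.random_state)
        values = X.to_numpy(dtype=float)
        active = np.ones(n, dtype=bool)      # not yet rejected
        confirmed = np.zeros(n, dtype=bool)
        rejected = np.zeros(n, dtype=bool)
        hits = np.zeros(n, dtype=int)
        trials = np.zeros(n, dtype=int)
        imp_sum = np.zeros(n)
        imp_count = np.zeros(n, dtype=int)

        it = 0
        for it in range(1, self.max_iter + 1):
            idx = np.flatnonzero(active)
            real = values[:, idx]
            shadow = real.copy()
            for j in range(shadow.shape[1]):
                rng.shuffle(shadow[:, j])
            forest = RandomForestClassifier(
                n_estimators=self.n_estimators,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(np.hstack([real, shadow]), y)
            imp = forest.feature_importances_
            real_imp = imp[: len(idx)]
            shadow_max = imp[len(idx):].max()
            hit = real_imp > shadow_max
            hits[idx] += hit
            trials[idx] += 1
            imp_sum[idx] += real_imp
            imp_count[idx] += 1

            undecided = active & ~confirmed
            und_idx = np.flatnonzero(undecided)
            if len(und_idx):
                pvals = np.array(
                    [
                        stats.binomtest(hits[j], trials[j], 0.5).pvalue
                        for j in und_idx
                    ]
                )
                sig = multipletests(pvals, alpha=self.alpha, method="fdr_bh")[0]
                for j, s in zip(und_idx, sig):
                    if not s:
                        continue
                    if hits[j] * 2 > trials[j]:
                        confirmed[j] = True
                    else:
                        rejected[j] = True
                        active[j] = False
            if not (active & ~confirmed).any():
                break

        self.n_iter_ = it
        mean_imp = np.where(imp_count > 0, imp_sum / np.maximum(imp_count, 1), -np.inf)
        conf_idx = np.flatnonzero(confirmed)
        tent_idx = np.flatnonzero(active & ~confirmed)
        conf_sorted = conf_idx[np.argsort(-mean_imp[conf_idx], kind="mergesort")]
        tent_sorted = tent_idx[np.argsort(-mean_imp[tent_idx], kind="mergesort")]
        ranking = list(conf_sorted) + list(tent_sorted)
        # backfill from the incoming (prefilter) order
        ranking += [j for j in range(n) if j not in set(ranking)]
        chosen = ranking[: self.k_target]
        self.confirmed_ = [features[j] for j in conf_sorted]
        self.tentative_ = [features[j] for j in tent_sorted]
        self.selected_ids_ = [features[j] for j in chosen]
        return self

    def transform(self, X) -> pd.DataFrame:
        return _as_frame(X)[self.selected_ids_]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_base_estimator(
    random_state: int = 0, n_estimators: int = 50, kind: str = "logistic"
):
    """Per-modality base probability estimator.

    The default is a standardized L2-regularized logistic model, which
    aggregates many weakly informative markers and stays stable at cohort
    sizes around 40; a gradient-boosted tree ensemble is available as
    ``kind="gbt"`` for nonlinear marker interactions.
    """
    if kind == "gbt":
        return GradientBoostingClassifier(
            n_estimators=n_estimators,
            max_depth=2,
            learning_rate=0.1,
            random_state=random_state,
        )
    if kind != "logistic":
        raise ValueError(f"unknown base estimator kind {kind!r}")
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(
            C=1.0, class_weight="balanced", random_state=random_state, max_iter=1000
        ),
    )


class NonNegativeLogisticCombiner(BaseEstimator):
    """Logistic stacker with non-negative weights shrunk toward the average.

    The inputs are base-model probabilities of the same event, so the
    combiner is constrained to be a (soft) weighted average: coefficients
    are bounded below by zero (the non-negativity constraint of classic
    stacked generalization) and L2-penalized toward equal unit weights.
    When the base probabilities carry no out-of-fold information the
    combiner therefore falls back to the simple average, and it can never
    sign-flip a noisy base model; with informative inputs the likelihood
    term reweights the modalities. The combined score is monotone
    non-decreasing in every base probability.
    """

    def __init__(self, alpha: float = 50.0):
        self.alpha = alpha

    def fit(self, X, y):
        from scipy.optimize import minimize

        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        w0 = np.ones(p)

        def objective(params):
            w, b = params[:p], params[p]
            z = X @ w + b
            ys = 2 * y - 1
            loss = np.logaddexp(0.0, -ys * z).mean()
            loss += 0.5 * self.alpha * np.sum((w - w0) ** 2) / n
            sig = 1.0 / (1.0 + np.exp(-z))
            grad_w = X.T @ (sig - y) / n + self.alpha * (w - w0) / n
            grad_b = (sig - y).mean()
            return loss, np.r_[grad_w, grad_b]

        bounds = [(0.0, None)] * p + [(None, None)]
        res = minimize(
            objective, x0=np.r_[w0, 0.0], jac=True,
            method="L-BFGS-B", bounds=bounds,
        )
        self.coef_ = res.x[:p]
        self.intercept_ = float(res.x[p])
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        z = np.asarray(X, float) @ self.coef_ + self.intercept_
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p1, p1])


def default_meta_estimator(random_state: int = 0):
    """Non-negative, average-anchored logistic combiner of base probabilities."""
    return NonNegativeLogisticCombiner(alpha=50.0)


@dataclass
class MesaConfig:
    """Tunable sizes of the MESA pipeline; defaults are the published ones."""

    prefilter_k: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PREFILTER_K)
    )
    boruta_k: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BORUTA_K)
    )
    boruta_max_iter: int = 50
    boruta_alpha: float = 0.05
    rf_estimators: int = 50
    base_kind: str = "logistic"
    base_estimators: int = 50
    inner_folds: int = 5
    max_missing: float = 0.20

    def scaled(self, **overrides) -> "MesaConfig":
        return replace(self, **overrides)


# ---------------------------------------------------------------------------
# base / meta training
# ---------------------------------------------------------------------------

def train_base(
    X: pd.DataFrame, y, seed: int = 0, n_estimators: int = 50, kind: str = "logistic"
):
    """Fit the per-modality base probability estimator on marker features."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("base estimator needs both classes")
    est = default_base_estimator(
        random_state=seed, n_estimators=n_estimators, kind=kind
    )
    est.fit(_as_frame(X).to_numpy(dtype=float), y)
    return est


def train_meta(base_probabilities: np.ndarray, y, seed: int = 0):
    """Fit the meta-classifier on (inner out-of-fold) base probabilities."""
    est = default_meta_estimator(random_state=seed)
    est.fit(np.asarray(base_probabilities, dtype=float), np.asarray(y, dtype=int))
    return est


# ---------------------------------------------------------------------------
# the stacked multimodal classifier
# ---------------------------------------------------------------------------

class MesaClassifier(BaseEstimator):
    """Stacked multimodal classifier over four epigenetic feature matrices.

    ``fit`` takes a mapping of modality name to samples x features
    DataFrame (all with identical sample index) and a label Series; the
    positive class is disease. Exposes fitted attributes ``markers_``,
    ``base_estimators_``, ``meta_`` and ``train_sample_ids_``.
    """

    def __init__(self, config: Optional[MesaConfig] = None, random_state: int = 0):
        self.config = config
        self.random_state = random_state

    def _cfg(self) -> MesaConfig:
        return self.config if self.config is not None else MesaConfig()

    def fit(self, Xs: Mapping[str, object], y: pd.Series) -> "MesaClassifier":
        cfg = self._cfg()
        frames = {m: _as_frame(Xs[m]) for m in MODALITY_ORDER if m in Xs}
        if not frames:
            raise ValueError(f"no known modalities in {list(Xs)}")
        index = None
        for m, f in frames.items():
            if index is None:
                index = f.index
            elif not f.index.equals(index):
                raise ValueError(f"sample index mismatch in modality {m!r}")
        if isinstance(y, pd.Series):
            y_bin = _binary_labels(y.reindex(index))
        else:
            y_bin = np.asarray(y, dtype=int)
        if len(np.unique(y_bin)) < 2:
            raise ValueError("need both classes to train")

        ss = np.random.SeedSequence([self.random_state, 2_000_001])
        seeds = ss.generate_state(4 * len(frames) + 2)
        self.markers_ = {}
        self.prefilters_ = {}
        self.base_estimators_ = {}
        marker_frames = {}
        for i, (modality, X) in enumerate(frames.items()):
            pre = MannWhitneyPrefilter(
                k=cfg.prefilter_k.get(modality, X.shape[1]),
                max_missing=cfg.max_missing,
            ).fit(X, y_bin)
            reduced = pre.transform(X)
            boruta = BorutaSelector(
                k_target=cfg.boruta_k.get(modality, reduced.shape[1]),
                max_iter=cfg.boruta_max_iter,
                alpha=cfg.boruta_alpha,
                n_estimators=cfg.rf_estimators,
                random_state=int(seeds[4 * i] % (2**31 - 1)),
            ).fit(reduced, y_bin)
            markers = boruta.transform(reduced)
            self.prefilters_[modality] = pre
            self.markers_[modality] = list(markers.columns)
            marker_frames[modality] = markers
            self.base_estimators_[modality] = train_base(
                markers, y_bin,
                seed=int(seeds[4 * i + 1] % (2**31 - 1)),
                n_estimators=cfg.base_estimators,
                kind=cfg.base_kind,
            )

        # inner out-of-fold base probabilities for leak-free meta training
        n_splits = min(cfg.inner_folds, int(np.bincount(y_bin).min()))
        n_splits = max(n_splits, 2)
        skf = StratifiedKFold(
            n_splits=n_splits, shuffle=True,
            random_state=int(seeds[-2] % (2**31 - 1)),
        )
        oof = np.zeros((len(y_bin), len(marker_frames)))
        for train_idx, test_idx in skf.split(np.zeros(len(y_bin)), y_bin):
            for col, (modality, markers) in enumerate(marker_frames.items()):
                values = markers.to_numpy(dtype=float)
                est = clone(self.base_estimators_[modality])
                est.fit(values[train_idx], y_bin[train_idx])
                oof[test_idx, col] = est.predict_proba(values[test_idx])[:, 1]
        self.meta_ = train_meta(oof, y_bin, seed=int(seeds[-1] % (2**31 - 1)))
        self.modalities_ = list(marker_frames)
        self.train_sample_ids_ = list(index)
        self.classes_ = np.array([0, 1])
        return self

    def _base_probabilities(self, Xs: Mapping[str, object]) -> np.ndarray:
        cols = []
        for modality in self.modalities_:
            X = _as_frame(Xs[modality])
            pre = self.prefilters_[modality]
            markers = self.markers_[modality]
            missing = [f for f in markers if f not in X.columns]
            if missing:
                if len(missing) > 0.5 * len(markers):
                    raise ValueError(
                        f"{modality}: {len(missing)}/{len(markers)} markers absent"
                    )
                logger.warning(
                    "%s: imputing %d absent markers with training means",
                    modality, len(missing),
                )
            values = X.reindex(columns=markers)
            values = values.fillna(pre.impute_means_.reindex(markers))
            cols.append(
                self.base_estimators_[modality].predict_proba(
                    values.to_numpy(dtype=float)
                )[:, 1]
            )
        return np.column_stack(cols)

    def predict_proba(self, Xs: Mapping[str, object]) -> np.ndarray:
        base = self._base_probabilities(Xs)
        return self.meta_.predict_proba(base)

    def predict(self, Xs: Mapping[str, object]) -> np.ndarray:
        return (self.predict_proba(Xs)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# cross-validation and cross-cohort application
# ---------------------------------------------------------------------------

def run_loocv(
    Xs: Mapping[str, object],
    labels: pd.Series,
    config: Optional[MesaConfig] = None,
    seed: int = 0,
    compute_ci: bool = True,
) -> CvReport:
    """Leave-one-out cross-validation with per-fold selection and training.

    Every held-out sample is predicted by a model whose prefilter, Boruta
    selection, base estimators and meta-classifier saw only the remaining
    n - 1 samples.
    """
    frames = {m: _as_frame(X) for m, X in Xs.items()}
    index = next(iter(frames.values())).index
    labels = labels.reindex(index)
    y = _binary_labels(labels)
    if len(index) < 6:
        raise ValueError("LOOCV needs n >= 6")

    probs = np.zeros(len(index))
    fold_seeds = np.random.SeedSequence([seed, 77]).generate_state(len(index))
    for i in range(len(index)):
        train_mask = np.ones(len(index), dtype=bool)
        train_mask[i] = False
        if len(np.unique(y[train_mask])) < 2:
            raise ValueError("both classes must remain in every training fold")
        train_Xs = {m: f.iloc[train_mask] for m, f in frames.items()}
        test_Xs = {m: f.iloc[[i]] for m, f in frames.items()}
        model = MesaClassifier(
            config=config, random_state=int(fold_seeds[i] % (2**31 - 1))
        ).fit(train_Xs, labels.iloc[train_mask])
        assert index[i] not in model.train_sample_ids_, "leakage: test sample in training fold"
        probs[i] = model.predict_proba(test_Xs)[0, 1]

    auc, roc, sens0 = roc_metrics(probs, y)
    ci = bootstrap_auc_ci(probs, y, seed=seed) if compute_ci else None
    return CvReport(
        probabilities=pd.Series(probs, index=index, name="p_disease"),
        labels=labels,
        auc=auc,
        sensitivity_at_fpr0=sens0,
        roc_points=roc,
        auc_ci=ci,
    )


def cross_cohort_apply(
    model: MesaClassifier, Xs: Mapping[str, object], labels: pd.Series
) -> CvReport:
    """Apply a trained model to an independent cohort without refitting."""
    frames = {m: _as_frame(X) for m, X in Xs.items()}
    index = next(iter(frames.values())).index
    labels = labels.reindex(index)
    y = _binary_labels(labels)
    probs = model.predict_proba(frames)[:, 1]
    auc, roc, sens0 = roc_metrics(probs, y)
    return CvReport(
        probabilities=pd.Series(probs, index=index, name="p_disease"),
        labels=labels,
        auc=auc,
        sensitivity_at_fpr0=sens0,
        roc_points=roc,
        markers={m: list(v) for m, v in model.markers_.items()},
    )


# ---------------------------------------------------------------------------
# biomarker variability
# ---------------------------------------------------------------------------

def biomarker_cv(
    beta: pd.DataFrame, cpg_ids: Sequence, groups: pd.Series
) -> pd.DataFrame:
    """Per-CpG, per-group coefficient of variation (sample sd / mean).

    NaN where the group mean is zero.
    """
    groups = groups.reindex(beta.index)
    rows = {}
    for g, sub in beta.loc[:, list(cpg_ids)].groupby(groups):
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        rows[g] = (sd / mean.replace(0.0, np.nan)).to_numpy()
    out = pd.DataFrame(rows, index=list(cpg_ids))
    out.index.name = "cpg"
    return out
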