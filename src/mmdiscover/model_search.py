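"""Exhaustive low-dimensional logistic classifier search with repeated
hold-out ensembling, Youden-index ranking and multimodal fusion.

Every subset of 1..3 features is fit with a ridge-stabilized logistic
regression; performance is estimated by stratified 80/20 hold-out splits
repeated many times (>= 200 by default), reporting ensemble test-set
sensitivity, specificity, PPV, NPV and AUC (mean, SD and a 2.5-97.5
percentile interval over repeats).  Models are ranked by Youden's
J = sensitivity + specificity - 1, ties broken by mean AUC and then by
feature id.  Multimodal fusion concatenates the top single-modality
candidates' features on the matched cohort and re-runs the same ensemble.

The logistic fit is a small Newton/IRLS solver with an L2 penalty
(default 1e-4) on the non-intercept coefficients so that perfectly
separable small-n training folds still converge to a finite optimum; it
matches scikit-learn's LogisticRegression with C = 1/penalty.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .containers import CohortLabels, FeatureTable

CLINICAL_COLUMNS = ("age", "PSA", "PIRADS")


@dataclasses.dataclass
class SearchConfig:
    """Knobs of the hold-out ensemble and the subset search."""

    max_subset_size: int = 3
    train_fraction: float = 0.8
    n_repeats: int = 200
    decision_threshold_rule: str = "train-youden"  # or "fixed-0.5"
    ridge_penalty: float = 1e-4
    seed: int = 0
    #: with a value M, multi-feature subsets are pre-screened by a single
    #: fixed-split AUC and only the top M receive the full ensemble
    prescreen_top: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.max_subset_size <= 3:
            raise ValueError("max_subset_size must be 1..3")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0,1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.decision_threshold_rule not in ("train-youden", "fixed-0.5"):
            raise ValueError("unknown decision_threshold_rule")
        if self.ridge_penalty < 0:
            raise ValueError("ridge_penalty must be non-negative")


@dataclasses.dataclass
class ModelResult:
    """A feature subset plus its ensembled hold-out metrics."""

    feature_ids: tuple[str, ...]
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc_mean: float
    auc_sd: float
    auc_ci: tuple[float, float]
    n_repeats: int

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def to_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "youden_j": self.youden_j,
            "n_repeats": self.n_repeats,
        }


# ---------------------------------------------------------------------------
# subset enumeration

def enumerate_subsets(
    feature_ids: Sequence[str], k: int
) -> tuple[Iterator[tuple[str, ...]], int]:
    """All k-subsets in lexicographic (input) order, plus their exact count."""
    if k > len(feature_ids):
        raise ValueError("k exceeds the number of features")
    return itertools.combinations(feature_ids, k), math.comb(len(feature_ids), k)


# ---------------------------------------------------------------------------
# logistic fit

class LogisticModel:
    """Ridge-penalized logistic regression scores, IRLS-fitted."""

    def __init__(self, intercept: float, coef: np.ndarray, mean: np.ndarray, scale: np.ndarray):
        self.intercept_ = intercept
        self.coef_ = coef
        self._mean = mean
        self._scale = scale

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(x) - self._mean) / self._scale
        return self.intercept_ + z @ self.coef_

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return expit(self.decision_function(x))


def _irls(x: np.ndarray, y: np.ndarray, ridge: float, max_iter: int = 60, tol: float = 1e-9):
    """Newton iteration for penalized logistic log-likelihood.

    Penalty 0.5*ridge*||w||^2 on non-intercept coefficients; step halving
    guards the few pathological small-n folds.
    """
    n, p = x.shape
    xd = np.column_stack([np.ones(n), x])
    lam = np.full(p + 1, ridge)
    lam[0] = 0.0
    w = np.zeros(p + 1)

    def negloglik(w):
        eta = xd @ w
        # log(1+exp(-|eta|)) formulation for stability
        ll = np.sum(np.logaddexp(0.0, eta) - y * eta)
        return ll + 0.5 * np.sum(lam * w * w)

    f = negloglik(w)
    for _ in range(max_iter):
        eta = xd @ w
        mu = expit(eta)
        wt = mu * (1.0 - mu) + 1e-12
        grad = xd.T @ (mu - y) + lam * w
        hess = (xd * wt[:, None]).T @ xd + np.diag(lam + 1e-10)
        step = np.linalg.solve(hess, grad)
        t = 1.0
        for _ in range(30):
            w_new = w - t * step
            f_new = negloglik(w_new)
            if f_new <= f + 1e-12:
                break
            t *= 0.5
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w, f = w_new, f_new
    return w


def fit_logistic(
    train_x: np.ndarray, train_y: np.ndarray, ridge_penalty: float = 1e-4
) -> LogisticModel:
    """Fit a (up to 3-predictor) logistic model; returns a scoring object.

    Predictors are standardized internally on the training data, so the
    penalty acts on comparably scaled coefficients; scores for new samples
    apply the training standardization.
    """
    x = np.atleast_2d(np.asarray(train_x, dtype=float))
    y = np.asarray(train_y, dtype=float)
    if x.shape[1] > 4:
        raise ValueError("at most 3-4 joint predictors are supported")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0.0] = 1.0
    z = (x - mean) / scale
    w = _irls(z, y, ridge_penalty)
    return LogisticModel(float(w[0]), w[1:].copy(), mean, scale)


# ---------------------------------------------------------------------------
# metrics

def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score+ > score-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC needs both classes")
    r = rankdata(scores)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Decision threshold maximizing J on the given (training) scores.

    Candidates are midpoints between adjacent distinct scores plus outer
    sentinels; the lowest maximizing threshold is returned (deterministic).
    """
    s = np.unique(np.asarray(scores, dtype=float))
    if len(s) == 1:
        return s[0]
    cand = np.concatenate([[s[0] - 1.0], (s[:-1] + s[1:]) / 2.0, [s[-1] + 1.0]])
    y = np.asarray(labels)
    best_t, best_j = cand[0], -np.inf
    for t in cand:
        pred = scores >= t
        se = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
        sp = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
        j = se + sp - 1.0
        if j > best_j + 1e-12:
            best_t, best_j = t, j
    return float(best_t)


def _confusion_rates(pred: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    se = tp / (tp + fn) if tp + fn else np.nan
    sp = tn / (tn + fp) if tn + fp else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    return se, sp, ppv, npv


# ---------------------------------------------------------------------------
# repeated hold-out ensemble

def _stratified_split(
    idx0: np.ndarray, idx1: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class 80/20 split with at least one test sample per class."""
    test_parts, train_parts = [], []
    for idx in (idx0, idx1):
        n_test = max(1, int(round(len(idx) * (1.0 - train_fraction))))
        n_test = min(n_test, len(idx) - 1)  # keep >= 1 training sample
        perm = rng.permutation(idx)
        test_parts.append(perm[:n_test])
        train_parts.append(perm[n_test:])
    return np.concatenate(train_parts), np.concatenate(test_parts)


def _batched_irls(z: np.ndarray, y: np.ndarray, ridge: float,
                  max_iter: int = 40, tol: float = 1e-7) -> np.ndarray:
    """Newton/IRLS over a stack of identically shaped training folds.

    ``z`` is (repeats, n, p) standardized predictors, ``y`` length n (the
    stratified layout makes labels identical across folds).  Returns
    weights (repeats, p+1) with the intercept first.  Step halving is
    applied per fold where the penalized deviance would increase.
    """
    r, n, p = z.shape
    xd = np.concatenate([np.ones((r, n, 1)), z], axis=2)
    lam = np.full(p + 1, ridge)
    lam[0] = 0.0
    w = np.zeros((r, p + 1))

    def negloglik(wm: np.ndarray) -> np.ndarray:
        eta = np.einsum("rnp,rp->rn", xd, wm)
        ll = np.logaddexp(0.0, eta) - y[None, :] * eta
        return ll.sum(axis=1) + 0.5 * (lam * wm * wm).sum(axis=1)

    f = negloglik(w)
    eye = np.diag(lam + 1e-10)
    for _ in range(max_iter):
        eta = np.einsum("rnp,rp->rn", xd, w)
        mu = expit(eta)
        wt = mu * (1.0 - mu) + 1e-12
        grad = np.einsum("rnp,rn->rp", xd, mu - y[None, :]) + lam * w
        hess = np.einsum("rnp,rn,rnq->rpq", xd, wt, xd) + eye
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        t = np.ones(r)
        w_new = w - step
        f_new = negloglik(w_new)
        for _ in range(25):
            bad = f_new > f + 1e-12
            if not bad.any():
                break
            t[bad] *= 0.5
            w_new[bad] = w[bad] - t[bad, None] * step[bad]
            f_new[bad] = negloglik(w_new)[bad]
        done = np.max(np.abs(w_new - w)) < tol
        w, f = w_new, f_new
        if done:
            break
    return w


def _batched_youden_thresholds(s_tr: np.ndarray, y_tr: np.ndarray) -> np.ndarray:
    """Per-fold training threshold maximizing Youden J (lowest maximizer)."""
    r, n = s_tr.shape
    ss = np.sort(s_tr, axis=1)
    cand = np.concatenate(
        [ss[:, :1] - 1.0, (ss[:, :-1] + ss[:, 1:]) / 2.0, ss[:, -1:] + 1.0], axis=1
    )  # (r, n+1), ascending
    pred = s_tr[:, None, :] >= cand[:, :, None]  # (r, c, n)
    pos = y_tr == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    se = pred[:, :, pos].sum(axis=2) / n1
    sp = (~pred[:, :, ~pos]).sum(axis=2) / n0
    j = se + sp - 1.0
    best = np.argmax(j, axis=1)  # first (lowest) maximizer
    return cand[np.arange(r), best]


def evaluate_holdout_ensemble(
    table: FeatureTable,
    labels: CohortLabels,
    subset: Sequence[str],
    cfg: SearchConfig,
    _x: np.ndarray | None = None,
    _y: np.ndarray | None = None,
    _rng: np.random.Generator | None = None,
) -> ModelResult:
    """Ensemble test metrics of one feature subset over repeated splits.

    Samples are ordered by id internally, so results are invariant to row
    permutations of the input table.  Stratified splits guarantee both
    classes in every training fold and at least one sample of each class in
    every test fold.  PPV/NPV are undefined on folds without the relevant
    predictions and are averaged over the folds where they exist.  All
    repeats are fit in one vectorized Newton solve; the result matches
    fitting each fold with :func:`fit_logistic`.
    """
    if _x is None or _y is None:
        y_series = labels.binary()
        common = sorted(s for s in table.sample_ids if s in y_series.index)
        y = y_series.loc[common].to_numpy()
        x = table.data.loc[common, list(subset)].to_numpy(dtype=float)
    else:
        x, y = _x, _y
    x = np.atleast_2d(np.asarray(x, dtype=float))
    idx0, idx1 = np.nonzero(y == 0)[0], np.nonzero(y == 1)[0]
    if len(idx0) < 2 or len(idx1) < 2:
        raise ValueError("each class needs >= 2 samples for a stratified split")
    rng = _rng if _rng is not None else np.random.default_rng(
        np.random.SeedSequence((cfg.seed, 7))
    )
    reps = cfg.n_repeats
    splits = [_stratified_split(idx0, idx1, cfg.train_fraction, rng) for _ in range(reps)]
    tr_idx = np.stack([s[0] for s in splits])  # (reps, n_tr), class-0 block first
    te_idx = np.stack([s[1] for s in splits])
    y_tr = y[tr_idx[0]]
    y_te = y[te_idx[0]]

    x_tr = x[tr_idx]  # (reps, n_tr, p)
    x_te = x[te_idx]
    mean = x_tr.mean(axis=1, keepdims=True)
    sd = x_tr.std(axis=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    z_tr = (x_tr - mean) / sd
    z_te = (x_te - mean) / sd
    w = _batched_irls(z_tr, y_tr, cfg.ridge_penalty)
    s_tr = w[:, :1] + np.einsum("rnp,rp->rn", z_tr, w[:, 1:])
    s_te = w[:, :1] + np.einsum("rnp,rp->rn", z_te, w[:, 1:])

    if cfg.decision_threshold_rule == "train-youden":
        thr = _batched_youden_thresholds(s_tr, y_tr)
    else:
        thr = np.zeros(reps)  # decision-function zero == probability 0.5
    pred = s_te >= thr[:, None]
    pos = y_te == 1
    tp = pred[:, pos].sum(axis=1).astype(float)
    fn = (~pred[:, pos]).sum(axis=1).astype(float)
    tn = (~pred[:, ~pos]).sum(axis=1).astype(float)
    fp = pred[:, ~pos].sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = tp / (tp + fn)
        sp = tn / (tn + fp)
        ppv = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        npv = np.where(tn + fn > 0, tn / np.maximum(tn + fn, 1), np.nan)
    ranks = rankdata(s_te, axis=1)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    auc = (ranks[:, pos].sum(axis=1) - n1 * (n1 + 1) / 2) / (n0 * n1)
    with np.errstate(invalid="ignore"):
        return ModelResult(
            feature_ids=tuple(subset),
            sensitivity=float(np.nanmean(se)),
            specificity=float(np.nanmean(sp)),
            ppv=float(np.nanmean(ppv)) if not np.isnan(ppv).all() else float("nan"),
            npv=float(np.nanmean(npv)) if not np.isnan(npv).all() else float("nan"),
            auc_mean=float(auc.mean()),
            auc_sd=float(auc.std(ddof=1)) if cfg.n_repeats > 1 else 0.0,
            auc_ci=(float(np.percentile(auc, 2.5)), float(np.percentile(auc, 97.5))),
            n_repeats=cfg.n_repeats,
        )


def rank_models(results: Iterable[ModelResult]) -> list[ModelResult]:
    """Youden J descending, then mean AUC descending, then feature ids."""
    results = list(results)
    if not results:
        raise ValueError("nothing to rank")
    return sorted(results, key=lambda m: (-m.youden_j, -m.auc_mean, m.feature_ids))


def _single_split_auc(
    x: np.ndarray, y: np.ndarray, cfg: SearchConfig, rng: np.random.Generator
) -> float:
    tr, te = _stratified_split(
        np.nonzero(y == 0)[0], np.nonzero(y == 1)[0], cfg.train_fraction, rng
    )
    model = fit_logistic(x[tr], y[tr], cfg.ridge_penalty)
    return auc_rank(model.decision_function(x[te]), y[te])


def search_models(
    table: FeatureTable,
    labels: CohortLabels,
    subset_size: int,
    cfg: SearchConfig,
) -> list[ModelResult]:
    """Evaluate every ``subset_size``-subset and return the ranked list.

    With ``cfg.prescreen_top`` set, subsets are first scored by one fixed
    stratified split and only the top candidates receive the full repeated
    ensemble (two-stage mode for large searches; exhaustive by default).
    """
    y_series = labels.binary()
    common = sorted(s for s in table.sample_ids if s in y_series.index)
    y = y_series.loc[common].to_numpy()
    data = table.data.loc[common]
    col_idx = {f: i for i, f in enumerate(data.columns)}
    xall = data.to_numpy(dtype=float)
    subsets_iter, _ = enumerate_subsets(table.feature_ids, subset_size)
    subsets = list(subsets_iter)
    if cfg.prescreen_top is not None and len(subsets) > cfg.prescreen_top:
        quick = []
        for si, sub in enumerate(subsets):
            xs = xall[:, [col_idx[f] for f in sub]]
            rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 11, si)))
            quick.append(_single_split_auc(xs, y, cfg, rng))
        order = np.argsort([-q for q in quick], kind="stable")
        subsets = [subsets[i] for i in order[: cfg.prescreen_top]]
    results = []
    for sub in subsets:
        xs = xall[:, [col_idx[f] for f in sub]]
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7)))
        results.append(
            evaluate_holdout_ensemble(table, labels, sub, cfg, _x=xs, _y=y, _rng=rng)
        )
    return rank_models(results)


# ---------------------------------------------------------------------------
# multimodal fusion and clinical baseline

def fuse_multimodal(
    tables: Mapping[str, FeatureTable],
    labels: CohortLabels,
    top_per_modality: Mapping[str, Sequence[ModelResult]],
    k_top: int,
    cfg: SearchConfig,
) -> list[ModelResult]:
    """Joint models from the top single-modality candidates.

    Takes the cross product of each modality's ``k_top`` best models,
    concatenates their feature sets (ids tagged ``modality:feature``) on
    the matched cohort, refits and re-ensembles, and returns the ranked
    combined leaderboard.
    """
    modalities = sorted(tables)
    if len(modalities) < 2:
        raise ValueError("fusion needs >= 2 modalities")
    ids0 = set(tables[modalities[0]].sample_ids)
    for m in modalities[1:]:
        if set(tables[m].sample_ids) != ids0:
            raise ValueError(f"sample ids of {m} do not match the matched cohort")
    for m in modalities:
        if m not in top_per_modality or not top_per_modality[m]:
            raise ValueError(f"no candidate models for modality {m}")

    joint = pd.concat(
        [
            tables[m].data.rename(columns=lambda f, m=m: f"{m}:{f}").sort_index()
            for m in modalities
        ],
        axis=1,
    )
    joint_table = FeatureTable(joint, tables[modalities[0]].modality)

    candidates = [list(top_per_modality[m])[:k_top] for m in modalities]
    results = []
    for combo in itertools.product(*candidates):
        subset: list[str] = []
        for m, res in zip(modalities, combo):
            subset.extend(f"{m}:{f}" for f in res.feature_ids)
        results.append(evaluate_holdout_ensemble(joint_table, labels, subset, cfg))
    return rank_models(results)


def clinical_baseline(
    clinical: FeatureTable, labels: CohortLabels, cfg: SearchConfig
) -> list[ModelResult]:
    """Ranked models over the clinical covariates age, PSA and PIRADS."""
    for col in CLINICAL_COLUMNS:
        if col not in clinical.feature_ids:
            raise KeyError(f"missing clinical column: {col}")
    table = clinical.select(list(CLINICAL_COLUMNS))
    results: list[ModelResult] = []
    for k in range(1, min(cfg.max_subset_size, len(CLINICAL_COLUMNS)) + 1):
        results.extend(search_models(table, labels, k, cfg))
    return rank_models(results)
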