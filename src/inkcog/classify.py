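"""Forward-stepwise logistic diagnostic models and their performance.

The diagnostic model for each task is a logistic regression on the
task's applicable features, built by forward stepwise selection with
likelihood-ratio (LR) entry and removal tests (the "Forward: LR"
procedure): at each step the candidate with the smallest LR p-value is
entered if p < ``entry_p`` (default .05); any entered variable whose LR
removal p-value exceeds ``removal_p`` (default .10) is then removed.
Ties break deterministically by candidate order.

Evaluation is in-sample (no cross-validation), matching the analysis
being reproduced; the resulting accuracy/sensitivity/specificity/AUC
are therefore optimistic estimates of out-of-sample performance and are
labelled as such wherever they are reported.  MCI is the positive
class.  AUC comes from the trapezoidal ROC (equivalently the scaled
Mann-Whitney U statistic), with a DeLong 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.utils.validation import check_is_fitted

from .errors import UndefinedMetricError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class LogisticFit:
    params: np.ndarray  # intercept first
    llf: float
    bse: np.ndarray
    pvalues: np.ndarray
    converged: bool
    separation: bool


def fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic fit (Newton/IRLS) with an intercept.

    Perfect separation is flagged rather than fatal: the coefficients of
    the final (diverging) iteration are reported with ``separation=True``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, method="newton", tol=1e-10, maxiter=100)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            res = model.fit(disp=0, method="bfgs", maxiter=500)
            separation = True
    # heuristics for quasi-separation: fitted probabilities at 0/1
    with np.errstate(over="ignore"):
        fitted = res.predict(design)
    if np.any(fitted < 1e-10) or np.any(fitted > 1 - 1e-10):
        separation = True
    return LogisticFit(
        params=np.asarray(res.params, dtype=float),
        llf=float(res.llf),
        bse=np.asarray(res.bse, dtype=float),
        pvalues=np.asarray(res.pvalues, dtype=float),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
    )


def _null_llf(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n = y.size
    return float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))


class StepwiseLogisticModel(BaseEstimator, ClassifierMixin):
    """Forward-stepwise (LR entry/removal) logistic classifier.

    Parameters
    ----------
    entry_p : float
        A candidate enters when its likelihood-ratio p-value against the
        current model is below this threshold.
    removal_p : float
        An entered variable is removed when its LR removal p-value
        exceeds this threshold.
    threshold : float
        Probability cutoff used by :meth:`predict` (0.5 keeps accuracy
        interpretable; an alternative such as the Youden point can be
        supplied here).
    pos_label : object
        The positive (patient) class.  With string labels {"HC","MCI"}
        the default picks "MCI"; with {0,1} it picks 1.

    Attributes (after fit)
    ----------------------
    selected_ : list of selected feature names, in entry order
    coef_, intercept_ : coefficients of the final model
    params_table_ : DataFrame with beta, OR, Wald 95% CI on OR, p
    fit_log_ : step-by-step record of entries/removals
    separation_ : True when (quasi-)perfect separation was flagged
    """

    def __init__(
        self,
        entry_p: float = 0.05,
        removal_p: float = 0.10,
        threshold: float = 0.5,
        pos_label=None,
        max_steps: int = 100,
    ):
        self.entry_p = entry_p
        self.removal_p = removal_p
        self.threshold = threshold
        self.pos_label = pos_label
        self.max_steps = max_steps

    # -- helpers ----------------------------------------------------------

    def _resolve_X(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), [str(c) for c in X.columns]
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X, [f"x{i}" for i in range(X.shape[1])]

    def _lr_pvalue(self, llf_full: float, llf_reduced: float) -> float:
        stat = max(0.0, 2.0 * (llf_full - llf_reduced))
        return float(sps.chi2.sf(stat, 1))

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y):
        Xa, names = self._resolve_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise UndefinedMetricError(
                f"need exactly 2 classes, got {self.classes_.tolist()}"
            )
        pos = self.pos_label
        if pos is None:
            pos = "MCI" if "MCI" in self.classes_.tolist() else self.classes_[1]
        if pos not in self.classes_:
            raise UndefinedMetricError(f"pos_label {pos!r} not among classes")
        # reorder classes_ so that classes_[1] is the positive class
        neg = [c for c in self.classes_.tolist() if c != pos][0]
        self.classes_ = np.asarray([neg, pos])
        yb = (y == pos).astype(float)
        if yb.sum() < 2 or (1 - yb).sum() < 2:
            raise UndefinedMetricError("need >= 2 subjects per class")
        if np.isnan(Xa).any():
            raise ValueError(
                "feature matrix contains missing cells; drop inapplicable "
                "columns upstream"
            )

        selected: list[int] = []
        fit_log: list[dict] = []
        current_llf = _null_llf(yb)
        current_fit: LogisticFit | None = None
        seen: set[frozenset[int]] = {frozenset()}
        separation = False

        def fit_subset(idx: list[int]) -> LogisticFit:
            if not idx:
                # intercept-only
                f = fit_logistic(np.zeros((yb.size, 0)), yb)
                return f
            return fit_logistic(Xa[:, idx], yb)

        for _ in range(self.max_steps):
            changed = False
            # entry scan
            best_j, best_p, best_fit = None, np.inf, None
            for j in range(Xa.shape[1]):
                if j in selected:
                    continue
                if np.ptp(Xa[:, j]) == 0:
                    continue  # constant column can never improve the fit
                try:
                    cand = fit_subset(selected + [j])
                except Exception:
                    continue
                p = self._lr_pvalue(cand.llf, current_llf)
                if p < best_p:
                    best_j, best_p, best_fit = j, p, cand
            if best_j is not None and best_p < self.entry_p:
                selected.append(best_j)
                current_fit, current_llf = best_fit, best_fit.llf
                separation = separation or best_fit.separation
                fit_log.append(
                    {"step": "enter", "feature": names[best_j], "p": best_p}
                )
                changed = True
            # removal scan
            removed = True
            while removed and len(selected) > 0:
                removed = False
                worst_k, worst_p, worst_fit = None, -np.inf, None
                for k in list(selected):
                    reduced = [s for s in selected if s != k]
                    red_fit = fit_subset(reduced) if reduced else None
                    red_llf = red_fit.llf if red_fit is not None else _null_llf(yb)
                    p = self._lr_pvalue(current_llf, red_llf)
                    if p > worst_p:
                        worst_k, worst_p, worst_fit = k, p, red_fit
                if worst_k is not None and worst_p > self.removal_p:
                    selected.remove(worst_k)
                    current_fit = worst_fit
                    current_llf = worst_fit.llf if worst_fit is not None else _null_llf(yb)
                    fit_log.append(
                        {"step": "remove", "feature": names[worst_k], "p": worst_p}
                    )
                    removed = True
                    changed = True
            if not changed:
                break
            state = frozenset(selected)
            if state in seen:  # entry/removal cycle; stop deterministically
                fit_log.append({"step": "cycle-stop", "feature": None, "p": None})
                break
            seen.add(state)

        if current_fit is None:
            current_fit = fit_subset(selected)
        self.selected_ = [names[j] for j in selected]
        self._selected_idx_ = list(selected)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = Xa.shape[1]
        self.intercept_ = np.asarray([current_fit.params[0]])
        self.coef_ = current_fit.params[1:][None, :]
        self.llf_ = current_fit.llf
        self.separation_ = separation or current_fit.separation
        self.fit_log_ = fit_log
        if self.separation_:
            warnings.warn(
                "perfect or quasi-perfect separation detected; coefficients "
                "and Wald intervals are unreliable",
                RuntimeWarning,
                stacklevel=2,
            )
        beta = current_fit.params[1:]
        se = current_fit.bse[1:]
        with np.errstate(over="ignore"):  # inf OR bounds under separation
            self.params_table_ = pd.DataFrame(
                {
                    "feature": self.selected_,
                    "beta": beta,
                    "or": np.exp(beta),
                    "or_ci_low": np.exp(beta - Z95 * se),
                    "or_ci_high": np.exp(beta + Z95 * se),
                    "p": current_fit.pvalues[1:],
                }
            )
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "selected_")
        Xa, _ = self._resolve_X(X)
        eta = self.intercept_[0]
        if self._selected_idx_:
            eta = eta + Xa[:, self._selected_idx_] @ self.coef_[0]
        else:
            eta = np.full(Xa.shape[0], eta)
        from scipy.special import expit

        p = expit(np.asarray(eta, dtype=float))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return np.where(p >= self.threshold, self.classes_[1], self.classes_[0])


def forward_stepwise(
    features: pd.DataFrame,
    labels: Sequence,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> StepwiseLogisticModel:
    """Functional wrapper: fit a stepwise model on a feature DataFrame."""
    return StepwiseLogisticModel(entry_p=entry_p, removal_p=removal_p).fit(
        features, np.asarray(labels)
    )


# ---------------------------------------------------------------------------
# Performance metrics


@dataclass
class DiagnosticPerformance:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    auc_ci: tuple[float, float]
    roc: list[tuple[float, float]]  # (fpr, tpr), starts (0,0), ends (1,1)
    confusion: tuple[int, int, int, int]  # tp, fn, tn, fp
    threshold: float = 0.5
    label: str = ""


def delong_auc_ci(
    scores: np.ndarray, y: np.ndarray, confidence: float = 0.95
) -> tuple[float, float, float]:
    """(auc, ci_low, ci_high) by DeLong's method.

    ``y`` is boolean (True = positive).  Uses the structural-component
    formulation with midranks for ties.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=bool)
    pos = scores[y]
    neg = scores[~y]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise UndefinedMetricError("DeLong CI needs both classes present")
    # placement values via midranks
    all_s = np.concatenate([pos, neg])
    rank_all = sps.rankdata(all_s)
    rank_pos = sps.rankdata(pos)
    rank_neg = sps.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n  # per-positive components
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m  # per-negative components
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = sps.norm.ppf(0.5 + confidence / 2)
    return auc, max(0.0, auc - z * se), min(1.0, auc + z * se)


def classify_metrics(
    probabilities: Sequence[float],
    labels: Sequence,
    threshold: float = 0.5,
    pos_label="MCI",
    label: str = "",
) -> DiagnosticPerformance:
    """Confusion-matrix metrics plus trapezoidal AUC with a DeLong CI.

    MCI (the patient group) is the positive class: sensitivity is the
    true-positive rate among MCI, specificity the true-negative rate
    among HC.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels)
    yb = y == pos_label if y.dtype.kind in ("U", "S", "O") else y.astype(bool)
    if yb.all() or not yb.any():
        raise UndefinedMetricError("labels contain a single class; metrics undefined")
    pred = p >= threshold
    tp = int(np.sum(pred & yb))
    fn = int(np.sum(~pred & yb))
    tn = int(np.sum(~pred & ~yb))
    fp = int(np.sum(pred & ~yb))
    fpr, tpr, _ = roc_curve(yb.astype(int), p, drop_intermediate=False)
    auc, lo, hi = delong_auc_ci(p, yb)
    roc = list(zip(fpr.tolist(), tpr.tolist()))
    # trapezoidal area over the empirical ROC equals the DeLong point
    # estimate; keep the trapezoid as the reported value
    auc_trap = float(_trapezoid_auc(fpr, tpr))
    return DiagnosticPerformance(
        accuracy=(tp + tn) / (tp + fn + tn + fp),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=auc_trap,
        auc_ci=(lo, hi),
        roc=roc,
        confusion=(tp, fn, tn, fp),
        threshold=threshold,
        label=label,
    )


def task_average_performance(
    performances: dict[str, DiagnosticPerformance],
    task_ids: Sequence[str],
) -> tuple[float, float]:
    """Unweighted mean (sensitivity, specificity) over the named tasks,
    rounded to 3 decimals."""
    if not task_ids:
        raise ValueError("need at least one task id")
    missing = [t for t in task_ids if t not in performances]
    if missing:
        raise KeyError(f"unknown task ids: {missing}")
    sens = float(np.mean([performances[t].sensitivity for t in task_ids]))
    spec = float(np.mean([performances[t].specificity for t in task_ids]))
    return round(sens, 3), round(spec, 3)
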