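"""Forward sequential feature selection with ridge logistic regression.

The discrimination machinery: a greedy forward selector wrapped around an
L2-penalized logistic regression, evaluated by stratified k-fold
cross-validation, with a Nagelkerke goodness-of-fit statistic and McNemar
comparison between competing models scored on the same subjects.

:class:`SFSRidgeClassifier` is a scikit-learn estimator (``fit`` /
``predict`` / ``predict_proba``, ``get_params`` / ``set_params``, fitted
attributes with a trailing underscore) and composes with sklearn model
selection;  :func:`fit_sfs_logistic` is a thin DataFrame-facing wrapper.

Design notes
------------
* Features are z-scored with training-fold statistics only; the reported
  coefficients come from a full-data refit of the selected set.
* Selection adds, at each step, the candidate with the highest mean CV score
  (log-loss by default — a proper, continuous scoring rule; accuracy
  selectable), stopping at ``max_features`` or when no candidate strictly
  improves the score.  Ties break by candidate order, so the path is
  deterministic given (data, seed).
* The reported cross-validated accuracy and the pooled out-of-fold
  predictions are *nested*: the forward selection is re-run from scratch
  inside every training fold before predicting its held-out fold.  Reusing
  the selection folds for evaluation would inflate accuracy well above
  chance even on pure noise (selection bias); nested evaluation is unbiased,
  which the null-calibration tests verify.  The (optimistic) score of the
  full-data selection path is kept separately as ``selection_cv_score_``.
* The inner loops use a dedicated Newton (IRLS) ridge-logistic solver —
  the same penalized objective as scikit-learn's ``LogisticRegression``
  (intercept unpenalized) without per-call validation overhead, which makes
  nested selection affordable; the reported full-data refit stays with
  scikit-learn.
* The goodness-of-fit pseudo-R² is Nagelkerke's, computed from an
  *unpenalized* maximum-likelihood refit of the selected set: the statistic
  is defined on maximized likelihoods, a penalized likelihood biases it
  downward, and only the unpenalized version reaches 1.0 under perfect
  separation.  McFadden's variant is selectable.
* McNemar's test uses the pooled out-of-fold (cross-validated) predictions —
  training predictions would be optimistic and inconsistent with reporting
  CV accuracy.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "SFSRidgeClassifier",
    "SFSModelResult",
    "McNemarResult",
    "fit_sfs_logistic",
    "pseudo_r2",
    "mcnemar_compare",
    "run_model_grid",
    "GridResult",
]

_EPS = 1e-12


def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def pseudo_r2(y_true, prob, kind: str = "nagelkerke") -> float:
    """Pseudo-R² of a binary model from its predicted probabilities.

    Nagelkerke (default): ``(1 - (L0/L1)^(2/n)) / (1 - L0^(2/n))``, bounded
    in [0, 1], reaching 1 under perfect prediction.  ``kind="mcfadden"``
    gives ``1 - logL1/logL0``.
    """
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(prob, dtype=float)
    if y.ndim != 1 or y.shape != p.shape:
        raise ValueError("y_true and prob must be 1-D and aligned")
    base = y.mean()
    if base in (0.0, 1.0):
        raise ValueError("degenerate single-class data")
    n = len(y)
    ll1 = _log_likelihood(y, p)
    ll0 = _log_likelihood(y, np.full(n, base))
    if kind == "mcfadden":
        return float(np.clip(1.0 - ll1 / ll0, 0.0, 1.0))
    if kind != "nagelkerke":
        raise ValueError(f"unknown pseudo-R² kind {kind!r}")
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    r2_max = 1.0 - np.exp(2.0 * ll0 / n)
    return float(np.clip(cox_snell / r2_max, 0.0, 1.0))


def _make_lr(C: float) -> LogisticRegression:
    # default penalty is L2; C is its inverse strength
    return LogisticRegression(C=C, solver="lbfgs", max_iter=1000)


def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (other - mu) / sd


def _fit_ridge_newton(X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    """Newton/IRLS fit of L2-penalized logistic regression.

    Minimizes the sum of cross-entropy losses plus ``1/(2C) * ||w||²`` with
    an unpenalized intercept (scikit-learn's objective).  Returns the
    coefficient vector with the intercept last.
    """
    from scipy.special import expit

    n, d = X.shape
    Xb = np.hstack([X, np.ones((n, 1))])
    w = np.zeros(d + 1)
    lam = 1.0 / C
    pen = np.ones(d + 1)
    pen[d] = 0.0
    for _ in range(30):
        p = expit(Xb @ w)
        g = Xb.T @ (p - y) + lam * pen * w
        wgt = np.maximum(p * (1.0 - p), 1e-10)
        H = (Xb * wgt[:, None]).T @ Xb
        H[np.diag_indices(d + 1)] += lam * pen
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            H[np.diag_indices(d + 1)] += 1e-8
            step = np.linalg.solve(H, g)
        w -= step
        if np.abs(step).max() < 1e-9:
            break
    return w


class SFSRidgeClassifier(ClassifierMixin, BaseEstimator):
    """Greedy forward feature selection under ridge logistic regression.

    Parameters
    ----------
    max_features : int
        Cap on the number of selected features (selection may stop earlier
        when no candidate improves the CV score).
    C : float
        Inverse L2 regularization strength of the logistic model (the
        exposed "regularization strength parameter"; 1.0 default).
    cv : int
        Number of stratified folds.
    scoring : {"neg_log_loss", "accuracy"}
        Greedy selection criterion, averaged over folds.  Log-loss (default)
        is a proper scoring rule and is continuous, so the greedy path is far
        better behaved than on 0/1 accuracy, whose plateaus stall the search
        and let chance features win steps; reported evaluation is always
        accuracy.
    random_state : int or None
        Fixes the fold assignment (shuffled stratified folds).

    Attributes
    ----------
    selected_ : list of int -- column indices in order of addition.
    support_ : bool array of shape (n_features_in_,).
    cv_scores_path_ : list of float -- mean CV score after each addition.
    selection_cv_score_ : float -- score of the full-data selection path
        (optimistic; for reference only).
    cv_accuracy_ : float -- mean nested out-of-fold accuracy (unbiased).
    fold_accuracies_ : array -- per-fold nested accuracy.
    oof_pred_, oof_proba_ : pooled nested out-of-fold predictions.
    fold_assignment_ : array -- fold index per subject.
    pseudo_r2_ : float -- Nagelkerke R² of the unpenalized refit.
    coef_, intercept_ : full-data ridge refit on standardized features.
    """

    def __init__(
        self,
        max_features: int = 6,
        C: float = 1.0,
        cv: int = 10,
        scoring: str = "neg_log_loss",
        random_state: int | None = None,
        tol: float = 1e-9,
    ):
        self.max_features = max_features
        self.C = C
        self.cv = cv
        self.scoring = scoring
        self.random_state = random_state
        self.tol = tol

    # -- internals ---------------------------------------------------------

    def _fold_scores(
        self, X: np.ndarray, y: np.ndarray, cols: list[int], folds
    ) -> np.ndarray:
        from scipy.special import expit

        scores = np.empty(len(folds))
        for k, (tr, te) in enumerate(folds):
            Xtr, Xte = _standardize(X[np.ix_(tr, cols)], X[np.ix_(te, cols)])
            w = _fit_ridge_newton(Xtr, y[tr], self.C)
            z = Xte @ w[:-1] + w[-1]
            if self.scoring == "accuracy":
                scores[k] = ((z > 0).astype(int) == y[te]).mean()
            elif self.scoring == "neg_log_loss":
                scores[k] = _log_likelihood(y[te], expit(z)) / len(te)
            else:
                raise ValueError(f"unknown scoring {self.scoring!r}")
        return scores

    def _forward_select(
        self, X: np.ndarray, y: np.ndarray, usable: list[int], folds
    ) -> tuple[list[int], list[float]]:
        selected: list[int] = []
        path: list[float] = []
        best = -np.inf
        remaining = list(usable)
        while remaining and len(selected) < self.max_features:
            cand_scores = [
                self._fold_scores(X, y, selected + [j], folds).mean()
                for j in remaining
            ]
            k_best = int(np.argmax(cand_scores))  # ties -> first in order
            if cand_scores[k_best] <= best + self.tol and selected:
                break
            best = cand_scores[k_best]
            selected.append(remaining.pop(k_best))
            path.append(best)
        return selected, path

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        classes, y_enc = np.unique(y, return_inverse=True)
        if len(classes) != 2:
            raise ValueError(f"binary classification only, got {len(classes)} classes")
        self.classes_ = classes
        n, p = X.shape
        counts = np.bincount(y_enc)
        if counts.min() < self.cv:
            raise ValueError(
                f"smallest group has {counts.min()} subjects; "
                f"need >= {self.cv} for {self.cv}-fold stratification"
            )

        usable = [j for j in range(p) if np.ptp(X[:, j]) > 0]
        if len(usable) < p:
            warnings.warn(
                f"dropping {p - len(usable)} constant feature(s) from the "
                "candidate set",
                stacklevel=2,
            )
        if not usable:
            raise ValueError("no non-constant candidate features")

        skf = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )
        folds = list(skf.split(X, y_enc))
        self.fold_assignment_ = np.empty(n, dtype=int)
        for k, (_, te) in enumerate(folds):
            self.fold_assignment_[te] = k

        # reported selected set: forward path on the full data
        selected, path = self._forward_select(X, y_enc, usable, folds)
        self.selected_ = selected
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[selected] = True
        self.cv_scores_path_ = path
        self.selection_cv_score_ = path[-1] if path else float("nan")

        # nested out-of-fold predictions: the selection is redone inside each
        # training fold, so the pooled accuracy is free of selection bias
        from scipy.special import expit

        fold_acc = np.empty(len(folds))
        oof_pred = np.empty(n, dtype=int)
        oof_proba = np.empty(n)
        for k, (tr, te) in enumerate(folds):
            ytr = y_enc[tr]
            inner = StratifiedKFold(
                n_splits=max(min(self.cv, int(np.bincount(ytr).min())), 2),
                shuffle=True,
                random_state=self.random_state,
            )
            usable_tr = [j for j in usable if np.ptp(X[tr, j]) > 0]
            inner_folds = list(inner.split(X[tr], ytr))
            sel_k, _ = self._forward_select(X[tr], ytr, usable_tr, inner_folds)
            Xtr, Xte = _standardize(X[np.ix_(tr, sel_k)], X[np.ix_(te, sel_k)])
            w = _fit_ridge_newton(Xtr, ytr, self.C)
            z = Xte @ w[:-1] + w[-1]
            oof_pred[te] = (z > 0).astype(int)
            oof_proba[te] = expit(z)
            fold_acc[k] = (oof_pred[te] == y_enc[te]).mean()
        self.fold_accuracies_ = fold_acc
        self.cv_accuracy_ = float(fold_acc.mean())
        self.oof_pred_ = classes[oof_pred]
        self.oof_proba_ = oof_proba

        # full-data ridge refit (reported model) on standardized features
        Xs, _ = _standardize(X[:, selected], X[:, selected])
        self._mu_ = X[:, selected].mean(axis=0)
        sd = X[:, selected].std(axis=0)
        sd[sd == 0] = 1.0
        self._sd_ = sd
        final = _make_lr(self.C).fit(Xs, y_enc)
        self.coef_ = final.coef_
        self.intercept_ = final.intercept_
        self._final_ = final

        # goodness of fit from the unpenalized ML refit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mle = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000).fit(
                Xs, y_enc
            )
            p1 = mle.predict_proba(Xs)[:, 1]
        self.pseudo_r2_ = pseudo_r2(y_enc, p1)
        self.pseudo_r2_mcfadden_ = pseudo_r2(y_enc, p1, kind="mcfadden")
        # likelihood-ratio test of the refit against the intercept-only model
        ll1 = _log_likelihood(y_enc, p1)
        ll0 = _log_likelihood(y_enc, np.full(n, y_enc.mean()))
        from scipy import stats as sps

        self.lr_pvalue_ = float(sps.chi2.sf(2 * (ll1 - ll0), df=max(len(selected), 1)))
        return self

    def _transform_selected(self, X) -> np.ndarray:
        return (X[:, self.selected_] - self._mu_) / self._sd_

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self._final_.predict_proba(self._transform_selected(X))

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        idx = self._final_.predict(self._transform_selected(X))
        return self.classes_[idx]


# ---------------------------------------------------------------------------
# DataFrame-facing wrapper and results

@dataclass
class SFSModelResult:
    group_pair: tuple[str, str]
    candidates: list[str]
    selected: list[str]
    fold_accuracies: np.ndarray
    cv_accuracy: float
    predictions: pd.DataFrame  # subject_id, y_true, y_pred (out-of-fold)
    pseudo_r2: float
    lr_pvalue: float
    coefficients: dict[str, float]
    seed: int | None
    fold_assignment: np.ndarray
    estimator: SFSRidgeClassifier = field(repr=False, default=None)


@dataclass
class McNemarResult:
    both_correct: int
    only_a_correct: int
    only_b_correct: int
    both_wrong: int
    statistic: float
    p: float
    method: str  # "exact_binomial" or "chi2_cc"

    @property
    def n(self) -> int:
        return self.both_correct + self.only_a_correct + self.only_b_correct + self.both_wrong


def fit_sfs_logistic(
    table: pd.DataFrame,
    pair: tuple[str, str],
    candidates: list[str],
    *,
    max_k: int = 6,
    ridge_strength: float = 1.0,
    folds: int = 10,
    seed: int | None = 0,
    scoring: str = "neg_log_loss",
    group_col: str = "group",
    subject_col: str = "subject_id",
) -> SFSModelResult:
    """Forward-SFS ridge logistic model for one group pair.

    ``ridge_strength`` is the exposed regularization strength parameter of
    the logistic model (the estimator's ``C``; 1.0 default).
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    missing = [c for c in candidates if c not in table.columns]
    if missing:
        raise ValueError(f"candidates not in table: {missing}")
    d = table[table[group_col].isin(pair)].dropna(subset=list(candidates))
    X = d[candidates].to_numpy(dtype=float)
    y = d[group_col].to_numpy()
    est = SFSRidgeClassifier(
        max_features=max_k, C=ridge_strength, cv=folds, scoring=scoring,
        random_state=seed,
    ).fit(X, y)
    preds = pd.DataFrame(
        {
            "subject_id": d[subject_col].to_numpy(),
            "y_true": y,
            "y_pred": est.oof_pred_,
        }
    )
    return SFSModelResult(
        group_pair=tuple(pair),
        candidates=list(candidates),
        selected=[candidates[j] for j in est.selected_],
        fold_accuracies=est.fold_accuracies_,
        cv_accuracy=est.cv_accuracy_,
        predictions=preds,
        pseudo_r2=est.pseudo_r2_,
        lr_pvalue=est.lr_pvalue_,
        coefficients={
            candidates[j]: float(est.coef_[0][k])
            for k, j in enumerate(est.selected_)
        },
        seed=seed,
        fold_assignment=est.fold_assignment_,
        estimator=est,
    )


def mcnemar_compare(a: SFSModelResult, b: SFSModelResult) -> McNemarResult:
    """McNemar test on two models' pooled cross-validated predictions.

    Builds the 2x2 correct/incorrect table over the shared subjects; exact
    two-sided binomial on the discordant pairs when they number < 25,
    otherwise chi-square with continuity correction.
    """
    pa = a.predictions.set_index("subject_id")
    pb = b.predictions.set_index("subject_id")
    if set(pa.index) != set(pb.index):
        raise ValueError("models were scored on different subjects")
    pb = pb.loc[pa.index]
    ok_a = (pa["y_pred"] == pa["y_true"]).to_numpy()
    ok_b = (pb["y_pred"] == pb["y_true"]).to_numpy()
    both = int((ok_a & ok_b).sum())
    only_a = int((ok_a & ~ok_b).sum())
    only_b = int((~ok_a & ok_b).sum())
    neither = int((~ok_a & ~ok_b).sum())
    table = [[both, only_a], [only_b, neither]]
    exact = (only_a + only_b) < 25
    if only_a + only_b == 0:
        stat, p, method = 0.0, 1.0, "exact_binomial"
    else:
        res = _sm_mcnemar(table, exact=exact, correction=True)
        stat, p = float(res.statistic), float(res.pvalue)
        method = "exact_binomial" if exact else "chi2_cc"
    return McNemarResult(both, only_a, only_b, neither, stat, min(p, 1.0), method)


# ---------------------------------------------------------------------------
# model grid

@dataclass
class GridResult:
    models: dict[tuple[tuple[str, str], tuple[str, ...]], SFSModelResult]
    comparisons: pd.DataFrame  # pair, blocks_a, blocks_b, discordant, p, method

    def summary(self) -> pd.DataFrame:
        rows = []
        for (pair, blocks), m in self.models.items():
            rows.append(
                {
                    "group_a": pair[0],
                    "group_b": pair[1],
                    "blocks": "+".join(blocks),
                    "r2": m.pseudo_r2,
                    "p": m.lr_pvalue,
                    "cv_accuracy": m.cv_accuracy,
                    "selected": ", ".join(m.selected),
                }
            )
        return pd.DataFrame(rows)


def _block_combinations(blocks: dict[str, list[str]]) -> list[tuple[str, ...]]:
    names = list(blocks)
    combos = []
    for r in range(1, len(names) + 1):
        combos.extend(itertools.combinations(names, r))
    return combos


def run_model_grid(
    table: pd.DataFrame,
    blocks: dict[str, list[str]],
    *,
    pairs: list[tuple[str, str]] | None = None,
    demographics: list[str] = ["sex", "age", "education"],
    hc_group: str = "HC",
    max_k: int = 6,
    ridge_strength: float = 1.0,
    folds: int = 10,
    seed: int = 0,
    group_col: str = "group",
) -> GridResult:
    """One SFS model per (group pair, feature-block combination).

    Pairs involving the control group run with the speech block only; patient
    pairs run every non-empty block combination (7 for three blocks).
    Demographic features join every model's candidate set.  All pairwise
    McNemar comparisons between a pair's models are emitted.
    """
    groups = sorted(table[group_col].unique())
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    missing_blocks = {
        name: [c for c in cols if c not in table.columns]
        for name, cols in blocks.items()
    }
    missing_blocks = {k: v for k, v in missing_blocks.items() if v}
    if missing_blocks:
        raise ValueError(f"block columns missing from table: {missing_blocks}")

    models: dict[tuple[tuple[str, str], tuple[str, ...]], SFSModelResult] = {}
    rows = []
    for pair in pairs:
        if hc_group in pair:
            combos = [("speech",)] if "speech" in blocks else []
        else:
            combos = _block_combinations(blocks)
        for combo in combos:
            candidates = list(demographics)
            for name in combo:
                candidates.extend(c for c in blocks[name] if c not in candidates)
            models[(pair, combo)] = fit_sfs_logistic(
                table,
                pair,
                candidates,
                max_k=max_k,
                ridge_strength=ridge_strength,
                folds=folds,
                seed=seed,
                group_col=group_col,
            )
        pair_combos = [c for (p, c) in models if p == pair]
        for ca, cb in itertools.combinations(pair_combos, 2):
            mc = mcnemar_compare(models[(pair, ca)], models[(pair, cb)])
            rows.append(
                {
                    "group_a": pair[0],
                    "group_b": pair[1],
                    "blocks_a": "+".join(ca),
                    "blocks_b": "+".join(cb),
                    "only_a_correct": mc.only_a_correct,
                    "only_b_correct": mc.only_b_correct,
                    "p": mc.p,
                    "method": mc.method,
                }
            )
    return GridResult(models=models, comparisons=pd.DataFrame(rows))
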