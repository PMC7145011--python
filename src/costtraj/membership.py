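"""Explaining latent-group membership from covariates.

A multinomial logistic regression links patient- and treatment-associated
factors to latent trajectory-group membership.  Because group assignment is
probabilistic, each patient enters the likelihood as J pseudo-observations
— one per group, weighted by the posterior membership probability w_ij —
so classification uncertainty propagates into the coefficients:

    loglik(B) = sum_i sum_j w_ij log P_j(x_i; B),

with P the softmax probabilities against a reference group.  The weighted
log-likelihood stays concave, so Newton-Raphson converges to the unique
maximum.  Inference is by Wald z-tests on the observed-information standard
errors; effect sizes are reported as odds ratios with 95% confidence
intervals.  Model reduction is backward elimination on AIC, dropping whole
covariates (all their J-1 coefficients jointly).  Overall fit is summarised
by McFadden's pseudo-R-squared and the classification accuracy against the
modal-group null model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator
from statsmodels.stats.proportion import proportion_confint


def build_design(patients: pd.DataFrame, covariates: list[str]):
    """Expand covariates into a design matrix with intercept.

    Numeric and boolean columns map to single columns; object/categorical
    columns expand into dummies against their first (sorted) level.  Returns
    ``(X, names, groups)`` where ``groups`` maps each covariate to its
    column indices, so elimination can drop covariates wholesale.
    """
    cols = [np.ones(len(patients))]
    names = ["intercept"]
    groups: dict[str, list[int]] = {}
    for cov in covariates:
        x = patients[cov]
        idx = []
        if x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype):
            levels = sorted(x.unique(), key=str)
            for lev in levels[1:]:
                idx.append(len(names))
                names.append(f"{cov}[{lev}]")
                cols.append((x == lev).to_numpy(dtype=float))
        else:
            idx.append(len(names))
            names.append(cov)
            cols.append(x.to_numpy(dtype=float))
        groups[cov] = idx
    X = np.column_stack(cols)
    return X, names, groups


class PosteriorWeightedMultinomial(BaseEstimator):
    """Multinomial logit with posterior-probability observation weights.

    Parameters
    ----------
    reference : int
        Index of the reference group (conventionally the largest,
        lowest-cost trajectory group).
    tol : convergence tolerance on the log-likelihood change.
    max_iter : Newton iteration cap.

    ``fit(X, W)`` accepts a design matrix X (n, p) — typically from
    :func:`build_design`, including the intercept — and either an (n, J)
    posterior matrix or a length-n hard label vector.  With degenerate 0/1
    weights the fit coincides with ordinary multinomial regression on the
    labels.
    """

    def __init__(self, reference: int = 0, tol: float = 1e-8, max_iter: int = 200):
        self.reference = reference
        self.tol = tol
        self.max_iter = max_iter

    # -- likelihood machinery ----------------------------------------------

    @staticmethod
    def _probs(X, B, reference, J):
        """Softmax probabilities (n, J) with the reference row fixed at 0."""
        n = X.shape[0]
        eta = np.zeros((n, J))
        others = [j for j in range(J) if j != reference]
        eta[:, others] = X @ B.T
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def _loglik(self, X, W, B, J):
        P = self._probs(X, B, self.reference, J)
        return float((W * np.log(np.maximum(P, 1e-300))).sum())

    def fit(self, X, W, feature_names=None, sample_weight=None):
        X = np.asarray(X, dtype=float)
        W = np.asarray(W)
        if W.ndim == 1:  # hard labels
            J = int(W.max()) + 1
            hard = np.zeros((len(W), J))
            hard[np.arange(len(W)), W.astype(int)] = 1.0
            W = hard
        W = W.astype(float)
        if not np.allclose(W.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("posterior weight rows must sum to 1")
        if sample_weight is not None:
            W = W * np.asarray(sample_weight, dtype=float)[:, None]
        n, p = X.shape
        J = W.shape[1]
        if not 0 <= self.reference < J:
            raise ValueError(f"reference group {self.reference} out of range")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("rank-deficient design matrix")
        self.feature_names_ = (
            list(feature_names) if feature_names is not None
            else [f"x{k}" for k in range(p)]
        )

        others = [j for j in range(J) if j != self.reference]
        B = np.zeros((J - 1, p))
        ll = self._loglik(X, W, B, J)
        for _ in range(self.max_iter):
            P = self._probs(X, B, self.reference, J)
            tot = W.sum(axis=1)
            grad = ((W[:, others] - tot[:, None] * P[:, others]).T @ X).ravel()
            # Hessian blocks: -sum_i tot_i P_ij (delta_jk - P_ik) x x^T
            H = np.zeros(((J - 1) * p, (J - 1) * p))
            for aj, j in enumerate(others):
                for ak, k in enumerate(others):
                    wgt = tot * P[:, j] * ((j == k) - P[:, k])
                    H[aj * p:(aj + 1) * p, ak * p:(ak + 1) * p] = X.T @ (wgt[:, None] * X)
            try:
                step = np.linalg.solve(H + 1e-12 * np.eye(H.shape[0]), grad)
            except np.linalg.LinAlgError:
                raise ValueError("singular information matrix; possible "
                                 "perfect separation or collinearity")
            step = step.reshape(J - 1, p)
            scale, ll_new = 1.0, None
            for _ in range(50):
                ll_new = self._loglik(X, W, B + scale * step, J)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            B = B + scale * step
            if ll_new - ll < self.tol:
                ll = ll_new
                break
            ll = ll_new
        if np.abs(B).max() > 30:
            worst = np.unravel_index(np.abs(B).argmax(), B.shape)
            raise ValueError(
                "diverging coefficient for covariate "
                f"{self.feature_names_[worst[1]]!r}: likely perfect separation")

        self.n_groups_ = J
        self.classes_ = np.arange(J)
        self.coef_ = B
        self.loglik_ = ll
        self.n_parameters_ = (J - 1) * p
        self.aic_ = -2 * ll + 2 * self.n_parameters_
        # observed information at the optimum
        P = self._probs(X, B, self.reference, J)
        tot = W.sum(axis=1)
        H = np.zeros(((J - 1) * p, (J - 1) * p))
        for aj, j in enumerate(others):
            for ak, k in enumerate(others):
                wgt = tot * P[:, j] * ((j == k) - P[:, k])
                H[aj * p:(aj + 1) * p, ak * p:(ak + 1) * p] = X.T @ (wgt[:, None] * X)
        self.cov_ = np.linalg.inv(H)
        self.bse_ = np.sqrt(np.diag(self.cov_)).reshape(J - 1, p)
        self.zvalues_ = self.coef_ / self.bse_
        self.pvalues_ = 2 * norm.sf(np.abs(self.zvalues_))

        # intercept-only null model: predicted probabilities are the column
        # means of W, so its log-likelihood has a closed form
        pbar = np.maximum(W.sum(axis=0) / W.sum(), 1e-300)
        self.null_probs_ = pbar
        self.loglik_null_ = float(W.sum() * (pbar * np.log(pbar)).sum())
        self.mcfadden_r2_ = 1.0 - self.loglik_ / self.loglik_null_
        self.other_groups_ = others
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self._probs(np.asarray(X, float), self.coef_, self.reference,
                           self.n_groups_)

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Tidy odds-ratio table: one row per (group, covariate column)."""
        z = norm.ppf(1 - alpha / 2)
        rows = []
        for aj, j in enumerate(self.other_groups_):
            for k, name in enumerate(self.feature_names_):
                b, se = self.coef_[aj, k], self.bse_[aj, k]
                rows.append({
                    "group": j, "covariate": name, "coef": b, "se": se,
                    "odds_ratio": np.exp(b),
                    "ci_low": np.exp(b - z * se), "ci_high": np.exp(b + z * se),
                    "z": self.zvalues_[aj, k], "pvalue": self.pvalues_[aj, k],
                    "significant": self.pvalues_[aj, k] <= 0.05,
                })
        return pd.DataFrame(rows)


def fit_weighted_multinomial(patients: pd.DataFrame, posterior: np.ndarray,
                             covariates: list[str], reference: int = 0,
                             **kwargs) -> PosteriorWeightedMultinomial:
    """Fit the posterior-weighted multinomial on named covariates."""
    X, names, groups = build_design(patients, covariates)
    model = PosteriorWeightedMultinomial(reference=reference, **kwargs)
    model.fit(X, posterior, feature_names=names)
    model.design_ = X
    model.covariate_groups_ = groups
    model.covariates_ = list(covariates)
    return model


def backward_eliminate(patients: pd.DataFrame, posterior: np.ndarray,
                       candidates: list[str], reference: int = 0,
                       **kwargs) -> PosteriorWeightedMultinomial:
    """Backward elimination on AIC, dropping whole covariates.

    At each round the covariate whose removal most decreases AIC is dropped
    (ties break by declaration order); the search stops when no removal
    improves AIC.  An empty candidate set yields the intercept-only model.
    """
    retained = list(candidates)
    current = fit_weighted_multinomial(patients, posterior, retained,
                                       reference=reference, **kwargs)
    while retained:
        best_aic, best_cov, best_model = current.aic_, None, None
        for cov in retained:
            trial = [c for c in retained if c != cov]
            model = fit_weighted_multinomial(patients, posterior, trial,
                                             reference=reference, **kwargs)
            if model.aic_ < best_aic - 1e-12:
                best_aic, best_cov, best_model = model.aic_, cov, model
        if best_cov is None:
            break
        retained.remove(best_cov)
        current = best_model
    current.retained_covariates_ = retained
    return current


def wilson_interval(successes: int, n: int, alpha: float = 0.05):
    """Wilson score confidence interval for a binomial proportion."""
    lo, hi = proportion_confint(successes, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def classification_accuracy(model: PosteriorWeightedMultinomial,
                            X: np.ndarray, labels: np.ndarray,
                            ci_method: str = "wilson") -> dict:
    """Accuracy of the fitted model against MAP labels, with 95% CI.

    The null comparator always predicts the modal group; its accuracy is the
    modal group's share.  ``ci_method`` is ``'wilson'`` (default; reproduces
    the asymmetric intervals typical near small proportions) or ``'beta'``
    for Clopper-Pearson.
    """
    labels = np.asarray(labels, dtype=int)
    pred = model.predict(np.asarray(X, dtype=float))
    n = len(labels)
    correct = int((pred == labels).sum())
    counts = np.bincount(labels, minlength=model.n_groups_)
    method = {"wilson": "wilson", "beta": "beta"}[ci_method]
    lo, hi = proportion_confint(correct, n, alpha=0.05, method=method)
    return {
        "accuracy": correct / n,
        "ci": (float(lo), float(hi)),
        "n": n,
        "null_accuracy": counts.max() / n,
        "modal_group": int(counts.argmax()),
    }


def null_model_accuracy(group_sizes) -> float:
    """Accuracy of always predicting the modal group, from group sizes."""
    sizes = np.asarray(group_sizes, dtype=float)
    return float(sizes.max() / sizes.sum())
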