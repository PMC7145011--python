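"""Group-based trajectory modelling with zero-inflated Poisson mixtures.

The model clusters patients by the shape of their monthly cost profile over
the last year of life.  Each latent group ``j`` follows its own trajectory:
for month ``m`` (mapped to scaled time ``t_m = (12 - m) / 11`` so that time
increases toward death) the cost count of a group-``j`` patient is

    y_im ~ ZIP(lambda_j(t_m), p_j(t_m)),
    log lambda_j(t) = sum_k beta_jk t^k,
    logit p_j(t)    = sum_k gamma_jk t^k   (or a per-group constant),

independently across observed months given the group.  The zero-inflation
component absorbs the excess of zero-cost months that a plain Poisson cannot
produce.  Masked (pre-diagnosis) months contribute nothing to the
likelihood.

Estimation is by expectation-maximisation over two layers of latent
structure: group membership and, within each zero count, the structural-zero
indicator.  Both M-step blocks reduce to 12-row weighted GLMs (Poisson with
log link for the rates, binomial with logit link for the zero mass), solved
by damped Newton ascent, so each EM sweep is exact and the observed-data
log-likelihood is non-decreasing.

Groups are relabelled in decreasing order of mean fitted cost, which makes
refits with the same seed bit-reproducible.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from scipy.special import expit, gammaln, logsumexp
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.utils import check_random_state

from .ledger import N_MONTHS, MonthlyCostMatrix

_CLIP = 30.0  # bound on linear predictors; exp(30) is far beyond any cost


def time_basis(degree: int, n_months: int = N_MONTHS) -> np.ndarray:
    """Polynomial basis (n_months, degree+1) on scaled time t in [0, 1].

    Month 1 (the last before death) maps to t = 1, month 12 to t = 0, so
    time increases toward death.
    """
    m = np.arange(1, n_months + 1)
    t = (n_months - m) / (n_months - 1.0)
    return np.vander(t, degree + 1, increasing=True)


def zip_logpmf(y, lam, p):
    """Log-pmf of the zero-inflated Poisson.

    P(0) = p + (1-p) e^{-lam};  P(y>0) = (1-p) Poisson(y; lam).
    Broadcasts over array arguments; ``y`` must hold non-negative integers.
    """
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    p = np.asarray(p, dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(y.dtype, np.integer):
        if not np.allclose(y, np.round(y)):
            raise ValueError("counts must be integers")
        y = np.round(y).astype(np.int64)
    if (lam <= 0).any():
        raise ValueError("rates must be positive")
    if (p < 0).any() or (p >= 1).any():
        raise ValueError("zero-inflation probability must lie in [0, 1)")
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
    lp_zero = np.logaddexp(np.broadcast_to(log_p, np.broadcast_shapes(log_p.shape, lam.shape)),
                           np.log1p(-p) - lam)
    lp_pos = np.log1p(-p) + y * np.log(lam) - lam - gammaln(y + 1.0)
    return np.where(y == 0, lp_zero, lp_pos)


def _newton_poisson(B: np.ndarray, s: np.ndarray, w: np.ndarray,
                    beta: np.ndarray, max_iter: int = 60, tol: float = 1e-10):
    """Maximise sum_m [s_m eta_m - w_m exp(eta_m)], eta = B beta.

    Weighted Poisson log-link score equations collapsed to one row per
    month; Newton with step halving guarantees ascent.
    """
    def q(b):
        eta = np.clip(B @ b, -_CLIP, _CLIP)
        return float(s @ eta - w @ np.exp(eta))

    q0 = q(beta)
    for _ in range(max_iter):
        eta = np.clip(B @ beta, -_CLIP, _CLIP)
        mu = w * np.exp(eta)
        grad = B.T @ (s - mu)
        hess = B.T @ (mu[:, None] * B)
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(40):
            q1 = q(beta + scale * step)
            if q1 >= q0:
                break
            scale *= 0.5
        else:
            break
        beta = beta + scale * step
        if q1 - q0 < tol * (abs(q0) + 1.0):
            q0 = q1
            break
        q0 = q1
    return beta


def _newton_binomial(B: np.ndarray, a: np.ndarray, b: np.ndarray,
                     gamma: np.ndarray, max_iter: int = 60, tol: float = 1e-10):
    """Maximise sum_m [a_m log sigma(eta_m) + b_m log(1 - sigma(eta_m))].

    ``a`` are structural-zero weights, ``b`` Poisson-process weights per
    month.  Newton with step halving; degenerate all-zero ``a`` drifts the
    intercept toward the clipped boundary, which is harmless.
    """
    def q(g):
        eta = np.clip(B @ g, -_CLIP, _CLIP)
        return float(a @ (-np.logaddexp(0.0, -eta)) + b @ (-np.logaddexp(0.0, eta)))

    q0 = q(gamma)
    for _ in range(max_iter):
        eta = np.clip(B @ gamma, -_CLIP, _CLIP)
        p = expit(eta)
        grad = B.T @ (a - (a + b) * p)
        wt = (a + b) * p * (1.0 - p)
        hess = B.T @ (wt[:, None] * B)
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(len(gamma)), grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(40):
            q1 = q(gamma + scale * step)
            if q1 >= q0:
                break
            scale *= 0.5
        else:
            break
        gamma = gamma + scale * step
        if q1 - q0 < tol * (abs(q0) + 1.0):
            q0 = q1
            break
        q0 = q1
    return np.clip(gamma, -4 * _CLIP, 4 * _CLIP)


class ZipTrajectoryModel(BaseEstimator):
    """Finite mixture of zero-inflated Poisson polynomial trajectories.

    Parameters
    ----------
    n_groups : int
        Number of latent trajectory groups J (1..9 in practice).
    degree : int
        Degree of the polynomial time trend, shared by all groups.
    zero_inflation : {"polynomial", "constant", "none"}
        Structure of the zero-inflation probability: a polynomial of the
        same degree in time, a per-group constant, or fixed at zero
        (plain Poisson mixture).
    max_iter, tol : EM stopping rule on the change in log-likelihood.
    n_starts : number of EM starts; the first uses k-means on the cost
        rows, the rest seeded random responsibilities.
    bic_n : {"patients", "cells"}
        Sample size used in the BIC penalty (subjects by default).
    random_state : seed for initialisation.

    Attributes (after ``fit``)
    --------------------------
    weights_ : (J,) mixing proportions pi_j.
    rate_coef_ : (J, degree+1) log-rate polynomial coefficients beta.
    zero_coef_ : (J, q) zero-inflation coefficients gamma on the logit scale.
    rates_, zero_prob_, mean_curve_ : (J, 12) fitted per-month rate,
        zero probability and expected cost (1 - p) * lambda.
    posterior_ : (n, J) membership probabilities; ``labels_`` their argmax.
    loglik_, n_parameters_, aic_, bic_, converged_, n_iter_, loglik_trace_.
    """

    def __init__(self, n_groups=6, degree=3, zero_inflation="polynomial",
                 max_iter=500, tol=1e-6, n_starts=2, bic_n="patients",
                 random_state=None):
        self.n_groups = n_groups
        self.degree = degree
        self.zero_inflation = zero_inflation
        self.max_iter = max_iter
        self.tol = tol
        self.n_starts = n_starts
        self.bic_n = bic_n
        self.random_state = random_state

    # -- internal -----------------------------------------------------------

    def _bases(self):
        T = time_basis(self.degree)
        if self.zero_inflation == "polynomial":
            G = T
        elif self.zero_inflation in ("constant", "none"):
            G = np.ones((N_MONTHS, 1))
        else:
            raise ValueError(f"unknown zero_inflation {self.zero_inflation!r}")
        return T, G

    def _check_data(self, X, observed):
        if isinstance(X, MonthlyCostMatrix):
            observed = X.observed
            X = X.values
        Y = np.asarray(X)
        if Y.ndim != 2 or Y.shape[1] != N_MONTHS:
            raise ValueError(f"expected (n, {N_MONTHS}) count matrix, got {Y.shape}")
        if (Y < 0).any() or not np.allclose(Y, np.round(Y)):
            raise ValueError("cost counts must be non-negative integers")
        Y = np.round(Y).astype(np.int64)
        if observed is None:
            observed = np.ones_like(Y, dtype=bool)
        O = np.asarray(observed, dtype=bool)
        if O.shape != Y.shape:
            raise ValueError("observed mask must match the count matrix shape")
        if not O.any(axis=1).all():
            raise ValueError("every patient needs at least one observed month")
        return Y, O

    def _group_curves(self, beta, gamma, T, G):
        lam = np.exp(np.clip(beta @ T.T, -_CLIP, _CLIP))       # (J, 12)
        if self.zero_inflation == "none":
            p = np.zeros_like(lam)
        else:
            p = expit(np.clip(gamma @ G.T, -_CLIP, _CLIP))
        return lam, p

    def _loglik_matrix(self, Y, O, lam, p):
        """Per-patient per-group log-likelihood contributions (n, J)."""
        n, J = Y.shape[0], lam.shape[0]
        L = np.empty((n, J))
        for j in range(J):
            lp = zip_logpmf(Y, lam[j][None, :], p[j][None, :])
            L[:, j] = np.where(O, lp, 0.0).sum(axis=1)
        return L

    def _e_step(self, Y, O, pi, lam, p):
        L = self._loglik_matrix(Y, O, lam, p)
        logw = np.log(pi)[None, :] + L
        norm = logsumexp(logw, axis=1)
        W = np.exp(logw - norm[:, None])
        return W, float(norm.sum())

    def _m_step(self, Y, O, W, beta, gamma, T, G):
        """Exact conditional maximisation given responsibilities W."""
        n, J = W.shape
        pi = W.mean(axis=0)
        lam, p = self._group_curves(beta, gamma, T, G)
        is_zero = (Y == 0) & O
        Of = O.astype(float)
        for j in range(J):
            w = W[:, j]
            # structural-zero responsibilities: identical for all zero cells
            # of a month within the group
            with np.errstate(over="ignore"):
                u_m = p[j] / (p[j] + (1.0 - p[j]) * np.exp(-np.minimum(lam[j], 700.0)))
            zero_w = w @ (is_zero.astype(float))            # (12,)
            tot_w = w @ Of                                   # (12,)
            a = zero_w * u_m                                 # structural-zero mass
            b = tot_w - a                                    # Poisson-process mass
            s = w @ (Y * Of)                                 # weighted count sums
            beta[j] = _newton_poisson(T, s, b, beta[j])
            if self.zero_inflation != "none":
                gamma[j] = _newton_binomial(G, a, b, gamma[j])
        return pi, beta, gamma

    def _init_responsibilities(self, Y, O, rng, start_index):
        n = Y.shape[0]
        J = self.n_groups
        if J == 1:
            return np.ones((n, 1))
        if start_index == 0:
            filled = np.where(O, Y, np.nan).astype(float)
            col_mean = np.nanmean(filled, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            inds = np.where(np.isnan(filled))
            filled[inds] = np.take(col_mean, inds[1])
            km = KMeans(n_clusters=J, n_init=3,
                        random_state=rng.randint(np.iinfo(np.int32).max))
            labels = km.fit_predict(np.log1p(filled))
            W = np.full((n, J), 0.05 / max(J - 1, 1))
            W[np.arange(n), labels] = 0.95
        else:
            W = rng.dirichlet(np.ones(J), size=n)
        return W

    def _init_params(self, Y, O, W, T, G):
        """Hard M-step from initial responsibilities, ignoring inflation."""
        J = W.shape[1]
        beta = np.zeros((J, T.shape[1]))
        gamma = np.full((J, G.shape[1]), 0.0)
        if self.zero_inflation != "none":
            gamma[:, 0] = -1.5          # ~18% zero inflation to start
        Of = O.astype(float)
        for j in range(J):
            w = W[:, j]
            tot_w = np.maximum(w @ Of, 1e-12)
            s = w @ (Y * Of)
            mean_m = np.maximum(s / tot_w, 1e-3)
            # least-squares on log means as a cheap warm start
            beta[j] = np.linalg.lstsq(T, np.log(mean_m), rcond=None)[0]
        return beta, gamma

    def _run_em(self, Y, O, W, T, G):
        beta, gamma = self._init_params(Y, O, W, T, G)
        pi = np.maximum(W.mean(axis=0), 1e-10)
        pi = pi / pi.sum()
        pi, beta, gamma = self._m_step(Y, O, W, beta, gamma, T, G)
        lam, p = self._group_curves(beta, gamma, T, G)
        trace = []
        prev = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            W, ll = self._e_step(Y, O, pi, lam, p)
            trace.append(ll)
            if ll - prev < self.tol and n_iter > 1:
                converged = True
                break
            prev = ll
            pi, beta, gamma = self._m_step(Y, O, W, beta, gamma, T, G)
            pi = np.maximum(pi, 1e-12)
            pi = pi / pi.sum()
            lam, p = self._group_curves(beta, gamma, T, G)
        return dict(pi=pi, beta=beta, gamma=gamma, W=W, loglik=trace[-1],
                    trace=np.array(trace), converged=converged, n_iter=n_iter)

    # -- sklearn surface ----------------------------------------------------

    def fit(self, X, observed=None, warm_start_params=None):
        """Fit the mixture to an (n, 12) count matrix (or MonthlyCostMatrix).

        ``warm_start_params`` (dict with pi, beta, gamma) replaces the usual
        multi-start initialisation with a single EM run from those values —
        used by the fast leave-one-out mode.
        """
        Y, O = self._check_data(X, observed)
        n = Y.shape[0]
        J = int(self.n_groups)
        if J < 1:
            raise ValueError("n_groups must be >= 1")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if n <= J:
            raise ValueError(f"need more patients ({n}) than groups ({J})")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        T, G = self._bases()
        rng = check_random_state(self.random_state)

        best = None
        if warm_start_params is not None:
            pi = np.asarray(warm_start_params["pi"], dtype=float)
            beta = np.array(warm_start_params["beta"], dtype=float)
            gamma = np.array(warm_start_params["gamma"], dtype=float)
            lam, p = self._group_curves(beta, gamma, T, G)
            W, _ = self._e_step(Y, O, pi, lam, p)
            best = self._run_em(Y, O, W, T, G)
        else:
            n_starts = 1 if J == 1 else max(1, int(self.n_starts))
            for k in range(n_starts):
                W0 = self._init_responsibilities(Y, O, rng, k)
                res = self._run_em(Y, O, W0, T, G)
                if best is None or res["loglik"] > best["loglik"] + 1e-12:
                    best = res

        if not best["converged"]:
            warnings.warn(
                f"EM did not converge in {self.max_iter} iterations "
                f"(J={J}, degree={self.degree})", RuntimeWarning)

        lam, p = self._group_curves(best["beta"], best["gamma"], T, G)
        mean_curve = (1.0 - p) * lam
        order = np.argsort(-mean_curve.mean(axis=1), kind="stable")

        self.weights_ = best["pi"][order]
        self.rate_coef_ = best["beta"][order]
        self.zero_coef_ = best["gamma"][order]
        self.rates_ = lam[order]
        self.zero_prob_ = p[order]
        self.mean_curve_ = mean_curve[order]
        self.posterior_ = best["W"][:, order]
        self.labels_ = np.argmax(self.posterior_, axis=1)
        self.loglik_ = best["loglik"]
        self.loglik_trace_ = best["trace"]
        self.converged_ = bool(best["converged"])
        self.n_iter_ = best["n_iter"]
        self.n_patients_ = n
        self.n_observed_cells_ = int(O.sum())
        q = 0 if self.zero_inflation == "none" else self.zero_coef_.shape[1]
        self.n_parameters_ = (J - 1) + J * (self.degree + 1) + J * q
        bic_n = n if self.bic_n == "patients" else self.n_observed_cells_
        self.aic_ = -2.0 * self.loglik_ + 2.0 * self.n_parameters_
        self.bic_ = -2.0 * self.loglik_ + self.n_parameters_ * np.log(bic_n)
        if (self.weights_ < 1.0 / (10.0 * n)).any():
            warnings.warn("degenerate near-empty group in the fitted mixture",
                          RuntimeWarning)
        return self

    def loglik(self, X, observed=None) -> float:
        """Observed-data log-likelihood of new data under the fitted model."""
        Y, O = self._check_data(X, observed)
        _, ll = self._e_step(Y, O, self.weights_, self.rates_, self.zero_prob_)
        return ll

    def predict_proba(self, X, observed=None) -> np.ndarray:
        """Posterior membership probabilities for each patient row."""
        Y, O = self._check_data(X, observed)
        W, _ = self._e_step(Y, O, self.weights_, self.rates_, self.zero_prob_)
        return W

    def predict(self, X, observed=None) -> np.ndarray:
        """MAP group labels; ties break toward the lower group index."""
        return np.argmax(self.predict_proba(X, observed), axis=1)

    def params_(self) -> dict:
        """Current parameters in warm-startable form."""
        return dict(pi=self.weights_.copy(), beta=self.rate_coef_.copy(),
                    gamma=self.zero_coef_.copy())

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "n_groups": self.n_groups, "degree": self.degree,
            "zero_inflation": self.zero_inflation,
            "weights": self.weights_.tolist(),
            "rate_coef": self.rate_coef_.tolist(),
            "zero_coef": self.zero_coef_.tolist(),
            "loglik": self.loglik_, "n_parameters": self.n_parameters_,
            "aic": self.aic_, "bic": self.bic_,
            "converged": self.converged_, "n_iter": self.n_iter_,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ZipTrajectoryModel":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls(n_groups=payload["n_groups"], degree=payload["degree"],
                    zero_inflation=payload["zero_inflation"])
        T, G = model._bases()
        model.weights_ = np.array(payload["weights"])
        model.rate_coef_ = np.array(payload["rate_coef"])
        model.zero_coef_ = np.array(payload["zero_coef"])
        lam, p = model._group_curves(model.rate_coef_, model.zero_coef_, T, G)
        model.rates_, model.zero_prob_ = lam, p
        model.mean_curve_ = (1 - p) * lam
        model.loglik_ = payload["loglik"]
        model.n_parameters_ = payload["n_parameters"]
        model.aic_ = payload["aic"]
        model.bic_ = payload["bic"]
        model.converged_ = payload["converged"]
        model.n_iter_ = payload["n_iter"]
        return model


def patient_loglik(y, observed, beta, gamma, degree=None,
                   zero_inflation="polynomial"):
    """Log-likelihood contribution of one patient row under one group.

    Sums ``zip_logpmf`` over observed months only.  Provided as a standalone
    building block; the estimator uses the same computation internally.
    """
    y = np.asarray(y)
    observed = np.asarray(observed, dtype=bool)
    if not observed.any():
        raise ValueError("patient row has no observed months")
    beta = np.asarray(beta, dtype=float)
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if degree is None:
        degree = len(beta) - 1
    T = time_basis(degree)
    lam = np.exp(np.clip(T @ beta, -_CLIP, _CLIP))
    if zero_inflation == "none":
        p = np.zeros(N_MONTHS)
    elif zero_inflation == "constant" or gamma.shape[0] == 1:
        p = np.full(N_MONTHS, expit(np.clip(gamma[0], -_CLIP, _CLIP)))
    else:
        p = expit(np.clip(T[:, : gamma.shape[0]] @ gamma, -_CLIP, _CLIP))
    lp = zip_logpmf(y, lam, p)
    return float(lp[observed].sum())


def posterior_assign(posterior: np.ndarray):
    """MAP labels and maximum posterior per patient from a posterior matrix.

    Ties break toward the lower group index (np.argmax convention).
    """
    W = np.asarray(posterior, dtype=float)
    labels = np.argmax(W, axis=1)
    return labels, W[np.arange(W.shape[0]), labels]


def information_criteria(loglik: float, n_parameters: int, n: int):
    """AIC and BIC from a maximised log-likelihood."""
    aic = -2.0 * loglik + 2.0 * n_parameters
    bic = -2.0 * loglik + n_parameters * np.log(n)
    return aic, bic
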