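"""Decoders mapping 96 MWP values to a continuous intended wrist angle.

Two decoders are provided, mirroring the analysis they come from:

- :class:`BetaRegression` — the interpretable model.  The cued angle is
  scaled to the unit interval and modeled with a beta likelihood whose mean
  follows a logit-linear model, ``logit(mu) = b0 + sum_j b_j MWP_j``, with a
  constant precision ``phi``.  Maximum likelihood is computed by Fisher
  scoring with step halving (monotone in the log-likelihood), and each
  channel gets a Wald test from the expected information, so the
  contribution of individual electrodes can be read off directly.
- :class:`SVRDecoder` — the performant model: epsilon-SVR with an RBF
  kernel on the same standardized features, better suited to the
  non-monotone channel tunings seen on real arrays.

Both are scikit-learn estimators and compose with sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import digamma, expit, gammaln, polygamma, logit as sp_logit
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted, validate_data

#: Boundary clamp for scaled angles: the beta likelihood is undefined at 0/1.
EPS_MU = 1e-3


def scale_angle(angle_deg, lo: float = 0.0, hi: float = 180.0, eps: float = EPS_MU):
    """Scale angles in [lo, hi] degrees to the open unit interval.

    The virtual experiment uses [0, 180]; the FES experiment maps the
    physical range [36, 128] the same way.  Values are clamped to
    [eps, 1 - eps] so the beta likelihood stays finite at the boundaries.
    """
    a = np.asarray(angle_deg, dtype=float)
    if np.any(a < lo - 1e-9) or np.any(a > hi + 1e-9):
        raise ValueError(f"angle outside [{lo}, {hi}] degrees")
    mu = np.clip((a - lo) / (hi - lo), eps, 1.0 - eps)
    return float(mu) if np.isscalar(angle_deg) else mu


def unscale_angle(mu, lo: float = 0.0, hi: float = 180.0):
    """Inverse of :func:`scale_angle` (without the clamp)."""
    return lo + (hi - lo) * np.asarray(mu, dtype=float)


@dataclass(frozen=True)
class DecodedState:
    """One decoded frame: scaled mean, angle in degrees, normalized force command."""

    mu: float
    angle_deg: float
    force_f: float


def _beta_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    a = mu * phi
    b = (1.0 - mu) * phi
    return float(
        np.sum(
            gammaln(phi) - gammaln(a) - gammaln(b)
            + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y)
        )
    )


class BetaRegression(RegressorMixin, BaseEstimator):
    """Beta regression with a logit link and constant precision.

    Fitted by Fisher scoring on (coefficients, log phi) with step halving,
    which guarantees the log-likelihood is non-decreasing over iterations.
    Standard errors and per-coefficient Wald p-values come from the inverse
    expected information at the MLE.

    Attributes
    ----------
    intercept_, coef_ : the linear predictor of logit(mu).
    phi_ : precision of the beta likelihood.
    se_, p_values_ : Wald standard errors / two-sided p-values per feature.
    loglik_path_ : log-likelihood at each accepted iteration (monotone).
    converged_ : whether the scoring iteration met the tolerance.
    """

    def __init__(self, max_iter: int = 200, tol: float = 1e-8, eps: float = EPS_MU):
        self.max_iter = max_iter
        self.tol = tol
        self.eps = eps

    def _score_info(self, Z, y, ystar, log1my, beta, log_phi):
        phi = np.exp(log_phi)
        eta = Z @ beta
        mu = expit(eta)
        mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
        a = mu * phi
        b = (1.0 - mu) * phi
        mustar = digamma(a) - digamma(b)
        t = mu * (1.0 - mu)  # dmu/deta for the logit link
        resid = ystar - mustar
        u_beta = phi * (Z.T @ (t * resid))
        u_phi = np.sum(mu * resid + log1my - digamma(b) + digamma(phi))
        psi1a = polygamma(1, a)
        psi1b = polygamma(1, b)
        w = phi * (psi1a + psi1b) * t * t
        k_bb = phi * (Z.T * w) @ Z
        c = phi * (psi1a * mu - psi1b * (1.0 - mu))
        k_bp = Z.T @ (t * c)
        k_pp = np.sum(psi1a * mu**2 + psi1b * (1.0 - mu) ** 2 - polygamma(1, phi))
        # reparameterize phi -> log phi (expected information transform)
        p = Z.shape[1]
        U = np.concatenate([u_beta, [phi * u_phi]])
        K = np.empty((p + 1, p + 1))
        K[:p, :p] = k_bb
        K[:p, p] = K[p, :p] = phi * k_bp
        K[p, p] = phi * phi * k_pp
        ll = _beta_loglik(y, mu, phi)
        return U, K, ll

    def fit(self, X, y) -> "BetaRegression":
        X, y = validate_data(self, X, y, y_numeric=True)
        if np.any(y <= 0) or np.any(y >= 1):
            raise ValueError("y must lie strictly inside (0, 1); use scale_angle")
        n, p = X.shape
        if n < p + 1:
            raise ValueError(f"need at least {p + 1} frames to fit {p} channels")
        Z = np.column_stack([np.ones(n), X])
        ystar = sp_logit(y)
        log1my = np.log1p(-y)
        # init: slope coefficients 0, intercept and phi from method of moments
        ybar, yvar = y.mean(), max(y.var(), 1e-10)
        beta = np.zeros(p + 1)
        beta[0] = sp_logit(np.clip(ybar, self.eps, 1 - self.eps))
        phi0 = max(ybar * (1.0 - ybar) / yvar - 1.0, 1.0)
        log_phi = np.log(phi0)
        theta = np.concatenate([beta, [log_phi]])
        U, K, ll = self._score_info(Z, y, ystar, log1my, theta[:-1], theta[-1])
        path = [ll]
        converged = False
        for _ in range(self.max_iter):
            try:
                delta = np.linalg.solve(K + 1e-10 * np.eye(K.shape[0]), U)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(K, U, rcond=None)[0]
            step = 1.0
            for _half in range(30):
                cand = theta + step * delta
                U_new, K_new, ll_new = self._score_info(
                    Z, y, ystar, log1my, cand[:-1], cand[-1]
                )
                if np.isfinite(ll_new) and ll_new >= ll:
                    break
                step *= 0.5
            else:
                break  # no ascent direction left
            improved = ll_new - ll
            theta, U, K, ll = cand, U_new, K_new, ll_new
            path.append(ll)
            if improved < self.tol * (1.0 + abs(ll)):
                converged = True
                break
        self.converged_ = converged
        self.loglik_ = ll
        self.loglik_path_ = np.asarray(path)
        self.n_iter_ = len(path) - 1
        self.intercept_ = float(theta[0])
        self.coef_ = theta[1:-1].copy()
        self.phi_ = float(np.exp(theta[-1]))
        # Wald SEs from the expected information in (beta, phi) coordinates
        cov = np.linalg.pinv(K, hermitian=True)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        self.se_intercept_ = float(se_all[0])
        self.se_ = se_all[1:-1].copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se_ > 0, self.coef_ / self.se_, np.inf)
        self.p_values_ = 2.0 * norm.sf(np.abs(z))
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted scaled angle mu in [eps, 1 - eps]."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        mu = expit(self.intercept_ + X @ self.coef_)
        return np.clip(mu, self.eps, 1.0 - self.eps)

    def predict_one(self, x: np.ndarray) -> float:
        """Single-frame prediction on the hot path (no re-validation)."""
        mu = float(expit(self.intercept_ + x @ self.coef_))
        return float(np.clip(mu, self.eps, 1.0 - self.eps))

    def decode(self, mwp: np.ndarray, lo: float = 0.0, hi: float = 180.0) -> DecodedState:
        """Decode a single 96-value MWP frame to an angle and force command."""
        mu = float(self.predict(np.asarray(mwp, dtype=float).reshape(1, -1))[0])
        return DecodedState(mu=mu, angle_deg=float(unscale_angle(mu, lo, hi)), force_f=mu)


class SVRDecoder(RegressorMixin, BaseEstimator):
    """Epsilon-SVR with an RBF kernel on standardized MWP features.

    A thin wrapper over the libsvm-based sklearn SVR that clamps predictions
    to the open unit interval used for scaled angles.  Defaults: C=10,
    epsilon=0.01, gamma=1/n_features; the tight tube keeps the rest state
    decoded at rest instead of drifting inside a wide epsilon band.
    """

    def __init__(self, C: float = 10.0, epsilon: float = 0.01, gamma="auto",
                 eps: float = EPS_MU):
        self.C = C
        self.epsilon = epsilon
        self.gamma = gamma
        self.eps = eps

    def fit(self, X, y) -> "SVRDecoder":
        X, y = validate_data(self, X, y, y_numeric=True)
        self.svr_ = SVR(kernel="rbf", C=self.C, epsilon=self.epsilon, gamma=self.gamma)
        self.svr_.fit(X, y)
        if self.gamma == "auto":
            self.gamma_ = 1.0 / X.shape[1]
        elif self.gamma == "scale":
            self.gamma_ = 1.0 / (X.shape[1] * X.var())
        else:
            self.gamma_ = float(self.gamma)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return np.clip(self.svr_.predict(X), self.eps, 1.0 - self.eps)

    def predict_one(self, x: np.ndarray) -> float:
        """Single-frame prediction on the hot path (no re-validation)."""
        sv = self.svr_.support_vectors_
        k = np.exp(-self.gamma_ * np.square(sv - x).sum(axis=1))
        mu = float(self.svr_.dual_coef_[0] @ k + self.svr_.intercept_[0])
        return float(np.clip(mu, self.eps, 1.0 - self.eps))

    def decode(self, mwp: np.ndarray, lo: float = 0.0, hi: float = 180.0) -> DecodedState:
        mu = float(self.predict(np.asarray(mwp, dtype=float).reshape(1, -1))[0])
        return DecodedState(mu=mu, angle_deg=float(unscale_angle(mu, lo, hi)), force_f=mu)


def beta_model_to_json(model: BetaRegression) -> str:
    """Serialize a fitted beta regression (coefficients, phi, inference)."""
    check_is_fitted(model)
    import json

    return json.dumps(
        {
            "intercept": model.intercept_,
            "coef": model.coef_.tolist(),
            "phi": model.phi_,
            "se": model.se_.tolist(),
            "p_values": model.p_values_.tolist(),
            "eps": model.eps,
        },
        indent=1,
    )


def beta_model_from_json(text: str) -> BetaRegression:
    import json

    d = json.loads(text)
    m = BetaRegression(eps=d["eps"])
    m.intercept_ = float(d["intercept"])
    m.coef_ = np.asarray(d["coef"], dtype=float)
    m.phi_ = float(d["phi"])
    m.se_ = np.asarray(d["se"], dtype=float)
    m.p_values_ = np.asarray(d["p_values"], dtype=float)
    m.n_features_in_ = m.coef_.size
    return m


def make_decoder(algo: str, **kwargs):
    """Factory for the two decoder families ("beta" or "svr")."""
    if algo == "beta":
        return BetaRegression(**kwargs)
    if algo == "svr":
        return SVRDecoder(**kwargs)
    raise ValueError(f"unknown decoder {algo!r}")


def rolling_training_set(
    blocks: Sequence[tuple[np.ndarray, np.ndarray]], max_blocks: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate the features/targets of the <=3 most recent blocks."""
    if not blocks:
        raise ValueError("need at least one completed block")
    recent = list(blocks)[-max_blocks:]
    X = np.concatenate([b[0] for b in recent], axis=0)
    y = np.concatenate([b[1] for b in recent], axis=0)
    return X, y


def median_abs_error(pred_angles, true_angles) -> float:
    """Median absolute error in degrees between decoded and cued angles."""
    p = np.asarray(pred_angles, dtype=float)
    t = np.asarray(true_angles, dtype=float)
    if p.size == 0 or p.shape != t.shape:
        raise ValueError("inputs must be nonempty and of equal length")
    return float(np.median(np.abs(p - t)))
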