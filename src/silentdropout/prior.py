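"""Logistic diabetes-duration prior P(CD|D).

The probability that an animal has crossed the dropout cutoff, given only its
diabetes duration D (weeks), is modelled as

    P(CD|D) = exp(b0 + b1*D) / (1 + exp(b0 + b1*D))

with (b0, b1) estimated by maximising the Bernoulli likelihood
prod_i P_i^y_i (1-P_i)^(1-y_i) via Newton-Raphson with step-halving.
Standard errors come from the inverse observed information at the optimum.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import DegenerateOutcomeError, InvalidInputError, SeparationError

__all__ = ["LogisticPrior", "DurationPrior", "fit_logistic_mle", "prior_probability"]


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    # evaluated on the log-odds scale; stable for large |eta|
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*log(p) + (1-y)*log(1-p) = sum y*eta - log(1+exp(eta)), stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass(frozen=True)
class LogisticPrior:
    """Fitted duration prior: intercept ``beta0`` and per-week slope ``beta1``."""

    beta0: float
    beta1: float
    log_likelihood: float
    converged: bool
    n_obs: int
    standard_errors: tuple[float, float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LogisticPrior":
        d = json.loads(text)
        d["standard_errors"] = tuple(d["standard_errors"])
        return cls(**d)


class DurationPrior:
    """Logistic-prior estimator (sklearn-style).

    Parameters
    ----------
    tol : float
        Convergence tolerance on the max-norm of the score (gradient).
    max_iter : int
        Newton-Raphson iteration cap.
    bound : float
        Separation guard: fitting aborts when either coefficient's magnitude
        on the log-odds scale exceeds this bound, since probabilities are
        numerically saturated beyond it.

    Attributes (after ``fit``)
    --------------------------
    beta0_, beta1_ : float
        MLE of intercept and per-week slope.
    standard_errors_ : (float, float)
        Square roots of the diagonal of the inverse observed information.
    log_likelihood_ : float
        Maximised log-likelihood (natural log; always <= 0).
    converged_ : bool
    n_obs_ : int
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100, bound: float = 30.0):
        self.tol = tol
        self.max_iter = max_iter
        self.bound = bound

    # minimal get/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {"tol": self.tol, "max_iter": self.max_iter, "bound": self.bound}

    def set_params(self, **params) -> "DurationPrior":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, durations, labels) -> "DurationPrior":
        D = np.asarray(durations, dtype=float).ravel()
        y = np.asarray(labels, dtype=float).ravel()
        if D.shape != y.shape:
            raise InvalidInputError("durations and labels must have equal length")
        if not np.isfinite(D).all():
            raise InvalidInputError("durations must be finite")
        if not np.isin(y, (0.0, 1.0)).all():
            raise InvalidInputError("labels must be binary 0/1")
        if y.min() == y.max():
            raise DegenerateOutcomeError(
                "labels contain a single class; the prior is not identifiable"
            )

        X = np.column_stack([np.ones_like(D), D])
        ybar = y.mean()
        beta = np.array([np.log(ybar / (1.0 - ybar)), 0.0])
        ll = _log_likelihood(X @ beta, y)
        converged = False
        for _ in range(self.max_iter):
            eta = X @ beta
            p = _sigmoid(eta)
            grad = X.T @ (y - p)
            if np.max(np.abs(grad)) < self.tol:
                converged = True
                break
            w = p * (1.0 - p)
            info = (X * w[:, None]).T @ X
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                self._raise_separation(beta)
            # step-halving: never accept a step that lowers the likelihood
            for _half in range(50):
                cand = beta + step
                cand_ll = _log_likelihood(X @ cand, y)
                if cand_ll >= ll - 1e-12:
                    break
                step *= 0.5
            beta, ll = cand, cand_ll
            if np.max(np.abs(beta)) > self.bound:
                self._raise_separation(beta)
        else:
            eta = X @ beta
            p = _sigmoid(eta)
            grad = X.T @ (y - p)
            converged = bool(np.max(np.abs(grad)) < 1e-8)

        p = _sigmoid(X @ beta)
        w = p * (1.0 - p)
        info = (X * w[:, None]).T @ X
        cov = np.linalg.inv(info)
        self.beta0_, self.beta1_ = float(beta[0]), float(beta[1])
        self.standard_errors_ = (float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])))
        self.log_likelihood_ = _log_likelihood(X @ beta, y)
        self.converged_ = converged
        self.n_obs_ = int(y.size)
        return self

    def _raise_separation(self, beta: np.ndarray):
        direction = 1 if beta[1] >= 0 else -1
        raise SeparationError(
            "complete separation detected: slope diverging towards "
            + ("+inf" if direction > 0 else "-inf"),
            direction=direction,
        )

    def predict_proba(self, durations):
        """Prior probability P(CD|D) for each duration (weeks)."""
        self._check_fitted()
        D = np.asarray(durations, dtype=float)
        eta = self.beta0_ + self.beta1_ * D
        out = _sigmoid(np.atleast_1d(eta))
        return float(out[0]) if np.isscalar(durations) else out.reshape(np.shape(D))

    def to_prior(self) -> LogisticPrior:
        self._check_fitted()
        return LogisticPrior(
            beta0=self.beta0_,
            beta1=self.beta1_,
            log_likelihood=self.log_likelihood_,
            converged=self.converged_,
            n_obs=self.n_obs_,
            standard_errors=self.standard_errors_,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "beta0_"):
            raise InvalidInputError("DurationPrior is not fitted; call fit first")


def fit_logistic_mle(durations, labels, **params) -> LogisticPrior:
    """Fit the duration prior and return the frozen :class:`LogisticPrior`."""
    return DurationPrior(**params).fit(durations, labels).to_prior()


def prior_probability(prior: LogisticPrior, D):
    """Evaluate P(CD|D) = sigmoid(beta0 + beta1*D) for duration(s) ``D`` (weeks)."""
    eta = np.atleast_1d(prior.beta0 + prior.beta1 * np.asarray(D, dtype=float))
    out = _sigmoid(eta)
    return float(out[0]) if np.isscalar(D) else out.reshape(np.shape(D))
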