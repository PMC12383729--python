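"""Bayesian fusion of classifier evidence with the duration prior.

Two probability estimates of the same dropout event -- the image classifier's
P(CD|AI) and the duration prior's P(CD|D) -- are combined by Bayes' rule
under conditional independence of the two evidence sources:

    P(CD|AI,D) = p_ai*p_prior / (p_ai*p_prior + (1-p_ai)*(1-p_prior))

which is exactly additive on the log-odds scale:
logit(posterior) = logit(p_ai) + logit(p_prior).  The independence assumption
is inherited from the product rule and is documented, not corrected.
Inputs are clamped to [1e-12, 1-1e-12] because the formula is 0/0 at the
conflicting corners (0,1) and (1,0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, JoinError
from .prior import LogisticPrior, prior_probability

__all__ = ["EPS", "fuse", "fuse_cohort", "posterior_surface", "PosteriorGrid"]

EPS = 1e-12


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def fuse(p_ai, p_prior):
    """Posterior P(CD|AI,D) from the two probability estimates.

    Symmetric, strictly increasing in each argument on (0,1), and the
    identity at 0.5: fuse(0.5, p) == p.  Scalar in, scalar out.
    """
    a = np.asarray(p_ai, dtype=float)
    b = np.asarray(p_prior, dtype=float)
    if ((a < 0) | (a > 1)).any() or ((b < 0) | (b > 1)).any():
        raise InvalidInputError("probabilities must lie in [0, 1]")
    a = np.clip(a, EPS, 1.0 - EPS)
    b = np.clip(b, EPS, 1.0 - EPS)
    # sigmoid(logit a + logit b), evaluated stably on the log-odds scale
    eta = _logit(a) + _logit(b)
    out = np.where(eta >= 0, 1.0 / (1.0 + np.exp(-np.abs(eta))),
                   np.exp(-np.abs(eta)) / (1.0 + np.exp(-np.abs(eta))))
    if np.isscalar(p_ai) and np.isscalar(p_prior):
        return float(out)
    return out


def fuse_cohort(
    scores: pd.DataFrame, prior: LogisticPrior, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Replace each image's score with its duration-fused posterior.

    Joins ``scores.animal_id`` to the cohort's diabetes duration, evaluates
    the prior per animal and fuses it with the per-image score.  True labels
    are untouched; the returned table has the same shape and ordering.
    """
    durations = cohort.set_index("animal_id")["diabetes_duration_weeks"]
    missing = sorted(set(scores["animal_id"]) - set(durations.index))
    if missing:
        raise JoinError(
            f"animal ids missing from cohort: {missing[:10]}", missing=missing
        )
    d = durations.loc[scores["animal_id"]].to_numpy(dtype=float)
    p_prior = prior_probability(prior, d)
    fused = scores.copy()
    fused["score"] = fuse(scores["score"].to_numpy(dtype=float), p_prior)
    return fused


@dataclass(frozen=True)
class PosteriorGrid:
    """Posterior P(CD|AI,D) over a grid: one row per duration, one column per
    classifier probability."""

    ai_axis: np.ndarray
    duration_axis: np.ndarray
    posterior: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.posterior,
            index=pd.Index(self.duration_axis, name="duration_weeks"),
            columns=pd.Index(self.ai_axis, name="p_ai"),
        )


def posterior_surface(
    prior: LogisticPrior,
    ai_grid=None,
    duration_grid=None,
) -> PosteriorGrid:
    """Posterior surface over all combinations of classifier probability and
    diabetes duration.

    Defaults: classifier axis 0..1 in steps of 0.01, duration axis 0..60
    weeks in steps of 1.  Rows are nondecreasing along the classifier axis
    and, when beta1 > 0, columns are nondecreasing along the duration axis.
    """
    ai = np.arange(0.0, 1.0 + 1e-9, 0.01) if ai_grid is None else np.asarray(ai_grid, float)
    dur = np.arange(0.0, 61.0, 1.0) if duration_grid is None else np.asarray(duration_grid, float)
    if ai.size == 0 or dur.size == 0:
        raise InvalidInputError("grids must be non-empty")
    if (np.diff(ai) < 0).any() or (np.diff(dur) < 0).any():
        raise InvalidInputError("grids must be sorted ascending")
    p_prior = prior_probability(prior, dur)
    post = fuse(ai[None, :], np.asarray(p_prior).reshape(-1, 1))
    return PosteriorGrid(ai_axis=ai, duration_axis=dur, posterior=post)
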