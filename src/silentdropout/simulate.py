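"""Synthetic cohort, classifier-score and expression-count generators.

The generators emulate the statistical structure of a diabetic Nile-rat
(*Arvicanthis niloticus*) retinopathy cohort:

* a per-animal covariate table (diabetes duration, mean random blood glucose,
  diet, sex, age) with an acellular-capillary-density response that increases
  with diabetes duration, so the density marginal spans the normal (<16),
  pre-dropout (17-18) and dropout (>=18 counts/mm^2) bands;
* per-image classifier probabilities whose class-conditional separation is
  calibrated to a target AUC -- the fluorescein-angiography deep-learning
  classifier is represented only by this probabilistic output;
* paired gene-count matrices with negative-binomial noise at two dispersion
  levels, emulating the comparison of a cross-species quantification pipeline
  against direct genome mapping.

All generators are pure functions of ``(config, seed)``: the same seed and
configuration produce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InvalidConfigError, InvalidDesignError

__all__ = [
    "DensityModel",
    "ClassifierModel",
    "SimulationConfig",
    "DESpec",
    "CountMatrix",
    "simulate_cohort",
    "simulate_classifier_scores",
    "simulate_expression",
    "beta_shape_for_auc",
]

COHORT_COLUMNS = [
    "animal_id",
    "sex",
    "diet",
    "age_weeks",
    "mean_rbg",
    "diabetes_duration_weeks",
    "acellular_density",
]

SCORE_COLUMNS = ["image_id", "animal_id", "score", "true_label"]


@dataclass(frozen=True)
class DensityModel:
    """Linear predictor for acellular capillary density (counts/mm^2).

    density = intercept + duration*D + rbg*(RBG - rbg_center) + diet*1[high_caloric]
              + age*age_weeks + sex*1[male] + sex_late*1[male]*max(D - 20, 0)
              + Normal(0, noise_sd), truncated at 0.

    Defaults place non-diabetic animals around 10-14 counts/mm^2 and animals
    with ~28 weeks of diabetes around 20-22, reproducing the importance
    ordering duration > glucose > diet > age >> sex.  ``sex_late`` is an
    optional interaction (males diverging only beyond 20 weeks of diabetes);
    it is off by default.
    """

    intercept: float = 6.5
    duration: float = 0.28
    rbg: float = 0.03
    diet: float = 2.0
    age: float = 0.04
    sex: float = 0.0
    sex_late: float = 0.0
    rbg_center: float = 120.0
    noise_sd: float = 2.5

    def validate(self) -> None:
        if not self.noise_sd > 0:
            raise InvalidConfigError(f"noise_sd must be > 0, got {self.noise_sd}")


@dataclass(frozen=True)
class ClassifierModel:
    """Class-conditional score distributions for the simulated classifier.

    Scores are Beta distributed: negatives ~ Beta(c, c*k) and positives
    ~ Beta(c*k, c) with ``c = concentration`` and ``k >= 1`` solved
    numerically so that P(score_pos > score_neg) equals ``target_auc``.
    A target of exactly 1.0 switches to disjoint supports (negatives below
    0.5, positives above), giving perfect separation.
    """

    target_auc: float = 0.86
    concentration: float = 2.0

    def validate(self) -> None:
        if not (0.5 < self.target_auc <= 1.0):
            raise InvalidConfigError(
                f"target_auc must be in (0.5, 1], got {self.target_auc}"
            )
        if not self.concentration > 0:
            raise InvalidConfigError("concentration must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of generator settings; a pure function of this + seed.

    ``images_per_animal`` may be an int or an inclusive ``(low, high)`` range.
    """

    seed: int = 0
    n_animals: int = 124
    density_model: DensityModel = field(default_factory=DensityModel)
    classifier_model: ClassifierModel = field(default_factory=ClassifierModel)
    images_per_animal: int | tuple[int, int] = 2
    # cohort composition: fraction on the high-caloric diet and the
    # diet-conditional probabilities of being diabetic
    p_high_caloric: float = 0.5
    p_diabetic_high_caloric: float = 0.75
    p_diabetic_high_fiber: float = 0.20
    max_duration_weeks: float = 52.0

    def validate(self) -> None:
        if self.n_animals < 0:
            raise InvalidConfigError(f"n_animals must be >= 0, got {self.n_animals}")
        self.density_model.validate()
        self.classifier_model.validate()
        ipa = self.images_per_animal
        if isinstance(ipa, tuple):
            lo, hi = ipa
            if lo < 1 or hi < lo:
                raise InvalidConfigError(f"bad images_per_animal range {ipa}")
        elif ipa < 1:
            raise InvalidConfigError("images_per_animal must be >= 1")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a per-animal cohort table.

    Returns a DataFrame with columns ``animal_id, sex, diet, age_weeks,
    mean_rbg, diabetes_duration_weeks, acellular_density``.  Non-diabetic
    animals have duration 0; density is the truncated linear-Gaussian model
    of :class:`DensityModel`, so its expectation is nondecreasing in duration
    whenever the duration coefficient is positive.
    """
    config.validate()
    n = config.n_animals
    rng = np.random.default_rng(config.seed)
    if n == 0:
        return pd.DataFrame(
            {
                "animal_id": pd.Series([], dtype=str),
                "sex": pd.Series([], dtype=str),
                "diet": pd.Series([], dtype=str),
                "age_weeks": pd.Series([], dtype=float),
                "mean_rbg": pd.Series([], dtype=float),
                "diabetes_duration_weeks": pd.Series([], dtype=float),
                "acellular_density": pd.Series([], dtype=float),
            }
        )

    male = rng.random(n) < 0.5
    high_caloric = rng.random(n) < config.p_high_caloric
    p_diab = np.where(
        high_caloric, config.p_diabetic_high_caloric, config.p_diabetic_high_fiber
    )
    diabetic = rng.random(n) < p_diab
    duration = np.where(
        diabetic, rng.uniform(2.0, config.max_duration_weeks, n), 0.0
    )
    # cross-sectional enrolment: ages vary independently of disease duration
    age = rng.uniform(24.0, 96.0, n)
    rbg_healthy = rng.normal(120.0, 12.0, n)
    rbg_diabetic = 150.0 + 2.2 * duration + rng.normal(0.0, 25.0, n)
    mean_rbg = np.clip(np.where(diabetic, rbg_diabetic, rbg_healthy), 60.0, 500.0)

    m = config.density_model
    linpred = (
        m.intercept
        + m.duration * duration
        + m.rbg * (mean_rbg - m.rbg_center)
        + m.diet * high_caloric
        + m.age * age
        + m.sex * male
        + m.sex_late * male * np.maximum(duration - 20.0, 0.0)
    )
    density = np.maximum(linpred + rng.normal(0.0, m.noise_sd, n), 0.0)

    return pd.DataFrame(
        {
            "animal_id": [f"rat{i:04d}" for i in range(n)],
            "sex": np.where(male, "male", "female"),
            "diet": np.where(high_caloric, "high_caloric", "high_fiber"),
            "age_weeks": age,
            "mean_rbg": mean_rbg,
            "diabetes_duration_weeks": duration,
            "acellular_density": density,
        }
    )


def _beta_auc(k: float, c: float, n_nodes: int = 240) -> float:
    """AUC of Beta(c*k, c) positives against Beta(c, c*k) negatives.

    P(X_pos > X_neg) = int f_pos(x) F_neg(x) dx, evaluated by fixed
    Gauss-Legendre quadrature on [0, 1].
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    x = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    f_pos = stats.beta.pdf(x, c * k, c)
    F_neg = stats.beta.cdf(x, c, c * k)
    return float(np.sum(w * f_pos * F_neg))


@lru_cache(maxsize=64)
def beta_shape_for_auc(target_auc: float, concentration: float = 2.0) -> float:
    """Solve for the shape ratio ``k`` giving the requested AUC.

    Negatives ~ Beta(c, c*k), positives ~ Beta(c*k, c); AUC is continuous and
    increasing in k with AUC(1) = 0.5, so a bracketing root-find suffices.
    """
    if not (0.5 < target_auc < 1.0):
        raise InvalidConfigError(
            f"target_auc must be in (0.5, 1) for Beta calibration, got {target_auc}"
        )
    hi = 2.0
    while _beta_auc(hi, concentration) < target_auc:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - target_auc < 1 guarantees a bracket
            raise InvalidConfigError("cannot bracket the requested AUC")
    return float(
        optimize.brentq(
            lambda k: _beta_auc(k, concentration) - target_auc, 1.0, hi, xtol=1e-10
        )
    )


def simulate_classifier_scores(
    cohort: pd.DataFrame, cutoff: float, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate per-image classifier probabilities for a cohort.

    Each animal contributes ``images_per_animal`` images.  The image's true
    label is 1 iff the animal's acellular density is >= ``cutoff`` (ties
    positive); scores are drawn from the class-conditional Beta distributions
    of :class:`ClassifierModel`, calibrated so the empirical AUC approaches
    the configured target as the number of images grows.
    """
    config.validate()
    if cutoff <= 0:
        raise InvalidConfigError(f"cutoff must be > 0, got {cutoff}")
    if len(cohort) == 0:
        raise InvalidConfigError("cohort is empty")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ipa = config.images_per_animal
    if isinstance(ipa, tuple):
        n_images = rng.integers(ipa[0], ipa[1] + 1, len(cohort))
    else:
        n_images = np.full(len(cohort), int(ipa))

    animal_ids = np.repeat(cohort["animal_id"].to_numpy(), n_images)
    labels = np.repeat(
        (cohort["acellular_density"].to_numpy() >= cutoff).astype(int), n_images
    )
    total = len(labels)

    target = config.classifier_model.target_auc
    c = config.classifier_model.concentration
    scores = np.empty(total)
    pos = labels == 1
    if target == 1.0:
        # disjoint supports: every positive strictly above every negative
        scores[pos] = rng.uniform(0.51, 1.0, pos.sum())
        scores[~pos] = rng.uniform(0.0, 0.49, (~pos).sum())
    else:
        k = beta_shape_for_auc(target, c)
        scores[pos] = rng.beta(c * k, c, pos.sum())
        scores[~pos] = rng.beta(c, c * k, (~pos).sum())

    return pd.DataFrame(
        {
            "image_id": [f"img{i:05d}" for i in range(total)],
            "animal_id": animal_ids,
            "score": scores,
            "true_label": labels,
        }
    )


@dataclass(frozen=True)
class DESpec:
    """Planted differential-expression design: ``n_de`` genes up-regulated in
    the pre-dropout group by ``fold_change`` (>= 1)."""

    n_de: int = 0
    fold_change: float = 1.0

    def validate(self, n_genes: int) -> None:
        if self.fold_change < 1.0:
            raise InvalidConfigError(
                f"fold_change must be >= 1, got {self.fold_change}"
            )
        if not (0 <= self.n_de <= n_genes):
            raise InvalidConfigError("n_de out of range")


@dataclass
class CountMatrix:
    """Genes x samples expected-read-count matrix with per-gene lengths (bp)
    and per-sample group labels ({normal, pre_dropout})."""

    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_lengths.index):
            raise InvalidConfigError("gene_lengths index must match counts rows")
        if list(self.counts.columns) != list(self.sample_groups.index):
            raise InvalidConfigError("sample_groups index must match counts columns")
        if (self.gene_lengths <= 0).any():
            raise InvalidConfigError("gene lengths must be strictly positive")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise InvalidConfigError("counts must be finite and >= 0")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB draw with mean mu and variance mu + alpha*mu^2 (alpha -> 0: Poisson)."""
    if alpha <= 1e-12:
        return rng.poisson(mu)
    size = 1.0 / alpha
    return rng.negative_binomial(size, size / (size + mu))


def simulate_expression(
    n_genes: int,
    groups: list[str] | np.ndarray,
    dispersion_a: float,
    dispersion_b: float,
    de_spec: DESpec | None = None,
    seed: int = 0,
    mean_log2_expr: float = 6.0,
    sd_log2_expr: float = 1.5,
) -> tuple[CountMatrix, CountMatrix, pd.Series, pd.DataFrame]:
    """Generate two paired count matrices differing only in NB dispersion.

    Both matrices share the same per-gene, per-sample mean structure (baseline
    means log-normal across genes; planted genes multiplied by the fold change
    in pre-dropout samples) and the same gene lengths; matrix A uses
    overdispersion ``dispersion_a`` and matrix B ``dispersion_b``, where the
    overdispersion alpha enters the NB variance as mu + alpha*mu^2.  With
    dispersion_a > dispersion_b, matrix A emulates the noisier cross-species
    quantification and matrix B direct genome mapping.

    Returns ``(counts_a, counts_b, gene_lengths, truth)`` where ``truth`` has
    one row per gene with columns ``is_de`` and ``fold_change``.
    """
    if n_genes < 1:
        raise InvalidConfigError(f"n_genes must be >= 1, got {n_genes}")
    if dispersion_a < 0 or dispersion_b < 0:
        raise InvalidConfigError("dispersions must be >= 0")
    groups = np.asarray(groups, dtype=object)
    bad = set(groups) - {"normal", "pre_dropout"}
    if bad:
        raise InvalidConfigError(f"unknown group labels: {sorted(bad)}")
    for g in ("normal", "pre_dropout"):
        if np.sum(groups == g) < 2:
            raise InvalidDesignError(f"group {g!r} needs >= 2 samples")
    de_spec = de_spec or DESpec()
    de_spec.validate(n_genes)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    genes = pd.Index([f"gene{i:05d}" for i in range(n_genes)], name="gene")
    samples = pd.Index([f"sample{i:03d}" for i in range(len(groups))], name="sample")

    base_mu = 2.0 ** rng.normal(mean_log2_expr, sd_log2_expr, n_genes)
    de_idx = rng.choice(n_genes, size=de_spec.n_de, replace=False)
    fc = np.ones(n_genes)
    fc[de_idx] = de_spec.fold_change

    mu = np.tile(base_mu[:, None], (1, len(groups)))
    pre = groups == "pre_dropout"
    mu[:, pre] *= fc[:, None]

    counts_a = _nb_draw(rng, mu, dispersion_a).astype(np.int64)
    counts_b = _nb_draw(rng, mu, dispersion_b).astype(np.int64)
    lengths = pd.Series(
        rng.integers(500, 5001, n_genes).astype(float), index=genes, name="length_bp"
    )
    group_series = pd.Series(groups, index=samples, name="group")
    truth = pd.DataFrame(
        {"is_de": fc > 1.0, "fold_change": fc}, index=genes
    )

    mat_a = CountMatrix(
        pd.DataFrame(counts_a, index=genes, columns=samples), lengths, group_series
    )
    mat_b = CountMatrix(
        pd.DataFrame(counts_b, index=genes, columns=samples), lengths, group_series
    )
    return mat_a, mat_b, lengths, truth
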