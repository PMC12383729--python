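"""Expression-quantification noise benchmark and the fold-change/FDR marker
screen.

Implements, for genes-x-samples count matrices:

* TPM (transcripts per million): per-sample length-normalised rates scaled
  to one million;
* median-of-ratios size factors (per-sample median of count / per-gene
  geometric-mean reference, over genes with all-positive counts);
* Spearman rank correlation (Pearson on mid-ranks);
* the per-gene overdispersion ratio (variance / mean of normalised counts) and
  a paired one-sided Wilcoxon signed-rank comparison of two quantification
  methods;
* the quantile-binned SD profile: the SD across samples of each sample's
  expression quantile at levels 25%..75% in 5% steps, a biology-free view of
  technical noise since genes are ranked only by expression level;
* the differential-expression screen: a two-group negative-binomial Wald test
  (method-of-moments dispersion common to both groups) with
  Benjamini-Hochberg FDR, flagging markers with fold-change of group medians
  > 2 and FDR < 5%.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidDesignError,
    InvalidInputError,
    NoReferenceError,
    UndefinedCorrelationError,
)
from .simulate import CountMatrix

__all__ = [
    "compute_tpm",
    "size_factors_median_of_ratios",
    "spearman_rho",
    "overdispersion_table",
    "overdispersion_compare",
    "wilcoxon_signed_rank",
    "quantile_sd_profile",
    "QuantileSdProfile",
    "benjamini_hochberg",
    "NegativeBinomialScreen",
    "de_screen",
    "SignedRankResult",
]

QUANTILE_LEVELS = np.arange(0.25, 0.751, 0.05)


def _counts_frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def compute_tpm(counts: CountMatrix) -> pd.DataFrame:
    """Transcripts per million for every sample column.

    rate_g = count_g / length_g; TPM_g = 1e6 * rate_g / sum_g rate_g.  Each
    non-degenerate column sums to 1e6; all-zero columns are returned as zeros
    with a warning.
    """
    mat = counts.counts.to_numpy(dtype=float)
    lengths = counts.gene_lengths.to_numpy(dtype=float)
    rates = mat / lengths[:, None]
    col_tot = rates.sum(axis=0)
    zero_cols = col_tot == 0
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} all-zero sample column(s); TPM left at 0",
            stacklevel=2,
        )
        col_tot = np.where(zero_cols, 1.0, col_tot)
    tpm = 1e6 * rates / col_tot
    return pd.DataFrame(tpm, index=counts.counts.index, columns=counts.counts.columns)


def size_factors_median_of_ratios(counts) -> pd.Series:
    """Median-of-ratios size factors (one positive real per sample).

    The reference is the per-gene geometric mean over samples, computed on
    genes with all-positive counts; each sample's factor is the median over
    those genes of count / reference.  Invariant to gene order and
    equivariant under scaling a sample's column.
    """
    frame = _counts_frame(counts)
    mat = frame.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise NoReferenceError("no gene has positive counts in every sample")
    ref = np.exp(np.log(mat[all_positive]).mean(axis=1))
    factors = np.median(mat[all_positive] / ref[:, None], axis=0)
    return pd.Series(factors, index=frame.columns, name="size_factor")


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidInputError("vectors must be equal length >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def overdispersion_table(counts) -> pd.Series:
    """Per-gene overdispersion ratio: variance / mean of size-factor
    normalised counts; NaN flags genes with zero mean."""
    frame = _counts_frame(counts)
    factors = size_factors_median_of_ratios(frame)
    norm = frame.to_numpy(dtype=float) / factors.to_numpy()
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean > 0, var / mean, np.nan)
    return pd.Series(ratio, index=frame.index, name="overdispersion")


@dataclass(frozen=True)
class SignedRankResult:
    statistic: float  # W+: rank sum of positive differences
    p_value: float
    n_nonzero: int


def wilcoxon_signed_rank(diff, alternative: str = "greater") -> SignedRankResult:
    """Paired Wilcoxon signed-rank test on a vector of differences.

    Zero differences are dropped; |differences| get mid-ranks; the statistic
    is the rank sum of positive differences, tested against its null mean
    with tie-corrected variance, continuity correction and the normal
    approximation.  All-zero differences return p = 1 by convention.
    """
    d = np.asarray(diff, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return SignedRankResult(0.0, 1.0, 0)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return SignedRankResult(w_plus, 1.0, n)
    sd = np.sqrt(var)
    if alternative == "greater":
        p = stats.norm.sf((w_plus - mu - 0.5) / sd)
    elif alternative == "less":
        p = stats.norm.cdf((w_plus - mu + 0.5) / sd)
    elif alternative == "two_sided":
        p = 2.0 * stats.norm.sf(max(abs(w_plus - mu) - 0.5, 0.0) / sd)
    else:
        raise InvalidInputError(f"unknown alternative {alternative!r}")
    return SignedRankResult(w_plus, float(min(p, 1.0)), n)


def overdispersion_compare(counts_a, counts_b):
    """Compare per-gene overdispersion between two quantification methods.

    Both matrices must share gene identifiers and sample count.  Returns the
    two per-gene overdispersion tables and a paired one-sided Wilcoxon
    signed-rank result testing whether method A's ratios exceed method B's
    (the direction in which a noisier quantification shows up).
    """
    frame_a = _counts_frame(counts_a)
    frame_b = _counts_frame(counts_b)
    if not frame_a.index.equals(frame_b.index):
        raise InvalidInputError("gene sets of the two matrices do not align")
    if frame_a.shape[1] != frame_b.shape[1]:
        raise InvalidInputError("matrices must have the same number of samples")
    tab_a = overdispersion_table(frame_a)
    tab_b = overdispersion_table(frame_b)
    both = tab_a.notna() & tab_b.notna()
    test = wilcoxon_signed_rank(
        tab_a[both].to_numpy() - tab_b[both].to_numpy(), alternative="greater"
    )
    return tab_a, tab_b, test


@dataclass(frozen=True)
class QuantileSdProfile:
    """SD across samples of per-sample expression quantiles, one value per
    level (25%..75% in 5% steps)."""

    levels: np.ndarray
    sd: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.sd, index=pd.Index(self.levels, name="quantile"), name="sd")


def quantile_sd_profile(tpm: pd.DataFrame, levels=QUANTILE_LEVELS) -> QuantileSdProfile:
    """Quantile-binned between-sample SD of expression.

    For each level q, take the empirical q-quantile of expression within each
    sample (linear interpolation between order statistics), then the SD of
    those per-sample values across samples.  Because genes are ranked solely
    by expression level within each sample, variation at a fixed quantile is
    driven by technical rather than biological differences.
    """
    if tpm.shape[1] < 2:
        raise InsufficientDataError("need >= 2 samples for a between-sample SD")
    levels = np.asarray(levels, dtype=float)
    q = np.quantile(tpm.to_numpy(dtype=float), levels, axis=0)  # levels x samples
    sd = q.std(axis=1, ddof=1)
    return QuantileSdProfile(levels=levels, sd=sd)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone); NaNs propagate."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    result = np.empty(m)
    result[order] = np.minimum(adj, 1.0)
    out[ok] = result
    return out


class NegativeBinomialScreen:
    """Two-group negative-binomial marker screen (sklearn-style).

    Counts are normalised by median-of-ratios size factors; per gene, a Wald
    statistic on the difference of log normalised group means is computed with
    a method-of-moments NB dispersion shared by the two groups (variance
    mu + alpha*mu^2, delta-method variance of the log mean (1/mu + alpha)/n).
    P-values get Benjamini-Hochberg adjustment, and a gene is flagged as a
    marker iff the fold-change of group medians (pre_dropout / normal) exceeds
    ``fc_threshold`` AND its FDR is below ``fdr_threshold`` — the two gates
    are conjunctive.

    Attributes after ``fit``: ``results_`` (per-gene DataFrame with columns
    fold_change, stat, p, fdr, marker), ``size_factors_``, ``n_markers_``.
    """

    def __init__(self, fc_threshold: float = 2.0, fdr_threshold: float = 0.05):
        self.fc_threshold = fc_threshold
        self.fdr_threshold = fdr_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"fc_threshold": self.fc_threshold, "fdr_threshold": self.fdr_threshold}

    def set_params(self, **params) -> "NegativeBinomialScreen":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, counts: CountMatrix) -> "NegativeBinomialScreen":
        groups = counts.sample_groups.to_numpy()
        normal = groups == "normal"
        pre = groups == "pre_dropout"
        if normal.sum() < 2 or pre.sum() < 2:
            raise InvalidDesignError("both groups need >= 2 samples")
        factors = size_factors_median_of_ratios(counts.counts)
        norm = counts.counts.to_numpy(dtype=float) / factors.to_numpy()
        n0, n1 = int(normal.sum()), int(pre.sum())
        x0, x1 = norm[:, normal], norm[:, pre]
        m0, m1 = x0.mean(axis=1), x1.mean(axis=1)
        v0, v1 = x0.var(axis=1, ddof=1), x1.var(axis=1, ddof=1)

        # shared method-of-moments dispersion: pooled excess variance
        with np.errstate(divide="ignore", invalid="ignore"):
            a0 = (v0 - m0) / m0**2
            a1 = (v1 - m1) / m1**2
        alpha = np.nan_to_num(
            ((n0 - 1) * a0 + (n1 - 1) * a1) / (n0 + n1 - 2), nan=0.0
        )
        alpha = np.maximum(alpha, 0.0)

        testable = (m0 > 0) & (m1 > 0)
        stat = np.full(m0.shape, np.nan)
        pvals = np.full(m0.shape, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_fc_means = np.log(m1) - np.log(m0)
            se = np.sqrt((1.0 / m1 + alpha) / n1 + (1.0 / m0 + alpha) / n0)
        stat[testable] = log_fc_means[testable] / se[testable]
        pvals[testable] = 2.0 * stats.norm.sf(np.abs(stat[testable]))
        fdr = benjamini_hochberg(pvals)

        med0 = np.median(x0, axis=1)
        med1 = np.median(x1, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold_change = np.where(
                med0 > 0, med1 / med0, np.where(med1 > 0, np.inf, np.nan)
            )
        marker = (
            np.nan_to_num(fold_change, nan=0.0) > self.fc_threshold
        ) & (np.nan_to_num(fdr, nan=1.0) < self.fdr_threshold)

        self.size_factors_ = factors
        self.results_ = pd.DataFrame(
            {
                "fold_change": fold_change,
                "stat": stat,
                "p": pvals,
                "fdr": fdr,
                "marker": marker,
            },
            index=counts.counts.index,
        )
        self.n_markers_ = int(marker.sum())
        return self


def de_screen(
    counts: CountMatrix, fc_threshold: float = 2.0, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Run the NB marker screen and return the per-gene results table."""
    return NegativeBinomialScreen(fc_threshold, fdr_threshold).fit(counts).results_
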