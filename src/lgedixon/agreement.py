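"""Agreement statistics: ICC(A,1) and Bland-Altman limits of agreement.

The intraclass correlation follows the two-way model with absolute
agreement for a single rater/measurement (McGraw-Wong ICC(A,1)).  From the
two-way ANOVA mean squares for rows/subjects (MSR), columns/raters (MSC)
and residual (MSE), with n subjects and k raters:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

The 95% confidence interval uses the F-distribution construction for the
absolute-agreement two-way model with a Satterthwaite-style denominator
degrees-of-freedom.  Bland-Altman analysis reports the mean difference
(bias), the sample SD of the differences (n-1 denominator), and the 95%
limits of agreement bias +/- 1.96 SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

LOA_MULTIPLIER = 1.96


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int
    model: str = "two-way mixed, absolute agreement, single measurement (ICC(A,1))"

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_subjects": self.n_subjects,
            "n_raters": self.n_raters,
            "model": self.model,
        }


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
        }


@dataclass
class AgreementResult:
    """Combined evidence for one method pair: ICC plus Bland-Altman."""

    icc: float
    ci_low: float
    ci_high: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _as_table(table, min_raters: int = 2) -> np.ndarray:
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"ratings table must be 2-D (subjects x raters), got shape {x.shape}")
    n, k = x.shape
    if n < 2:
        raise ValueError(f"need at least 2 subjects, got {n}")
    if k < min_raters:
        raise ValueError(f"need at least {min_raters} raters, got {k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings table contains missing or non-finite cells")
    return x


def anova_mean_squares(table) -> tuple[float, float, float]:
    """Two-way (subjects x raters) ANOVA mean squares (MSR, MSC, MSE)."""
    x = _as_table(table)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc_a1(table, confidence: float = 0.95) -> IccResult:
    """ICC(A,1) point estimate with its F-based confidence interval."""
    x = _as_table(table)
    n, k = x.shape
    if np.ptp(x) == 0:
        raise ValueError("ratings table is constant: total variance is zero")
    msr, msc, mse = anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("degenerate table: ICC denominator is zero")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse <= 0 and msc <= 0:
        # Columns identical: perfect absolute agreement.
        return IccResult(1.0, 1.0, 1.0, n, k)

    r = icc
    a = k * r / (n * (1.0 - r)) if r < 1 else np.inf
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r)) if r < 1 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else (n - 1) * (k - 1)
    else:
        v = (n - 1) * (k - 1)
    v = max(v, 1.0)

    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = (
        n * (msr - f_l * mse)
        / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    )
    upper = (
        n * (f_u * msr - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    )
    lower = float(min(lower, icc))
    upper = float(max(upper, icc))
    return IccResult(float(icc), lower, min(upper, 1.0), n, k)


def bland_altman(table) -> BlandAltmanResult:
    """Bland-Altman analysis of a two-column (method pair) table."""
    x = _as_table(table)
    if x.shape[1] != 2:
        raise ValueError(f"Bland-Altman needs exactly 2 columns, got {x.shape[1]}")
    d = x[:, 0] - x[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    low, high = loa_from_summary(bias, sd)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=low,
        loa_high=high,
        means=x.mean(axis=1),
        diffs=d,
    )


def loa_from_summary(bias: float, sd_diff: float) -> tuple[float, float]:
    """95% limits of agreement from a printed bias and SD: bias +/- 1.96 SD."""
    if sd_diff < 0:
        raise ValueError(f"sd_diff must be non-negative, got {sd_diff}")
    half = LOA_MULTIPLIER * sd_diff
    return bias - half, bias + half


def agreement_summary(table) -> AgreementResult:
    """ICC and Bland-Altman for a two-column table, in one record."""
    ba = bland_altman(table)
    icc = icc_a1(table)
    return AgreementResult(
        icc=icc.icc,
        ci_low=icc.ci_low,
        ci_high=icc.ci_high,
        bias=ba.bias,
        sd_diff=ba.sd_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
    )


def simulate_raters(
    true_values,
    rater_bias,
    noise_sd,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a complete subjects-by-raters table.

    table[i, j] = true_values[i] + rater_bias[j] + N(0, noise_sd[j]); noise_sd
    may be a scalar (shared) or per-rater.  Seeded and reproducible.
    """
    tv = np.asarray(true_values, dtype=float)
    rb = np.asarray(rater_bias, dtype=float)
    if tv.ndim != 1 or rb.ndim != 1:
        raise ValueError("true_values and rater_bias must be 1-D")
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), rb.shape).copy()
    if np.any(sd < 0):
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((tv.size, rb.size)) * sd[None, :]
    return tv[:, None] + rb[None, :] + noise
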