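"""Method-agreement and group-comparison statistics for paired SCP values.

Agreement between the sensor-derived and stopwatch-derived stair climb
power is quantified the way method-comparison studies conventionally do:

* Pearson product-moment correlation (consistency),
* ICC(2,1) -- two-way random effects, absolute agreement, single
  measurement -- with a 95% CI by the F-distribution method,
* Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 sd of the
  paired differences), with normal-theory CIs,
* Welch unequal-variance two-sample t tests for group effects (age, sex),
  reported with fractional Welch-Satterthwaite degrees of freedom.

The difference direction is fixed as method A minus method B, with A the
stopwatch (reference) method and B the sensor method, so a negative bias
means the sensor overestimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "pearson_correlation",
    "icc_2_1",
    "bland_altman",
    "welch_t_test",
    "agreement_report",
    "bland_altman_plot",
]


@dataclass
class PairedMeasurements:
    """Per-subject paired values from two measurement methods (watts)."""

    method_a: np.ndarray  # reference (e.g. stopwatch SCP)
    method_b: np.ndarray  # comparator (e.g. sensor SCP)
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.method_a = np.asarray(self.method_a, dtype=float)
        self.method_b = np.asarray(self.method_b, dtype=float)
        if self.method_a.shape != self.method_b.shape or self.method_a.ndim != 1:
            raise ValueError("paired methods must be equal-length 1-d arrays")
        if not (np.all(np.isfinite(self.method_a)) and np.all(np.isfinite(self.method_b))):
            raise ValueError("missing or non-finite pairs are not allowed")

    @property
    def n(self) -> int:
        return int(self.method_a.size)


class PearsonResult(NamedTuple):
    r: float
    p: float


class IccResult(NamedTuple):
    icc: float
    lower: float
    upper: float


class BlandAltmanResult(NamedTuple):
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    bias_ci: tuple[float, float]
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def pearson_correlation(pairs: PairedMeasurements) -> PearsonResult:
    """Pearson r with two-sided t-based p value."""
    if pairs.n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(pairs.method_a) == 0.0 or np.std(pairs.method_b) == 0.0:
        raise ValueError("correlation undefined: a method has zero variance")
    res = stats.pearsonr(pairs.method_a, pairs.method_b)
    return PearsonResult(float(res.statistic), float(res.pvalue))


def icc_2_1(pairs: PairedMeasurements, ci: float = 0.95) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rating.

    Computed from the two-way ANOVA mean squares (subjects x methods)
    with the F-distribution confidence interval of the McGraw-Wong
    convention.  Perfectly identical methods short-circuit to
    ``(1, 1, 1)``.
    """
    if pairs.n < 5:
        raise ValueError("need at least 5 subjects for a stable ICC")
    data = np.column_stack([pairs.method_a, pairs.method_b])
    n, k = data.shape

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)  # between subjects
    msc = ss_cols / (k - 1)  # between methods
    mse = ss_err / ((n - 1) * (k - 1))  # residual

    if np.array_equal(pairs.method_a, pairs.method_b):
        # exact agreement: no residual or method variance to partition
        return IccResult(1.0, 1.0, 1.0)
    # guard the degenerate zero-residual case (e.g. B = A + constant)
    mse = max(mse, 1e-12 * max(msr, msc, 1.0))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom

    alpha = 1.0 - ci
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return IccResult(float(icc), float(lower), float(upper))


def bland_altman(pairs: PairedMeasurements, ci: float = 0.95) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of the paired differences A - B.

    LoA = bias +/- 1.96 sd(d).  CIs use the classical normal-theory
    formulas: SE(bias) = sd/sqrt(n), SE(LoA) = sd*sqrt(3/n), both with
    t(n-1) critical values.
    """
    if pairs.n < 3:
        raise ValueError("need at least 3 pairs")
    d = pairs.method_a - pairs.method_b
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = bias - 1.96 * sd
    loa_high = bias + 1.96 * sd
    tcrit = stats.t.ppf(0.5 + ci / 2, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        bias_ci=(bias - tcrit * se_bias, bias + tcrit * se_bias),
        loa_low_ci=(loa_low - tcrit * se_loa, loa_low + tcrit * se_loa),
        loa_high_ci=(loa_high - tcrit * se_loa, loa_high + tcrit * se_loa),
    )


def welch_t_test(values: Sequence[float], groups: Sequence) -> WelchResult:
    """Welch unequal-variance two-sample t test with fractional df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {levels.size}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0.0:
        return WelchResult(0.0, float(na + nb - 2), 1.0)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


@dataclass
class AgreementReport:
    """Bundle of the full agreement analysis for one paired comparison."""

    pearson: PearsonResult
    icc: IccResult
    bland_altman: BlandAltmanResult
    t_tests: dict[str, dict[str, WelchResult]]
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson": {"r": self.pearson.r, "p": self.pearson.p},
            "icc": {
                "icc": self.icc.icc,
                "lower": self.icc.lower,
                "upper": self.icc.upper,
            },
            "bland_altman": {
                "bias": self.bland_altman.bias,
                "sd": self.bland_altman.sd,
                "loa": [self.bland_altman.loa_low, self.bland_altman.loa_high],
                "bias_ci": list(self.bland_altman.bias_ci),
                "loa_low_ci": list(self.bland_altman.loa_low_ci),
                "loa_high_ci": list(self.bland_altman.loa_high_ci),
            },
            "t_tests": {
                g: {
                    m: {"t": r.t, "df": r.df, "p": r.p}
                    for m, r in per_method.items()
                }
                for g, per_method in self.t_tests.items()
            },
        }


def agreement_report(pairs: PairedMeasurements) -> AgreementReport:
    """Run the full agreement suite, including per-grouping Welch tests."""
    t_tests: dict[str, dict[str, WelchResult]] = {}
    for name, labels in pairs.groups.items():
        t_tests[name] = {
            "method_a": welch_t_test(pairs.method_a, labels),
            "method_b": welch_t_test(pairs.method_b, labels),
        }
    return AgreementReport(
        pearson=pearson_correlation(pairs),
        icc=icc_2_1(pairs),
        bland_altman=bland_altman(pairs),
        t_tests=t_tests,
        n=pairs.n,
    )


def bland_altman_plot(pairs: PairedMeasurements, path: str) -> None:
    """Save a Bland-Altman scatter with bias and LoA lines (optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(pairs)
    means = (pairs.method_a + pairs.method_b) / 2.0
    diffs = pairs.method_a - pairs.method_b
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=14, alpha=0.7)
    ax.axhline(0.0, color="red", lw=1)
    ax.axhline(ba.bias, color="blue", lw=1.2, label=f"bias = {ba.bias:.2f} W")
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="green", lw=1, ls="--")
    ax.set_xlabel("mean of methods (W)")
    ax.set_ylabel("difference A - B (W)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
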