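"""Agreement and repeated-measures statistics for paired device data.

Implements the validation toolkit for comparing two measurement methods on
the same subjects: Bland-Altman limits of agreement (classic and the
repeated-measures variant that splits the difference variance into within-
and between-subject components), intraclass correlation ICC(A,1) with
F-based confidence intervals, the repeated-measures correlation (common
slope ANCOVA with subject-specific intercepts), paired t-tests, and the
Shapiro-Wilk and variance-ratio distributional gates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedObservations",
    "AgreementResult",
    "IccResult",
    "RmCorrResult",
    "bland_altman",
    "icc_absolute_single",
    "rm_corr",
    "r_squared_rm",
    "paired_t",
    "shapiro_wilk",
    "variance_f_test",
    "bland_altman_plot",
]

Z95 = 1.96  # conventional 95% limits-of-agreement multiplier


@dataclass
class PairedObservations:
    """Paired measurements (same units) grouped by subject."""

    subject: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.subject = np.asarray(self.subject)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.subject) == len(self.x) == len(self.y)):
            raise ValueError("subject, x and y must have equal length")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise ValueError("missing pairs are not allowed")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.subject))


@dataclass
class AgreementResult:
    bias: float
    loa_lower: float
    loa_upper: float
    sd_total: float
    var_between: float
    var_within: float
    n_subjects: int
    n_pairs: int
    method: str
    bias_ci: tuple[float, float] | None = None
    loa_lower_ci: tuple[float, float] | None = None
    loa_upper_ci: tuple[float, float] | None = None


def _oneway_anova_components(subject: np.ndarray, d: np.ndarray):
    """Variance components of d under a one-way random-effects model.

    Returns (sigma2_between, sigma2_within, df_between, df_within) using
    expected mean squares with the unbalanced-design coefficient n0.
    """
    groups = [d[subject == s] for s in np.unique(subject)]
    k = len(groups)
    N = len(d)
    grand = d.mean()
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    dfw, dfb = N - k, k - 1
    msw = ssw / dfw if dfw > 0 else 0.0
    msb = ssb / dfb if dfb > 0 else 0.0
    n0 = (N - sum(len(g) ** 2 for g in groups) / N) / dfb if dfb > 0 else 1.0
    s2w = msw
    s2b = max(0.0, (msb - msw) / n0) if n0 > 0 else 0.0
    return s2b, s2w, dfb, dfw


def bland_altman(pairs: PairedObservations, ci: bool = False,
                 alpha: float = 0.05) -> AgreementResult:
    """Bland-Altman agreement with 95% limits ``bias +/- 1.96 sd``.

    Differences are ``d = y - x`` (second-listed minus first-listed method).
    With repeated observations per subject the SD of differences is
    ``sqrt(sigma2_between + sigma2_within)`` from a one-way random-effects
    ANOVA with subject as the factor, so the limits describe a difference
    for a new observation on a new subject.  Input from a single subject
    (or one pair per subject) degrades to the classic formula.

    ``ci=True`` adds confidence intervals: a t-interval on the bias and
    MOVER-style intervals on each limit of agreement.
    """
    if len(pairs) < 3:
        raise ValueError("Bland-Altman requires at least 3 pairs")
    d = pairs.y - pairs.x
    bias = float(d.mean())
    counts = np.unique(pairs.subject, return_counts=True)[1]
    repeated = pairs.n_subjects >= 2 and np.any(counts >= 2)
    if repeated:
        s2b, s2w, dfb, dfw = _oneway_anova_components(pairs.subject, d)
        sd = float(np.sqrt(s2b + s2w))
        df_eff = dfb  # subject-level df for the bias
        method = "repeated-measures"
    else:
        s2w = float(d.var(ddof=1))
        s2b = 0.0
        sd = float(np.sqrt(s2w))
        df_eff = len(d) - 1
        method = "classic"
    res = AgreementResult(
        bias=bias, loa_lower=bias - Z95 * sd, loa_upper=bias + Z95 * sd,
        sd_total=sd, var_between=s2b, var_within=s2w,
        n_subjects=pairs.n_subjects, n_pairs=len(pairs), method=method,
    )
    if ci and sd > 0:
        n = len(d)
        df = max(df_eff, 1)
        se_bias = sd / np.sqrt(pairs.n_subjects if repeated else n)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        res.bias_ci = (bias - tcrit * se_bias, bias + tcrit * se_bias)
        # MOVER: combine bias uncertainty with chi-square limits on sd
        chi_lo = np.sqrt(df / stats.chi2.ppf(1 - alpha / 2, df))
        chi_hi = np.sqrt(df / stats.chi2.ppf(alpha / 2, df))
        for sign in (-1, 1):
            l = bias + sign * Z95 * sd
            half = np.sqrt((tcrit * se_bias) ** 2 + (Z95 * sd * (chi_hi - 1)) ** 2)
            half_in = np.sqrt((tcrit * se_bias) ** 2 + (Z95 * sd * (1 - chi_lo)) ** 2)
            interval = (l - (half if sign < 0 else half_in),
                        l + (half_in if sign < 0 else half))
            if sign < 0:
                res.loa_lower_ci = interval
            else:
                res.loa_upper_ci = interval
    return res


@dataclass
class IccResult:
    icc: float
    ci_lower: float
    ci_upper: float
    model: str
    ms: dict = field(default_factory=dict)
    warning: str | None = None


def icc_absolute_single(pairs: PairedObservations, model: str = "two-way random",
                        alpha: float = 0.05) -> IccResult:
    """ICC(A,1): single-measurement, absolute-agreement intraclass correlation.

    Subjects are rows, the two methods are columns of a two-way ANOVA;
    ``ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))``.
    The 95% CI uses the F-distribution closed forms (McGraw & Wong).  The
    ``model`` label ("two-way random" or "two-way mixed") records the
    intended inference; estimate and CI are computed identically, as in the
    standard implementations.

    Each subject must contribute exactly one x and one y; with repeated
    observations pass per-subject means or per-occasion pseudo-subjects.
    """
    subjects = np.unique(pairs.subject)
    n = len(subjects)
    if n < 2:
        raise ValueError("ICC requires at least 2 subjects")
    rows = np.empty((n, 2))
    for i, s in enumerate(subjects):
        m = pairs.subject == s
        if np.count_nonzero(m) != 1:
            raise ValueError(
                "ICC expects exactly one (x, y) pair per subject; aggregate "
                "repeated observations first"
            )
        rows[i] = [pairs.x[m][0], pairs.y[m][0]]
    k = 2
    grand = rows.mean()
    msr = k * ((rows.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((rows.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sst = ((rows - grand) ** 2).sum()
    sse = sst - msr * (n - 1) - msc * (k - 1)
    dfe = (n - 1) * (k - 1)
    mse = sse / dfe
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    warning = None
    if denom <= 0:
        icc = 0.0
        warning = "degenerate ANOVA table; ICC clamped to 0"
    else:
        icc = (msr - mse) / denom
    icc = float(np.clip(icc, -1.0, 1.0))

    # McGraw & Wong F-based CI for ICC(A,1)
    if mse <= 0 or icc >= 1.0:
        lo = hi = icc  # perfect agreement: the interval degenerates
    else:
        a = k * icc / (n * (1 - icc))
        b = 1 + k * icc * (n - 1) / (n * (1 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    lo, hi = float(min(lo, icc)), float(max(hi, icc))
    return IccResult(icc=icc, ci_lower=max(lo, -1.0), ci_upper=min(hi, 1.0),
                     model=model, ms={"MSR": float(msr), "MSC": float(msc),
                                      "MSE": float(mse)}, warning=warning)


@dataclass
class RmCorrResult:
    r_rm: float
    df: int
    p_value: float
    slope: float
    n_subjects_used: int
    dropped_subjects: list = field(default_factory=list)


def rm_corr(pairs: PairedObservations) -> RmCorrResult:
    """Repeated-measures correlation: within-subject association with a
    common slope.

    Equivalent to ANCOVA of y on x with subject as a categorical factor:
    after centring x and y within subjects, ``r_rm`` is their correlation
    and ``df = N - n_subjects - 1``.  Invariant to adding any per-subject
    constant to x or y.  Subjects with fewer than 2 observations carry no
    within-subject information and are dropped.
    """
    keep = np.ones(len(pairs), dtype=bool)
    dropped = []
    for s in np.unique(pairs.subject):
        m = pairs.subject == s
        if np.count_nonzero(m) < 2:
            keep &= ~m
            dropped.append(s)
    subject, x, y = pairs.subject[keep], pairs.x[keep], pairs.y[keep]
    n_subj = len(np.unique(subject))
    if n_subj < 2:
        raise ValueError("repeated-measures correlation needs >= 2 subjects with >= 2 observations")
    xc = x.copy()
    yc = y.copy()
    for s in np.unique(subject):
        m = subject == s
        xc[m] -= x[m].mean()
        yc[m] -= y[m].mean()
    sxx = float(np.dot(xc, xc))
    syy = float(np.dot(yc, yc))
    sxy = float(np.dot(xc, yc))
    if sxx == 0 or syy == 0:
        raise ValueError("no within-subject variance; r_rm undefined")
    r = sxy / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    df = len(x) - n_subj - 1
    if df <= 0:
        raise ValueError("insufficient residual degrees of freedom")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        f = r * r / (1 - r * r) * df
        p = float(stats.f.sf(f, 1, df))
    return RmCorrResult(r_rm=r, df=df, p_value=p, slope=sxy / sxx,
                        n_subjects_used=n_subj, dropped_subjects=dropped)


def r_squared_rm(pairs: PairedObservations) -> float:
    """Coefficient of determination of the common-slope fit: ``r_rm ** 2``."""
    return rm_corr(pairs).r_rm ** 2


def paired_t(pairs: PairedObservations):
    """Two-sided paired t-test on ``d = y - x``.

    Returns ``{"t", "df", "p", "zero_variance"}``; a zero-variance nonzero
    difference is reported as infinite t with p -> 0 and the flag set.
    """
    if len(pairs) < 3:
        raise ValueError("paired t-test requires n >= 3")
    d = pairs.y - pairs.x
    sd = d.std(ddof=1)
    n = len(d)
    if sd == 0:
        if d.mean() == 0:
            return {"t": 0.0, "df": n - 1, "p": 1.0, "zero_variance": True}
        return {"t": float(np.sign(d.mean()) * np.inf), "df": n - 1,
                "p": 0.0, "zero_variance": True}
    t, p = stats.ttest_rel(pairs.y, pairs.x)
    return {"t": float(t), "df": n - 1, "p": float(p), "zero_variance": False}


def shapiro_wilk(v):
    """Shapiro-Wilk normality test."""
    v = np.asarray(v, dtype=float)
    if len(v) < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3")
    w, p = stats.shapiro(v)
    return {"W": float(w), "p": float(p)}


def variance_f_test(a, b):
    """Two-sided F-test for equality of variances of two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("variance F-test requires n >= 3 per sample")
    f = a.var(ddof=1) / b.var(ddof=1)
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    return {"F": float(f), "p": float(min(p, 1.0))}


def bland_altman_plot(pairs: PairedObservations, result: AgreementResult | None = None,
                      ax=None, title: str | None = None):
    """Draw a Bland-Altman plot: differences vs pair means, with the bias
    line, the zero line, and dashed 95% limits of agreement."""
    import matplotlib.pyplot as plt

    result = result or bland_altman(pairs)
    if ax is None:
        _, ax = plt.subplots()
    mean = (pairs.x + pairs.y) / 2
    ax.scatter(mean, pairs.y - pairs.x, s=12, alpha=0.6)
    ax.axhline(0, color="grey")
    ax.axhline(result.bias, color="black")
    for loa in (result.loa_lower, result.loa_upper):
        ax.axhline(loa, color="black", linestyle="--")
    ax.set_xlabel("Mean of methods")
    ax.set_ylabel("Difference (second - first)")
    if title:
        ax.set_title(title)
    return ax
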