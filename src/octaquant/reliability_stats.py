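"""Test-retest agreement statistics for repeated OCT-A measurements.

Implements the statistics used to validate an automated quantification
program on repeated scans of the same eyes:

* ICC — the two-way, absolute-agreement, single-measurement intraclass
  correlation ICC(A,1), computed from the ANOVA mean squares

      ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

  with MS_R the between-subject, MS_C the between-session and MS_E the
  residual mean square; 95 % CI by the McGraw-Wong F-distribution bounds.
  The consistency form ICC(C,1) is available behind a flag.

* CR — coefficient of repeatability, 1.96 x SD of the within-subject
  differences between two sessions (Bland-Altman convention): 95 % of
  repeat differences are expected to fall below CR.  CI from chi-square
  bounds on the difference variance.  The 2.77 x within-subject-SD
  convention is available via ``method='within_sd'``.

* Bland-Altman mean difference and 95 % limits of agreement.

* The ICC precision/sample-size relation: an approximate 95 % CI width for
  a planned (n subjects, k raters) design at an assumed ICC, using the
  large-sample variance  2 (1-rho)^2 (1+(k-1) rho)^2 / (k (k-1) (n-1))
  (Bonett 2002) mapped through the Fisher-type transformation
  Z = ln((1+(k-1) rho)/(1-rho)) / 2, and its inverse ``icc_for_width``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DegenerateDataError, UnbalancedDataError

Z95 = stats.norm.ppf(0.975)


@dataclass
class ReliabilityResult:
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    n_subjects: int
    k_raters: int
    cr: Optional[float] = None
    cr_ci_low: Optional[float] = None
    cr_ci_high: Optional[float] = None


@dataclass
class BlandAltman:
    mean_difference: float
    loa_low: float
    loa_high: float
    n_pairs: int
    sd_difference: float = 0.0


def _to_matrix(data) -> np.ndarray:
    """Coerce long-format (subject, session, value) or wide input to n x k."""
    if isinstance(data, pd.DataFrame):
        cols = {c.lower(): c for c in data.columns}
        for key in ("subject_id", "subject"):
            if key in cols:
                subj = cols[key]
                break
        else:
            # already wide: first column = subject id
            return data.set_index(data.columns[0]).to_numpy(dtype=float)
        sess = cols.get("session")
        val = cols.get("value")
        wide = data.pivot(index=subj, columns=sess, values=val)
        if wide.isna().any().any():
            raise UnbalancedDataError(
                "every subject needs a value for every session"
            )
        return wide.to_numpy(dtype=float)
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise UnbalancedDataError("expected an n_subjects x k_sessions array")
    if np.isnan(arr).any():
        raise UnbalancedDataError("missing cells in the subjects x sessions grid")
    return arr


def _anova_ms(x: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return msr, msc, mse, n, k


def icc_two_way(data, form: str = "agreement", confidence: float = 0.95) -> ReliabilityResult:
    """Two-way single-measurement ICC with a 95 % confidence interval.

    ``form='agreement'`` gives ICC(A,1) (absolute agreement; session means
    count against agreement); ``form='consistency'`` gives ICC(C,1).
    Input: long DataFrame (subject_id, session, value) or an n x k array.
    """
    x = _to_matrix(data)
    n, k = x.shape
    if n < 2 or k < 2:
        raise DegenerateDataError("need >= 2 subjects and >= 2 sessions")
    msr, msc, mse, n, k = _anova_ms(x)
    if msr <= 0 and mse <= 0:
        raise DegenerateDataError("zero total variance; ICC undefined")
    alpha = 1.0 - confidence
    if form == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:
            lo = hi = icc
        else:
            fobs = msr / mse
            fl = fobs / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
            fu = fobs * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    elif form == "agreement":
        icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        if mse == 0 and msc == 0:
            lo = hi = icc
        else:
            # McGraw & Wong (1996) CI for ICC(A,1)
            a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
            b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
            if not np.isfinite(a):
                lo = hi = 1.0
            else:
                num = (a * msc + b * mse) ** 2
                den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                v = num / den if den > 0 else 1.0
                f_star_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
                f_star_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
                lo = (
                    n * (msr - f_star_l * mse)
                    / (f_star_l * (k * msc + (k * n - k - n) * mse) + n * msr)
                )
                hi = (
                    n * (f_star_u * msr - mse)
                    / (k * msc + (k * n - k - n) * mse + n * f_star_u * msr)
                )
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    lo, hi = float(min(lo, icc)), float(max(hi, icc))
    return ReliabilityResult(
        icc=float(icc),
        icc_ci_low=max(lo, -1.0),
        icc_ci_high=min(hi, 1.0),
        n_subjects=n,
        k_raters=k,
    )


def coefficient_of_repeatability(
    data, method: str = "bland_altman", confidence: float = 0.95
) -> tuple[float, float, float]:
    """Coefficient of repeatability with a chi-square confidence interval.

    Returns ``(cr, ci_low, ci_high)``.  'bland_altman': 1.96 x SD of the
    paired differences.  'within_sd': 2.77 x within-subject SD (sqrt(MSE)
    of the one-way ANOVA), usable for k > 2.
    """
    x = _to_matrix(data)
    n, k = x.shape
    if n < 3:
        raise DegenerateDataError("need >= 3 subjects for a repeatability CI")
    alpha = 1.0 - confidence
    if method == "bland_altman":
        if k != 2:
            raise UnbalancedDataError("bland_altman CR requires exactly 2 sessions")
        d = x[:, 0] - x[:, 1]
        var = float(np.var(d, ddof=1))
        dof = n - 1
        cr = Z95 * math.sqrt(var)
    elif method == "within_sd":
        # one-way within-subject mean square
        sw2 = float(((x - x.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (k - 1)))
        var, dof = sw2, n * (k - 1)
        cr = math.sqrt(2.0) * Z95 * math.sqrt(sw2)
    else:
        raise ValueError(f"unknown CR method {method!r}")
    if var == 0:
        return cr, 0.0, 0.0
    lo = cr * math.sqrt(dof / stats.chi2.ppf(1 - alpha / 2, dof))
    hi = cr * math.sqrt(dof / stats.chi2.ppf(alpha / 2, dof))
    return cr, float(lo), float(hi)


def bland_altman(pairs: Sequence[tuple[float, float]]) -> BlandAltman:
    """Mean difference and 95 % limits of agreement for paired measurements."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DegenerateDataError("need >= 3 (a, b) pairs")
    d = arr[:, 0] - arr[:, 1]
    mean = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return BlandAltman(
        mean_difference=mean,
        loa_low=mean - Z95 * sd,
        loa_high=mean + Z95 * sd,
        n_pairs=arr.shape[0],
        sd_difference=sd,
    )


def bland_altman_plot(pairs, ax=None, title: Optional[str] = None):
    """Standard Bland-Altman scatter with mean-difference and LoA lines."""
    import matplotlib.pyplot as plt

    ba = bland_altman(pairs)
    arr = np.asarray(pairs, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(arr.mean(axis=1), arr[:, 0] - arr[:, 1], s=18, alpha=0.7)
    for y, style in [(ba.mean_difference, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")]:
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference (a - b)")
    if title:
        ax.set_title(title)
    return ax


def _check_design(n: int, k: int, icc: Optional[float] = None) -> None:
    if n < 5 or k < 2:
        raise ValueError("need n >= 5 subjects and k >= 2 raters")
    if icc is not None and not (0 < icc < 1):
        raise ValueError("assumed ICC must lie strictly in (0, 1)")


def icc_ci_width(n: int, k: int, icc: float, confidence: float = 0.95) -> float:
    """Approximate CI width for an ICC estimated from an (n, k) design.

    Large-sample variance of the ICC estimate (Bonett 2002) propagated
    through the Fisher-type transformation Z = ln((1+(k-1)r)/(1-r))/2; the
    interval is computed on the Z scale and back-transformed, so the width
    respects the [0, 1) boundary.  Width is monotone decreasing in both n
    and icc.
    """
    _check_design(n, k, icc)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    var = 2.0 * (1 - icc) ** 2 * (1 + (k - 1) * icc) ** 2 / (k * (k - 1) * (n - 1))
    # delta method on the transformed scale
    dz_dr = 0.5 * ((k - 1) / (1 + (k - 1) * icc) + 1.0 / (1 - icc))
    sd_z = math.sqrt(var) * dz_dr
    z0 = 0.5 * math.log((1 + (k - 1) * icc) / (1 - icc))

    def back(zv: float) -> float:
        e = math.exp(2.0 * zv)
        return (e - 1.0) / (e + k - 1.0)

    return back(z0 + z * sd_z) - back(z0 - z * sd_z)


def icc_for_width(n: int, k: int, width: float, confidence: float = 0.95) -> float:
    """Invert :func:`icc_ci_width`: the ICC detectable at a given CI width.

    Returns the ICC whose approximate CI width for the (n, k) design equals
    ``width``; e.g. 30 subjects with two raters resolve an ICC near 0.86 to
    a width of 0.2.
    """
    _check_design(n, k)
    if not (0 < width < 1):
        raise ValueError("width must lie in (0, 1)")
    lo, hi = 1e-6, 1.0 - 1e-9
    f = lambda r: icc_ci_width(n, k, r, confidence) - width
    if f(lo) < 0:
        raise ValueError(f"width {width} not attainable with n={n}, k={k}")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def reliability_summary(data, cr_method: str = "bland_altman") -> ReliabilityResult:
    """ICC(A,1) plus CR for a repeated-measures table, in one record."""
    res = icc_two_way(data)
    cr, lo, hi = coefficient_of_repeatability(data, method=cr_method)
    res.cr, res.cr_ci_low, res.cr_ci_high = cr, lo, hi
    return res
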