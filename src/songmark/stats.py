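"""Differential-expression statistics for one nucleus-vs-surround contrast.

Two-channel arrays go through "half" background correction, within-array
print-tip loess normalization of the M-vs-A trend, and a sample-over-
reference orientation step (the common-reference, dye-balanced design means
half the arrays carry the sample in Cy3).  Oligo-array values arrive
pre-normalized and instead pass a ranked-intensity low-signal filter and a
coefficient-of-variation filter.  Both paths end in an empirical-Bayes
moderated two-group t-test with method-of-moments variance shrinkage and
multiple-testing adjustment (Benjamini-Hochberg or Storey q-values).

The moderated test follows the standard hierarchical model: per-probe
residual variances s_g^2 with d_g degrees of freedom are shrunk toward a
prior (d0, s0^2) fitted by moments on log s_g^2, giving posterior variances
s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g) and t-statistics on d0 + d_g
degrees of freedom.  d0 = 0 recovers the ordinary pooled t exactly and
d0 -> infinity the fixed-variance z-form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModeratedModel",
    "background_correct_half",
    "normalize_within_array",
    "to_sample_over_reference",
    "process_two_channel",
    "low_signal_cutoff",
    "high_variance_filter",
    "fit_fdist_moments",
    "fit_moderated_t",
    "adjust_pvalues",
]


def background_correct_half(fg, bg):
    """Subtract local background from foreground; zero or negative results
    are set to 0.5 so no spot is lost to the log transform."""
    fg = np.asarray(fg, dtype=float)
    bg = np.asarray(bg, dtype=float)
    if np.any(fg < 0) or np.any(bg < 0):
        raise ValueError("foreground and background intensities must be >= 0")
    out = fg - bg
    return np.where(out > 0, out, 0.5)


def normalize_within_array(
    M,
    A,
    tip_groups=None,
    span: float = 0.3,
    iterations: int = 3,
    min_group: int = 50,
):
    """Print-tip loess normalization: per tip group, subtract a robust
    loess fit of M on A (span 0.3, degree 1, 3 robustness iterations).

    Groups smaller than ``min_group`` probes fall back to the global loess
    curve — a local fit on a handful of spots would chase real signal
    rather than dye bias; a group whose A values are all identical has its
    median M subtracted instead.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    if M.shape != A.shape:
        raise ValueError("M and A must have the same shape")

    def _fit(m, a):
        if np.ptp(a) == 0:
            return np.full_like(m, np.median(m))
        return lowess(m, a, frac=span, it=iterations, return_sorted=False)

    if tip_groups is None:
        return M - _fit(M, A)

    tip_groups = np.asarray(tip_groups)
    out = np.empty_like(M)
    global_fit = None
    for g in np.unique(tip_groups):
        idx = tip_groups == g
        if idx.sum() < min_group:
            if global_fit is None:
                global_fit = _fit(M, A)
            out[idx] = M[idx] - global_fit[idx]
        else:
            out[idx] = M[idx] - _fit(M[idx], A[idx])
    return out


def to_sample_over_reference(M, dye_of_sample):
    """Orient a log-ratio so it reads log2(sample/reference).

    M is log2(Cy5/Cy3); when the sample was labeled with Cy3 the ratio is
    inverted, i.e. the sign flips.
    """
    M = np.asarray(M, dtype=float)
    if isinstance(dye_of_sample, str):
        if dye_of_sample == "Cy5":
            return M.copy()
        if dye_of_sample == "Cy3":
            return -M
        raise ValueError(f"unknown dye orientation {dye_of_sample!r}")
    dye = np.asarray(dye_of_sample)
    bad = ~np.isin(dye, ("Cy5", "Cy3"))
    if bad.any():
        raise ValueError(f"unknown dye orientation {dye[bad][0]!r}")
    return np.where(dye == "Cy5", M, -M)


def process_two_channel(
    arrays: dict[str, pd.DataFrame],
    design: pd.DataFrame,
    tip_groups=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Background-correct, normalize and orient a set of two-channel arrays.

    Returns (ratios, avalues): probes x arrays frames of oriented
    normalized log2(sample/reference) and mean log2 intensity.
    """
    ratios = {}
    avals = {}
    tips = None if tip_groups is None else np.asarray(tip_groups)
    for row in design.itertuples(index=False):
        arr = arrays[row.array_id]
        cy5 = background_correct_half(arr["F_Cy5"], arr["B_Cy5"])
        cy3 = background_correct_half(arr["F_Cy3"], arr["B_Cy3"])
        M = np.log2(cy5) - np.log2(cy3)
        A = 0.5 * (np.log2(cy5) + np.log2(cy3))
        M = normalize_within_array(M, A, tip_groups=tips)
        ratios[row.array_id] = to_sample_over_reference(M, row.dye_of_sample)
        avals[row.array_id] = A
    index = arrays[design["array_id"].iloc[0]].index
    return (
        pd.DataFrame(ratios, index=index),
        pd.DataFrame(avals, index=index),
    )


def low_signal_cutoff(
    region_means: pd.DataFrame,
    statistic: str = "max",
    window_frac: float = 0.01,
    k_sd: float = 2.5,
    slope_ratio: float = 10.0,
):
    """Rank-intensity low-signal filter.

    Per probe the detection statistic is the max (default) or mean of its
    per-region mean intensities.  Probes are ranked high to low; the
    inflection where the curve drops onto the near-background shoulder is
    located automatically: the cliff is the steepest interior descent of
    the rank-smoothed curve, and the inflection point is where the descent
    relaxes again, i.e. the top of the background shoulder.  The removal
    threshold is the mean of the statistic over a ``window_frac`` rank
    window at the inflection plus ``k_sd`` times its standard deviation;
    probes below the threshold are removed.

    A curve with no detectable inflection (the steepest interior descent is
    less than ``slope_ratio`` times the median descent, as for a unimodal
    expressed-only array) triggers a warning and removes nothing.

    Returns (threshold, removed_index, info dict).
    """
    if statistic == "max":
        stat = region_means.max(axis=1)
    elif statistic == "mean":
        stat = region_means.mean(axis=1)
    else:
        raise ValueError("statistic must be 'max' or 'mean'")

    order = stat.sort_values(ascending=False, kind="stable")
    y = order.to_numpy(dtype=float)
    n = len(y)
    info = {"method": "fallback", "knee_rank": None, "statistic": statistic}
    if n < 50 or np.ptp(y) == 0:
        warnings.warn("too few probes or flat curve; low-signal filter skipped")
        return -np.inf, stat.index[:0], info

    w = max(5, int(round(window_frac * n)))
    smooth = np.convolve(y, np.ones(w) / w, mode="same")
    slopes = -np.gradient(smooth)  # positive descent per rank
    lo, hi = int(0.05 * n), int(0.95 * n)
    interior = slopes[lo:hi]
    med = float(np.median(interior))
    cliff = lo + int(np.argmax(interior))
    peak = float(slopes[cliff])
    if med <= 0 or peak < slope_ratio * med:
        warnings.warn("no detectable inflection in rank-intensity curve; "
                      "low-signal filter removed nothing")
        return -np.inf, stat.index[:0], info

    # walk down the cliff until the descent relaxes: that rank is the
    # inflection, the top of the near-background shoulder
    relax = max(peak / 3.0, 2.0 * med)
    after = np.nonzero(slopes[cliff:] <= relax)[0]
    knee = cliff + int(after[0]) if len(after) else cliff
    knee = min(knee, n - 1)

    wlo = knee
    whi = min(n, knee + 2 * w + 1)
    window = y[wlo:whi]
    if len(window) < 3:
        warnings.warn("inflection too close to the curve end; filter skipped")
        return -np.inf, stat.index[:0], info
    threshold = float(window.mean() + k_sd * window.std(ddof=1))
    removed = stat.index[stat < threshold]
    info.update(method="knee", knee_rank=knee, cliff_rank=cliff,
                window=(wlo, whi))
    return threshold, removed, info


def high_variance_filter(values: pd.DataFrame, factor: float = 2.0):
    """Coefficient-of-variation filter on unlogged normalized intensities.

    Removes probes whose stdev/mean across samples is strictly greater than
    ``factor`` times the population-mean CV; probes with a non-positive
    mean cannot yield a CV and are removed with their own flag.

    Returns (removed_index, cv series, threshold, nonpositive_index).
    """
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    bad = means <= 0
    cv = sds / means.where(~bad)
    mean_cv = float(cv[~bad].mean())
    threshold = factor * mean_cv
    removed = cv.index[(~bad) & (cv > threshold)]
    return removed, cv, threshold, cv.index[bad]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_fdist_moments(s2, dg) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse chi-square variance prior.

    Matches the classical empirical-Bayes recipe: moments of log s^2 give
    the prior degrees of freedom d0 (via the inverse trigamma) and the
    prior variance s0^2.  When the moment equation has no positive solution
    the prior is degenerate (d0 = infinity, complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    dg = np.broadcast_to(np.asarray(dg, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (dg > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmedian(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    z = np.log(s2[ok])
    d = dg[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0).mean()
    if evar > 0:
        half_d0 = _trigamma_inverse(evar)
        d0 = 2.0 * half_d0
        s0sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    else:
        d0 = np.inf
        s0sq = float(np.exp(emean))
    return d0, s0sq


@dataclass
class ModeratedModel:
    """Fitted variance-moderation hyperparameters for one contrast."""

    d0: float      # prior degrees of freedom (may be inf)
    s0sq: float    # prior variance
    dg: float      # per-probe residual degrees of freedom
    n1: int
    n2: int


def fit_moderated_t(
    values: pd.DataFrame,
    groups,
    group_order: tuple[str, str] = ("nucleus", "surround"),
    d0: float | None = None,
    s0sq: float | None = None,
    adjust: str = "BH",
) -> tuple[pd.DataFrame, ModeratedModel]:
    """Moderated two-group t-test over a probes x samples matrix.

    ``groups`` labels each column; ``group_order`` fixes the sign of the
    contrast as first minus second (nucleus minus surround).  When ``d0``
    is None the prior is estimated by moments on log s^2; explicit d0 = 0
    and d0 = inf give the ordinary pooled t and the fixed-variance z-form.

    Returns a stats frame (probe_id, M, A, s2, t_mod, df_total, p, q) and
    the fitted :class:`ModeratedModel`.
    """
    groups = np.asarray(groups)
    g1, g2 = group_order
    m1 = values.loc[:, groups == g1]
    m2 = values.loc[:, groups == g2]
    n1, n2 = m1.shape[1], m2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    dg = n1 + n2 - 2

    mean1 = m1.mean(axis=1).to_numpy()
    mean2 = m2.mean(axis=1).to_numpy()
    M = mean1 - mean2
    A = values.mean(axis=1).to_numpy()
    ss = m1.var(axis=1, ddof=1).to_numpy() * (n1 - 1) + m2.var(
        axis=1, ddof=1
    ).to_numpy() * (n2 - 1)
    s2 = ss / dg

    if d0 is None:
        d0, s0sq_fit = fit_fdist_moments(s2, dg)
        s0sq = s0sq_fit if s0sq is None else s0sq
    elif d0 > 0 and s0sq is None:
        _, s0sq = fit_fdist_moments(s2, dg)
    if d0 == 0:
        s2_post = s2
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
    else:
        s2_post = (d0 * s0sq + dg * s2) / (d0 + dg)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = M / se
    df_total = d0 + dg
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    q = adjust_pvalues(p, method=adjust)

    out = pd.DataFrame(
        {
            "probe_id": values.index.to_numpy(),
            "M": M,
            "A": A,
            "s2": s2,
            "t_mod": t,
            "df_total": df_total,
            "p": p,
            "q": q,
        }
    )
    model = ModeratedModel(
        d0=float(d0), s0sq=float(s0sq) if s0sq is not None else float("nan"),
        dg=float(dg), n1=n1, n2=n2,
    )
    return out, model


def storey_pi0(p, lambdas=None) -> float:
    """Median-lambda estimate of the null proportion pi0, clipped to (0,1]."""
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = len(p)
    ests = [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
    pi0 = float(np.median(ests))
    return min(max(pi0, np.finfo(float).tiny), 1.0)


def adjust_pvalues(p, method: str = "BH"):
    """Multiple-testing adjustment.

    ``BH`` is the Benjamini-Hochberg step-up; ``storey`` rescales the BH
    q-values by the estimated null proportion pi0 (median-lambda smoother),
    reducing exactly to BH when pi0 = 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "BH":
        return q
    if method == "storey":
        return np.minimum(q * storey_pi0(p), 1.0)
    raise ValueError(f"unknown adjustment method {method!r}")
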