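"""Joinpoint (piecewise log-linear) trend models for rate time series.

The model assumes the log of the rate follows a continuous piecewise
linear path in time,

    ln r(t) = b0 + b1 * t + sum_j d_j * (t - tau_j)+

with hinge terms at joinpoint years ``tau_j`` placed at observed years.
For each candidate number of joinpoints ``k`` an exhaustive grid search
over admissible placements is fitted by (optionally weighted) least
squares, and the number and location of joinpoints is selected by the
Bayesian Information Criterion

    BIC = n * ln(SSE / n) + (2k + 2) * ln(n)

where each joinpoint is charged two parameters, one for its location and
one for its slope change — the convention of the standard joinpoint
surveillance software.  Exact BIC ties resolve to fewer joinpoints, then
to the earliest placement.

Each segment reports the annual percent change APC = 100*(exp(b) - 1) of
its log-scale slope with a t-based confidence interval, and the fit
reports the average annual percent change (AAPC), the segment-length
weighted geometric mean of the per-year rate multipliers, with a delta
method interval on the weighted slope.

Rates derived from Poisson death counts have log-scale variance close to
1/count, so observations can be precision-weighted: ``weighting="count"``
uses supplied counts, ``weighting="rate"`` uses the rate itself as a
proxy when denominators are unavailable but roughly constant, and
``weighting="none"`` (default) fits ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .io import RateSeries

__all__ = [
    "JoinpointRegression",
    "Segment",
    "fit_loglinear",
    "fit_joinpoint",
    "label_trend",
    "admissible_placements",
]


def label_trend(ci_low: float, ci_high: float) -> str:
    """Trend label from a confidence interval on a percent change."""
    if ci_low > 0:
        return "Increasing"
    if ci_high < 0:
        return "Decreasing"
    return "Stable"


def significance_bin(p: float) -> str:
    """Significance marker bins used in surveillance trend tables."""
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return "<0.01"
    if p < 0.05:
        return "<0.05"
    return "ns"


@dataclass(frozen=True)
class Segment:
    """One fitted segment between consecutive boundary years (inclusive).

    The boundary year shared with the adjacent segment belongs to both.
    ``slope`` is the log-scale slope per year; APC and its CI are on the
    percent scale.
    """

    start_year: int
    end_year: int
    slope: float
    slope_se: float
    apc: float
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def label(self) -> str:
        return label_trend(self.ci_low, self.ci_high)

    @property
    def significance(self) -> str:
        return significance_bin(self.p_value)


def fit_loglinear(years: Sequence[float], rates: Sequence[float],
                  weights: Optional[Sequence[float]] = None):
    """Least squares of ln(rate) on year for a single segment.

    Returns ``(slope, intercept, slope_se, p_value)`` with a two-sided p
    from the slope t statistic on n-2 degrees of freedom.  Noiseless
    input gives a zero standard error.
    """
    t = np.asarray(years, dtype=float)
    r = np.asarray(rates, dtype=float)
    if len(t) < 2:
        raise ValueError("at least two observations are required")
    if np.any(r <= 0):
        raise ValueError("rates must be positive on the log scale; "
                         "see the zero_rate policy of JoinpointRegression")
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    y = np.log(r)
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta
    sse = float(w @ resid**2)
    df = len(t) - 2
    if df <= 0:
        return float(beta[1]), float(beta[0]), np.nan, np.nan
    s2 = sse / df
    cov = s2 * np.linalg.inv((X * w[:, None]).T @ X)
    se = float(np.sqrt(cov[1, 1]))
    if se == 0.0:
        p = 0.0 if beta[1] != 0 else 1.0
    else:
        p = float(2 * stats.t.sf(abs(beta[1] / se), df))
    return float(beta[1]), float(beta[0]), se, p


def admissible_placements(n: int, k: int, min_obs: int) -> list[tuple[int, ...]]:
    """Index tuples of k joinpoints among n observations.

    Consecutive boundaries (the data ends and every joinpoint) must be at
    least ``min_obs`` observations apart, so each segment contributes
    ``min_obs`` observations beyond the boundary it shares with its
    predecessor.
    """
    if k == 0:
        return [()]
    out = []
    for combo in combinations(range(min_obs, n - min_obs), k):
        if all(b - a >= min_obs for a, b in zip(combo, combo[1:])):
            out.append(combo)
    return out


def _hinge_design(t: np.ndarray, taus: Sequence[float]) -> np.ndarray:
    cols = [np.ones_like(t), t]
    cols += [np.maximum(t - tau, 0.0) for tau in taus]
    return np.column_stack(cols)


class JoinpointRegression(RegressorMixin, BaseEstimator):
    """Piecewise log-linear trend model with BIC joinpoint selection.

    Parameters
    ----------
    max_joinpoints : int or None
        Largest number of joinpoints searched.  ``None`` uses 3 for
        series of at least 20 observations and otherwise the most the
        minimum-segment rule admits.
    min_obs_per_segment : int
        Observations each segment must contribute beyond the boundary
        shared with its predecessor (equivalently, the minimum spacing of
        boundary indices).
    weighting : {"none", "rate", "count"}
        Observation weights for the least-squares fit: unweighted,
        precision proportional to the rate (Poisson counts with a stable
        denominator), or proportional to supplied death counts.
    confidence : float
        Two-sided confidence level for APC/AAPC intervals.
    zero_rate : {"error", "substitute"}
        Zero rates either raise, or are replaced by half the smallest
        positive rate in the series (a continuity substitution).
    ci_method : {"parametric", "bootstrap"}
        ``parametric`` builds t-based intervals from the fit covariance,
        conditional on the selected joinpoints; these are known to
        undercover when the breakpoint location is itself estimated.
        ``bootstrap`` is an empirical-quantile interval: data are
        resampled parametrically around the fitted path, the joinpoint
        placement is re-searched (at the selected number of joinpoints)
        on each resample, and APC/AAPC intervals are percentile
        intervals of the resampled estimates.
    n_boot : int
        Bootstrap replicates for ``ci_method="bootstrap"``.
    random_state : int or None
        Seed for the bootstrap resampling.

    Attributes
    ----------
    joinpoint_years_ : list of joinpoint years of the selected model.
    segments_ : list of fitted :class:`Segment`.
    aapc_, aapc_ci_ : average annual percent change and its interval
        over the full observation window.
    bic_, sse_, df_resid_ : selection score and fit summaries.
    coef_ : regression coefficients (intercept, base slope, slope changes).
    """

    def __init__(self, max_joinpoints: Optional[int] = None,
                 min_obs_per_segment: int = 4, weighting: str = "none",
                 confidence: float = 0.95, zero_rate: str = "error",
                 ci_method: str = "parametric", n_boot: int = 500,
                 random_state: Optional[int] = None):
        self.max_joinpoints = max_joinpoints
        self.min_obs_per_segment = min_obs_per_segment
        self.weighting = weighting
        self.confidence = confidence
        self.zero_rate = zero_rate
        self.ci_method = ci_method
        self.n_boot = n_boot
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y, sample_weight=None):
        """Fit the model.

        ``X`` is the years (1-D or a single column), ``y`` the positive
        rates.  ``sample_weight`` overrides the ``weighting`` policy;
        with ``weighting="count"`` it must hold the death counts.
        """
        t_years = np.asarray(X, dtype=float).reshape(-1)
        r = np.asarray(y, dtype=float).reshape(-1)
        if t_years.shape != r.shape:
            raise ValueError("X and y must have the same length")
        n = len(r)
        if n < 3:
            raise ValueError("need at least three observations")
        if np.any(np.diff(t_years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("rates must be non-negative")
        if np.any(r == 0):
            if self.zero_rate == "substitute":
                positive = r[r > 0]
                if not len(positive):
                    raise ValueError("all rates are zero; nothing to fit")
                r = np.where(r == 0, positive.min() / 2.0, r)
            else:
                raise ValueError("zero rates are undefined on the log scale; "
                                 "set zero_rate='substitute' to proceed")

        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=float).reshape(-1)
        elif self.weighting == "rate":
            w = r.copy()
        elif self.weighting == "count":
            raise ValueError("weighting='count' requires sample_weight=counts")
        elif self.weighting == "none":
            w = np.ones(n)
        else:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        w = w / w.mean()  # scale-free: only relative precision matters

        m = self.min_obs_per_segment
        k_feasible = (n - 1) // m - 1
        if self.max_joinpoints is None:
            k_max = 3 if n >= 20 else max(k_feasible, 0)
        else:
            k_max = self.max_joinpoints
        k_max = max(0, min(k_max, k_feasible))

        t = t_years - t_years[0]  # centre time at the first year
        y_log = np.log(r)
        sw = np.sqrt(w)

        best = None  # (bic, k, placement, beta, sse)
        for k in range(k_max + 1):
            for combo in admissible_placements(n, k, m):
                taus = t[list(combo)]
                Xd = _hinge_design(t, taus)
                beta, *_ = np.linalg.lstsq(Xd * sw[:, None], y_log * sw, rcond=None)
                sse = float(w @ (y_log - Xd @ beta) ** 2)
                # a residual RMS below 1e-8 on the log scale is numerically a
                # perfect fit; flooring the SSE lets such fits tie instead of
                # competing on rounding noise, and the tie-break then prefers
                # the simpler model
                bic = n * np.log(max(sse, n * 1e-16) / n) + (2 * k + 2) * np.log(n)
                cand = (bic, k, combo, beta, sse)
                if best is None or bic < best[0] - 1e-12:
                    best = cand
                elif abs(bic - best[0]) <= 1e-12 and (k, combo) < (best[1], best[2]):
                    best = cand  # tie: fewer joinpoints, then earliest placement

        bic, k, combo, beta, sse = best
        self.n_obs_ = n
        self.years_ = t_years.astype(int) if np.allclose(t_years % 1, 0) else t_years
        self.rates_ = r
        self.weights_ = w
        self.t0_ = t_years[0]
        self.n_joinpoints_ = k
        self.joinpoint_indices_ = list(combo)
        self.joinpoint_years_ = [self.years_[i] for i in combo]
        self.coef_ = beta
        self.sse_ = sse
        self.bic_ = float(bic)
        self.df_resid_ = n - (2 * k + 2)
        self._finalize_inference(t, y_log, w, combo, beta)
        if self.ci_method == "bootstrap":
            self._bootstrap_inference(t, w)
        elif self.ci_method != "parametric":
            raise ValueError(f"unknown ci_method {self.ci_method!r}")
        return self

    def _finalize_inference(self, t, y_log, w, combo, beta):
        n = len(t)
        k = len(combo)
        taus = t[list(combo)]
        Xd = _hinge_design(t, taus)
        df = self.df_resid_
        if df > 0:
            s2 = self.sse_ / df
            cov_beta = s2 * np.linalg.inv((Xd * w[:, None]).T @ Xd)
        else:
            cov_beta = np.full((2 + k, 2 + k), np.nan)
        # segment slopes are cumulative sums of (b1, d1, .., dk)
        L = np.zeros((k + 1, 2 + k))
        for i in range(k + 1):
            L[i, 1] = 1.0
            L[i, 2:2 + i] = 1.0
        slopes = L @ beta
        cov_slopes = L @ cov_beta @ L.T
        alpha = 1 - self.confidence
        tcrit = stats.t.ppf(1 - alpha / 2, df) if df > 0 else np.nan

        bounds = [0] + list(combo) + [n - 1]
        segments = []
        for i in range(k + 1):
            b = float(slopes[i])
            se = float(np.sqrt(cov_slopes[i, i])) if df > 0 else np.nan
            apc = 100 * (np.exp(b) - 1)
            if df > 0 and se > 0:
                lo = 100 * (np.exp(b - tcrit * se) - 1)
                hi = 100 * (np.exp(b + tcrit * se) - 1)
                p = float(2 * stats.t.sf(abs(b / se), df))
            else:
                lo = hi = apc
                p = 0.0 if b != 0 else 1.0
            segments.append(Segment(
                start_year=int(self.years_[bounds[i]]),
                end_year=int(self.years_[bounds[i + 1]]),
                slope=b, slope_se=se, apc=apc, ci_low=lo, ci_high=hi, p_value=p))
        self.segments_ = segments
        self._slopes = slopes
        self._cov_slopes = cov_slopes
        self._bounds = bounds
        self._boot_slopes = None
        self._boot_bounds = None
        self.aapc_, self.aapc_ci_ = self.aapc()

    def _bootstrap_inference(self, t, w):
        """Empirical-quantile intervals re-searching the joinpoint placement.

        Resamples log rates parametrically around the fitted path with
        the estimated (weighted) residual variance, refits every
        admissible placement at the selected number of joinpoints, and
        replaces the APC/AAPC intervals by percentile intervals of the
        resampled estimates.  Point estimates and p-values keep the
        original fit.
        """
        n, k = self.n_obs_, self.n_joinpoints_
        if self.df_resid_ <= 0:
            return  # no residual scale to resample from
        rng = np.random.default_rng(self.random_state)
        combos = admissible_placements(n, k, self.min_obs_per_segment)
        sw = np.sqrt(w)
        designs = [_hinge_design(t, t[list(c)]) for c in combos]
        s2 = self.sse_ / self.df_resid_
        B = self.n_boot
        yhat = designs[combos.index(tuple(self.joinpoint_indices_))] @ self.coef_
        Y = yhat[:, None] + rng.normal(size=(n, B)) * np.sqrt(s2 / w)[:, None]
        Yw = Y * sw[:, None]

        best_sse = np.full(B, np.inf)
        best_at = np.zeros(B, dtype=int)
        all_beta = np.empty((len(combos), 2 + k, B))
        for i, X in enumerate(designs):
            Xw = X * sw[:, None]
            beta = np.linalg.pinv(Xw) @ Yw
            sse = ((Yw - Xw @ beta) ** 2).sum(axis=0)
            all_beta[i] = beta
            better = sse < best_sse
            best_at[better] = i
            best_sse[better] = sse[better]

        beta_sel = all_beta[best_at, :, np.arange(B)]       # (B, p)
        L = np.zeros((k + 1, 2 + k))
        for i in range(k + 1):
            L[i, 1] = 1.0
            L[i, 2:2 + i] = 1.0
        slopes = beta_sel @ L.T                              # (B, k+1)
        seg_bounds = np.empty((B, k + 2))
        for b in range(B):
            seg_bounds[b] = [0, *combos[best_at[b]], n - 1]

        alpha = 1 - self.confidence
        q = (alpha / 2, 1 - alpha / 2)
        new_segments = []
        for i, seg in enumerate(self.segments_):
            lo, hi = np.quantile(100 * (np.exp(slopes[:, i]) - 1), q)
            new_segments.append(Segment(seg.start_year, seg.end_year, seg.slope,
                                        seg.slope_se, seg.apc, float(lo), float(hi),
                                        seg.p_value))
        self.segments_ = new_segments
        self._boot_slopes = slopes
        self._boot_bounds = seg_bounds
        self.aapc_, self.aapc_ci_ = self.aapc()

    # -- summaries -------------------------------------------------------

    def aapc(self, start_year: Optional[int] = None, end_year: Optional[int] = None):
        """Average annual percent change over ``[start_year, end_year]``.

        The AAPC is ``100*(exp(sum_i w_i b_i) - 1)`` with weights the
        fraction of the period's year intervals each segment spans; its
        interval comes from the delta method on the weighted slope using
        the fitted slope covariance.
        """
        check_is_fitted(self, "segments_")
        years = self.years_
        start = years[0] if start_year is None else start_year
        end = years[-1] if end_year is None else end_year
        if start < years[0] or end > years[-1] or start >= end:
            raise ValueError(f"period {start}-{end} outside fitted window "
                             f"{years[0]}-{years[-1]}")
        weights = np.zeros(len(self.segments_))
        for i, seg in enumerate(self.segments_):
            overlap = min(end, seg.end_year) - max(start, seg.start_year)
            weights[i] = max(overlap, 0)
        weights = weights / weights.sum()
        wb = float(weights @ self._slopes)
        aapc = 100 * (np.exp(wb) - 1)
        if getattr(self, "_boot_slopes", None) is not None:
            # each resample weights its own re-searched segment layout
            by = self.years_[self._boot_bounds.astype(int)]
            span = (np.minimum(end, by[:, 1:]) - np.maximum(start, by[:, :-1])).clip(min=0)
            wboot = (span * self._boot_slopes).sum(axis=1) / span.sum(axis=1)
            alpha = 1 - self.confidence
            lo, hi = np.quantile(100 * (np.exp(wboot) - 1), (alpha / 2, 1 - alpha / 2))
            return aapc, (float(lo), float(hi))
        var = float(weights @ self._cov_slopes @ weights)
        df = self.df_resid_
        if df > 0 and var > 0:
            tcrit = stats.t.ppf(1 - (1 - self.confidence) / 2, df)
            half = tcrit * np.sqrt(var)
            ci = (100 * (np.exp(wb - half) - 1), 100 * (np.exp(wb + half) - 1))
        else:
            ci = (aapc, aapc)
        return aapc, ci

    @property
    def aapc_label_(self) -> str:
        return label_trend(*self.aapc_ci_)

    def predict(self, X):
        """Fitted rates at the given years (exp of the fitted log path)."""
        check_is_fitted(self, "coef_")
        t = np.asarray(X, dtype=float).reshape(-1) - self.t0_
        taus = (np.asarray(self.joinpoint_years_, dtype=float) - self.t0_
                if self.n_joinpoints_ else [])
        return np.exp(_hinge_design(t, taus) @ self.coef_)

    def predict_log(self, X):
        check_is_fitted(self, "coef_")
        t = np.asarray(X, dtype=float).reshape(-1) - self.t0_
        taus = (np.asarray(self.joinpoint_years_, dtype=float) - self.t0_
                if self.n_joinpoints_ else [])
        return _hinge_design(t, taus) @ self.coef_

    def summary_rows(self, stratum: str) -> list[dict]:
        """Per-segment rows for the trend table writer."""
        check_is_fitted(self, "segments_")
        rows = []
        for seg in self.segments_:
            rows.append({
                "stratum": stratum,
                "segment_start": seg.start_year, "segment_end": seg.end_year,
                "apc": seg.apc, "apc_ci_low": seg.ci_low, "apc_ci_high": seg.ci_high,
                "p_value": seg.p_value, "significance": seg.significance,
                "trend": seg.label,
                "aapc": self.aapc_, "aapc_ci_low": self.aapc_ci_[0],
                "aapc_ci_high": self.aapc_ci_[1], "overall_trend": self.aapc_label_,
            })
        return rows


def fit_joinpoint(series: RateSeries, max_joinpoints: Optional[int] = None,
                  min_obs_per_segment: int = 4, weighting: str = "none",
                  confidence: float = 0.95, zero_rate: str = "error") -> JoinpointRegression:
    """Fit a :class:`JoinpointRegression` to a :class:`RateSeries`."""
    model = JoinpointRegression(max_joinpoints=max_joinpoints,
                                min_obs_per_segment=min_obs_per_segment,
                                weighting=weighting, confidence=confidence,
                                zero_rate=zero_rate)
    sw = None
    if weighting == "count" and series.counts is not None:
        sw = series.counts
    return model.fit(series.years, series.rates, sample_weight=sw)
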