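"""Scale-invariant variability measures for per-beat series.

Three complementary descriptors are used on beat-to-beat interval and
contraction-strength series:

* sample entropy (SampEn): the negative log of the conditional
  probability that runs similar for m points stay similar for m+1,
  with Chebyshev distance, tolerance r = 0.15 * SD, self-matches excluded;
* Higuchi fractal dimension (D_H): minus the slope of the mean curve
  length L(k) versus the delay k on log-log axes, ~1 for smooth lines and
  ~2 for white noise;
* the DFA scaling exponent alpha: slope of the detrended fluctuation
  function on log-log axes, 0.5 for white noise and 1.5 for Brownian noise.

All three share an ordinary least-squares log-log fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "NonlinearResult",
    "HiguchiCurve",
    "sample_entropy",
    "higuchi_dimension",
    "dfa_alpha",
    "fit_loglog",
    "analyze_series",
]


@dataclass
class HiguchiCurve:
    """Mean curve lengths L(k) and per-offset lengths L_m(k) for k = 1..k_max."""

    k: np.ndarray
    lk: np.ndarray
    lmk: list  # lmk[j] holds the k[j] per-offset lengths

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=int)
        self.lk = np.asarray(self.lk, dtype=float)
        if np.any(self.lk <= 0):
            raise ValueError("curve lengths must be positive")


@dataclass
class NonlinearResult:
    """SampEn, Higuchi dimension (with fit r^2) and DFA alpha for one series."""

    sampen: float
    d_h: float
    d_h_r2: float
    dfa_alpha: float
    params: dict = field(default_factory=dict)

    @property
    def sampen_defined(self) -> bool:
        return np.isfinite(self.sampen)


def sample_entropy(
    x: np.ndarray, m: int = 2, r_factor: float = 0.15, r: Optional[float] = None
) -> float:
    """Sample entropy of a series.

    Template vectors X_m(i) = [x(i), ..., x(i+m-1)] are compared with the
    Chebyshev (maximum) metric; a pair matches when its distance is <= r,
    with r = ``r_factor`` times the population SD of the full series unless
    an absolute ``r`` is given.  Self-matches are excluded.  Per-template
    match counts are normalised by the number of templates and averaged
    over all but the last template:

        B^m = (1 / (N - m)) * sum_{i=1}^{N-m} C_i^m,
        C_i^m = #{j != i : d[X_m(i), X_m(j)] <= r} / (N - m + 1),

    and SampEn = -ln(B^{m+1} / B^m).  When no (m+1)-matches exist the value
    is +inf (flagged undefined by :class:`NonlinearResult`), not an error,
    so batch tables stay aligned.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"series of length {n} too short for m={m}")
    sd = float(np.std(x))
    if r is None:
        if sd == 0.0:
            raise ValueError("degenerate series: zero standard deviation")
        r = r_factor * sd

    def _b(mm: int) -> float:
        n_templates = n - mm + 1
        # (n_templates, mm) strided template matrix
        tmpl = np.lib.stride_tricks.sliding_window_view(x, mm)
        # Chebyshev distances, built dimension-wise to keep memory modest
        match = np.ones((n_templates, n_templates), dtype=bool)
        for d in range(mm):
            col = tmpl[:, d]
            match &= np.abs(col[:, None] - col[None, :]) <= r
        np.fill_diagonal(match, False)
        counts = match.sum(axis=1) / n_templates
        return float(counts[: n - mm].sum() / (n - mm))

    bm = _b(m)
    bm1 = _b(m + 1)
    if bm == 0.0 or bm1 == 0.0:
        return float("inf")
    return float(-np.log(bm1 / bm))


def higuchi_curve(x: np.ndarray, k_max: int = 30) -> HiguchiCurve:
    """Curve lengths L_m(k) and their means L(k) for k = 1..k_max.

    For delay k and initial offset m (1..k) the subsampled series
    x(m), x(m+k), ... has length

        L_m(k) = (1/k) * [ sum |x(m+ik) - x(m+(i-1)k)| ] * (N-1) / (floor((N-m)/k) * k),

    where the last factor renormalises for the number of usable increments.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= 2 * k_max:
        raise ValueError(f"series of length {n} too short for k_max={k_max}")
    ks = np.arange(1, k_max + 1)
    lk = np.empty(ks.size)
    lmk_all: list[np.ndarray] = []
    for j, k in enumerate(ks):
        lmk = np.empty(k)
        for m in range(1, k + 1):
            sub = x[m - 1 :: k]
            n_inc = (n - m) // k
            inc = np.abs(np.diff(sub[: n_inc + 1]))
            norm = (n - 1) / (n_inc * k)
            lmk[m - 1] = inc.sum() * norm / k
        lmk_all.append(lmk)
        lk[j] = lmk.mean()
    return HiguchiCurve(ks, lk, lmk_all)


def higuchi_dimension(
    x: np.ndarray, k_max: int = 30
) -> tuple[float, HiguchiCurve, float]:
    """Higuchi fractal dimension: D_H = -slope of ln L(k) vs ln k, k = 1..k_max.

    Returns ``(d_h, curve, r2)`` where ``r2`` is the coefficient of
    determination of the log-log fit (a linearity diagnostic; the
    experimental series here give r2 well above 0.95).
    """
    curve = higuchi_curve(x, k_max=k_max)
    slope, _, r2 = fit_loglog(curve.k, curve.lk)
    return -slope, curve, r2


def dfa_alpha(
    x: np.ndarray,
    min_window: int = 4,
    max_window: int = 30,
    order: int = 1,
) -> float:
    """Detrended fluctuation analysis scaling exponent.

    The mean-removed series is integrated into a profile, the profile is
    split into non-overlapping windows of every integer size in
    [min_window, max_window] (all integers: the range is small), each
    window is detrended with a polynomial of the given order, and alpha is
    the slope of ln F(n) vs ln n where F(n) is the RMS residual pooled over
    all windows of size n.
    """
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0.0:
        raise ValueError("degenerate series: constant input")
    if x.size < 4 * max_window:
        raise ValueError(
            f"series of length {x.size} too short for max_window={max_window}"
        )
    profile = np.cumsum(x - x.mean())
    ns = np.arange(min_window, max_window + 1)
    fn = np.empty(ns.size)
    for j, n in enumerate(ns):
        n_seg = profile.size // n
        segs = profile[: n_seg * n].reshape(n_seg, n)
        t = np.arange(n, dtype=float)
        # least-squares polynomial detrend of all segments at once
        design = np.vander(t, order + 1)
        coef, *_ = np.linalg.lstsq(design, segs.T, rcond=None)
        resid = segs.T - design @ coef
        fn[j] = np.sqrt(np.mean(resid**2))
    slope, _, _ = fit_loglog(ns, fn)
    return slope


def fit_loglog(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float, float]:
    """OLS fit of ln(ys) on ln(xs); returns (slope, intercept, r2)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 3 or ys.size != xs.size:
        raise ValueError("need at least 3 aligned points")
    if np.any(xs <= 0) or np.any(ys <= 0):
        raise ValueError("log-log fit needs strictly positive inputs")
    lx, ly = np.log(xs), np.log(ys)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def analyze_series(
    x: np.ndarray,
    m: int = 2,
    r_factor: float = 0.15,
    k_max: int = 30,
    dfa_min_window: int = 4,
    dfa_max_window: int = 30,
) -> NonlinearResult:
    """All three nonlinear measures for one per-beat series.

    ``k_max`` and the DFA window cap shrink automatically for short series
    (kept at most len/2 - 1 and len/4) so batch runs do not abort; the
    values actually used are recorded in ``params``.
    """
    x = np.asarray(x, dtype=float)
    k_eff = min(k_max, max(2, (x.size - 1) // 2))
    dfa_max_eff = min(dfa_max_window, max(dfa_min_window + 2, x.size // 4))
    sampen = sample_entropy(x, m=m, r_factor=r_factor)
    d_h, _, r2 = higuchi_dimension(x, k_max=k_eff)
    alpha = dfa_alpha(x, min_window=dfa_min_window, max_window=dfa_max_eff)
    return NonlinearResult(
        sampen=sampen,
        d_h=d_h,
        d_h_r2=r2,
        dfa_alpha=alpha,
        params={
            "m": m,
            "r_factor": r_factor,
            "k_max": k_eff,
            "dfa_windows": (dfa_min_window, dfa_max_eff),
        },
    )
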