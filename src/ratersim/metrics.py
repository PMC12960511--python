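"""Agreement metrics for paired ordinal ratings.

Five summaries of human--AI agreement on a finite ordered rating scale
(default rubric categories 0..4):

* ``icc_a1`` -- intraclass correlation for absolute agreement of single
  measurements, ICC(A,1), treating each examinee as a target rated by
  k = 2 raters.
* ``kripp_alpha`` -- Krippendorff's alpha with a pluggable squared
  distance over categories (squared category-index difference by
  default, the cumulative-frequency ordinal metric as an option).
* ``qwk`` -- quadratic weighted kappa over the full category set.
* ``bland_altman`` -- mean difference, SD of differences and the 95%
  limits of agreement.
* ``tolerance_agreement`` -- proportion of pairs within k rubric points.

Degenerate inputs (zero variance where a coefficient's denominator
vanishes) return ``nan`` rather than raising, so that a batch of Monte
Carlo replications never aborts; callers count and exclude these.

Also houses the Wilson score interval used to wrap Monte Carlo
exceedance proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

DEFAULT_CATEGORIES: tuple[int, ...] = (0, 1, 2, 3, 4)

__all__ = [
    "DEFAULT_CATEGORIES",
    "RatingPair",
    "MetricSet",
    "WilsonInterval",
    "icc_a1",
    "kripp_alpha",
    "qwk",
    "bland_altman",
    "tolerance_agreement",
    "wilson_interval",
    "metric_set",
]


@dataclass(frozen=True)
class RatingPair:
    """A paired sample of integer ratings on a common ordered scale.

    Parameters
    ----------
    h, a
        Equal-length vectors of integer categories, one entry per
        examinee (conventionally the human and the AI rating).
    categories
        The full ordered category set; ratings must be members.
        Agreement coefficients that involve chance-expected terms are
        computed over this full set even when some categories are
        unobserved.
    """

    h: NDArray[np.int64]
    a: NDArray[np.int64]
    categories: tuple[int, ...] = DEFAULT_CATEGORIES

    def __init__(self, h: ArrayLike, a: ArrayLike,
                 categories: tuple[int, ...] = DEFAULT_CATEGORIES) -> None:
        h_arr = np.asarray(h, dtype=np.int64)
        a_arr = np.asarray(a, dtype=np.int64)
        if h_arr.ndim != 1 or a_arr.ndim != 1:
            raise ValueError("ratings must be one-dimensional vectors")
        if h_arr.shape != a_arr.shape:
            raise ValueError(
                f"rating vectors differ in length: {h_arr.size} vs {a_arr.size}")
        if h_arr.size < 2:
            raise ValueError("need at least two rated units")
        cats = tuple(int(c) for c in categories)
        if sorted(set(cats)) != list(cats):
            raise ValueError("categories must be strictly increasing and unique")
        allowed = np.asarray(cats)
        for name, v in (("h", h_arr), ("a", a_arr)):
            if not np.isin(v, allowed).all():
                bad = np.unique(v[~np.isin(v, allowed)])
                raise ValueError(f"{name} contains values outside the category "
                                 f"set {cats}: {bad.tolist()}")
        object.__setattr__(self, "h", h_arr)
        object.__setattr__(self, "a", a_arr)
        object.__setattr__(self, "categories", cats)

    def __len__(self) -> int:
        return int(self.h.size)

    def swapped(self) -> "RatingPair":
        return RatingPair(self.a, self.h, self.categories)

    def _index_pair(self) -> tuple[NDArray[np.int64], NDArray[np.int64], int]:
        """Ratings mapped to 0-based category indices plus the set size."""
        cats = np.asarray(self.categories)
        hi = np.searchsorted(cats, self.h)
        ai = np.searchsorted(cats, self.a)
        return hi, ai, cats.size


@dataclass(frozen=True)
class MetricSet:
    """The five agreement summaries for one rating pair.

    ``icc_a1``, ``kripp_alpha`` and ``qwk`` are ``nan`` when undefined
    (degenerate zero-variance samples).  ``loa_lower``/``loa_upper`` are
    always ``ba_bias ± 1.96·ba_sd``; ``tol1``/``tol2`` are the within-1
    and within-2 tolerance proportions.
    """

    icc_a1: float
    kripp_alpha: float
    qwk: float
    ba_bias: float
    ba_sd: float
    loa_lower: float
    loa_upper: float
    tol1: float
    tol2: float

    def as_dict(self) -> dict[str, float]:
        return {
            "icc_a1": self.icc_a1,
            "kripp_alpha": self.kripp_alpha,
            "qwk": self.qwk,
            "ba_bias": self.ba_bias,
            "ba_sd": self.ba_sd,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "tol1": self.tol1,
            "tol2": self.tol2,
        }


@dataclass(frozen=True)
class WilsonInterval:
    """Wilson score interval for a binomial proportion.

    The point estimate is recentred, ``(p̂ + z²/2n) / (1 + z²/n)``, and
    the interval is the symmetric half-width around it, clipped to
    [0, 1].  With ``z = 0`` it degenerates to ``(p̂, 0)``.
    """

    point: float
    half_width: float
    lower: float
    upper: float
    z: float = 1.96
    n: int = field(default=1)

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError("Wilson bounds must satisfy 0 <= lower <= upper <= 1")


def _contingency(pair: RatingPair) -> NDArray[np.float64]:
    """K x K joint count table over the full category set (rows = h)."""
    hi, ai, k = pair._index_pair()
    return np.bincount(hi * k + ai, minlength=k * k).reshape(k, k).astype(float)


def icc_a1(pair: RatingPair, form: str = "twoway") -> float:
    """Intraclass correlation for absolute agreement, single rating.

    Each examinee is a target rated by k = 2 raters (h_i, a_i).  The
    default ``form="twoway"`` is the McGraw--Wong ICC(A,1) from the
    two-way layout (target and rater effects),

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1)·MSE + (k/n)·(MSC - MSE)),

    which charges both random disagreement and a systematic level
    difference between the two rating sources against agreement.
    ``form="oneway"`` collapses the rater effect into the residual and
    returns ``(MSB - MSW)/(MSB + (k-1)·MSW)``; the two coincide when the
    rating sources share a mean.

    Returns ``nan`` when the denominator vanishes (all ratings one
    constant), never raises on degenerate data.
    """
    if form not in ("twoway", "oneway"):
        raise ValueError(f"unknown ICC form {form!r}")
    n = len(pair)
    k = 2
    x = np.stack([pair.h, pair.a], axis=1).astype(float)
    row_m = x.mean(axis=1)
    grand = x.mean()
    if form == "oneway":
        msb = k * np.sum((row_m - grand) ** 2) / (n - 1)
        msw = np.sum((x - row_m[:, None]) ** 2) / (n * (k - 1))
        denom = msb + (k - 1) * msw
        if denom == 0.0:
            return math.nan
        return float((msb - msw) / denom)
    col_m = x.mean(axis=0)
    msr = k * np.sum((row_m - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_m - grand) ** 2) / (k - 1)
    resid = x - row_m[:, None] - col_m[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        return math.nan
    return float((msr - mse) / denom)


def _alpha_distance(counts_by_cat: NDArray[np.float64], k: int,
                    distance: str) -> NDArray[np.float64]:
    """Squared-distance matrix delta²(c, k) for Krippendorff's alpha."""
    idx = np.arange(k, dtype=float)
    if distance == "squared_category":
        return (idx[:, None] - idx[None, :]) ** 2
    if distance == "ordinal_cumulative":
        # delta²(c,k) = (sum of pooled marginal counts n_g for g between
        # c and k inclusive, minus (n_c + n_k)/2)², the classic ordinal
        # metric on cumulative frequencies.
        csum = np.concatenate([[0.0], np.cumsum(counts_by_cat)])
        lo = np.minimum.outer(np.arange(k), np.arange(k))
        hi = np.maximum.outer(np.arange(k), np.arange(k))
        between = csum[hi + 1] - csum[lo]
        ends = (counts_by_cat[:, None] + counts_by_cat[None, :]) / 2.0
        return (between - ends) ** 2
    raise ValueError(f"unknown alpha distance {distance!r}")


def kripp_alpha(pair: RatingPair, distance: str = "squared_category") -> float:
    """Krippendorff's alpha for two complete ratings per unit.

    alpha = 1 - D_o / D_e with the coincidence-matrix construction:
    each unit contributes both ordered value pairs, observed
    disagreement averages delta² over coincidences, and expected
    disagreement draws pairs without replacement from the pooled
    marginals.  ``distance`` selects delta²: squared category-index
    difference (default) or the cumulative-frequency ordinal metric.

    Returns ``nan`` when all pooled ratings are one category (D_e = 0).
    """
    cont = _contingency(pair)
    k = cont.shape[0]
    o = cont + cont.T                       # coincidence matrix
    n_c = o.sum(axis=1)                     # pooled marginals, sum = 2n
    n_tot = n_c.sum()
    d2 = _alpha_distance(n_c, k, distance)
    d_obs = float((o * d2).sum()) / n_tot
    d_exp = float((np.outer(n_c, n_c) * d2).sum()) / (n_tot * (n_tot - 1.0))
    if d_exp == 0.0:
        return math.nan
    return float(1.0 - d_obs / d_exp)


def qwk(pair: RatingPair) -> float:
    """Quadratic weighted kappa over the full category set.

    kappa_w = 1 - sum(w·O) / sum(w·E) with w_ij = (i - j)² on category
    indices, O the observed joint proportions and E the outer product
    of the two marginal proportion vectors.  Marginals span the full
    declared category set, so E stays well-defined under imbalanced
    samples with unobserved categories.  ``nan`` when sum(w·E) = 0.
    """
    cont = _contingency(pair)
    n = cont.sum()
    obs = cont / n
    k = cont.shape[0]
    idx = np.arange(k, dtype=float)
    w = (idx[:, None] - idx[None, :]) ** 2
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    denom = float((w * exp).sum())
    if denom == 0.0:
        return math.nan
    return float(1.0 - (w * obs).sum() / denom)


def bland_altman(pair: RatingPair) -> tuple[float, float, float, float]:
    """Mean difference, SD of differences and the 95% limits of agreement.

    Differences are d_i = h_i - a_i; the SD uses the n-1 denominator and
    the limits are exactly ``d̄ ± 1.96·s_d``.  Constant differences give
    s_d = 0 and limits collapsing onto the bias.
    """
    d = pair.h.astype(float) - pair.a.astype(float)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def tolerance_agreement(pair: RatingPair, k: int = 1) -> float:
    """Proportion of pairs with |h_i - a_i| <= k rubric points."""
    if k < 0:
        raise ValueError("tolerance width k must be non-negative")
    return float((np.abs(pair.h - pair.a) <= k).mean())


def wilson_interval(successes: int, n: int, z: float = 1.96) -> WilsonInterval:
    """Wilson score interval for ``successes`` out of ``n`` trials.

    Uses the recentred point estimate and symmetric half-width

        p̂_W = (p̂ + z²/2n) / (1 + z²/n)
        SE_W = z·sqrt(p̂(1-p̂)/n + z²/4n²) / (1 + z²/n)

    with bounds clipped to [0, 1].  Raises on an empty cell (n = 0).
    """
    if n < 1:
        raise ValueError("Wilson interval requires n >= 1 (empty cell)")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    p_hat = successes / n
    shrink = 1.0 + z * z / n
    point = (p_hat + z * z / (2.0 * n)) / shrink
    half = z * math.sqrt(p_hat * (1.0 - p_hat) / n + z * z / (4.0 * n * n)) / shrink
    # at p̂ = 0 (or 1) the interval touches the boundary exactly
    lower = 0.0 if successes == 0 else max(0.0, point - half)
    upper = 1.0 if successes == n else min(1.0, point + half)
    return WilsonInterval(
        point=point,
        half_width=half,
        lower=lower,
        upper=upper,
        z=z,
        n=n,
    )


def metric_set(pair: RatingPair, alpha_distance: str = "squared_category",
               icc_form: str = "twoway") -> MetricSet:
    """All five agreement summaries for one rating pair."""
    bias, sd, lo, hi = bland_altman(pair)
    return MetricSet(
        icc_a1=icc_a1(pair, form=icc_form),
        kripp_alpha=kripp_alpha(pair, distance=alpha_distance),
        qwk=qwk(pair),
        ba_bias=bias,
        ba_sd=sd,
        loa_lower=lo,
        loa_upper=hi,
        tol1=tolerance_agreement(pair, 1),
        tol2=tolerance_agreement(pair, 2),
    )
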