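"""Synthetic human/AI score generation under controlled distortions.

One Monte Carlo replication draws a latent ability vector theta ~ N(0,1),
two independent human ratings H = theta + eps_H (the second human exists
only to anchor the human--human QWK gap rule), and an AI rating
A* = theta + b + eps_A.  Before discretization the AI scores optionally
pass through three distortion mechanisms, applied in this fixed order:

1. midpoint compression  A <- (1 - lambda_c)·A
2. class imbalance       lower 40% of the empirical distribution shifted
   down, upper 10% shifted up
3. fairness offset       A <- A + delta·G for a random half of examinees

All three continuous score vectors are then cut into rubric categories
0..4 with fixed cut-points on the latent continuum; the imbalance flag
switches the cut-point set (for humans and AI alike, so human--human
agreement stays a clean baseline).  Values exactly on a cut-point fall
in the lower category.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

N_LEVELS: tuple[int, ...] = (100, 300, 1000)
BIAS_LEVELS: tuple[float, ...] = (-0.5, 0.0, 0.5)
VAR_LEVELS: tuple[str, ...] = ("low", "mid", "high")

__all__ = [
    "N_LEVELS", "BIAS_LEVELS", "VAR_LEVELS",
    "Condition", "DistortionParams", "Replicate",
    "draw_latent", "gen_human", "gen_ai",
    "apply_compression", "apply_imbalance", "apply_fairness",
    "discretize", "make_replicate",
]


@dataclass(frozen=True)
class Condition:
    """One cell of the factorial design.

    ``n`` examinees, additive AI bias ``b``, AI error-variance level
    (low/mid/high mapping to sigma_A), and three boolean distortion
    flags.  ``strict`` relaxes the level checks so off-grid conditions
    can be explored.
    """

    n: int
    bias: float
    ai_var_level: str
    compression: bool = False
    imbalance: bool = False
    fairness: bool = False
    strict: bool = True

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("condition needs n >= 2 examinees")
        if self.ai_var_level not in VAR_LEVELS:
            raise ValueError(
                f"unknown AI variance level {self.ai_var_level!r}; "
                f"expected one of {VAR_LEVELS}")
        if self.strict:
            if self.n not in N_LEVELS:
                raise ValueError(f"n={self.n} not in design levels {N_LEVELS}; "
                                 "pass strict=False to override the grid")
            if self.bias not in BIAS_LEVELS:
                raise ValueError(f"bias={self.bias} not in design levels "
                                 f"{BIAS_LEVELS}; pass strict=False to override")

    @property
    def label(self) -> str:
        flags = "".join(
            ch if on else "-"
            for ch, on in zip("cif", (self.compression, self.imbalance,
                                      self.fairness)))
        return f"n{self.n}_b{self.bias:+.1f}_{self.ai_var_level}_{flags}"

    @property
    def is_strict_null(self) -> bool:
        """Zero bias, variance matched to humans, no distortion flags."""
        return (self.bias == 0.0 and self.ai_var_level == "mid"
                and not (self.compression or self.imbalance or self.fairness))


@dataclass(frozen=True)
class DistortionParams:
    """Numeric constants of the data-generating process.

    sigma_h is the human rater error SD; the "mid" AI level equals it by
    construction, so the strict null makes the AI exchangeable with a
    second human rater.  lambda_c is the compression intensity, delta
    the fairness offset, and the cut-point tuples map the latent
    continuum onto rubric categories 0..4 (the imbalanced set spreads
    the cut-points so category frequencies skew).  Imbalance shifts move
    scores below the 0.40 and above the 0.90 empirical quantiles.
    """

    sigma_h: float = 0.50
    sigma_a_map: dict[str, float] = field(
        default_factory=lambda: {"low": 0.40, "mid": 0.50, "high": 0.95})
    lambda_c: float = 0.40
    delta: float = 0.30
    cutpoints_balanced: tuple[float, ...] = (-0.8, -0.2, 0.2, 0.8)
    cutpoints_imbalanced: tuple[float, ...] = (-1.2, -0.4, 0.4, 1.2)
    imb_low_q: float = 0.40
    imb_high_q: float = 0.90
    imb_low_shift: float = -0.30
    imb_high_shift: float = 0.30
    group_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_h <= 0:
            raise ValueError("sigma_h must be positive")
        if any(s <= 0 for s in self.sigma_a_map.values()):
            raise ValueError("all sigma_a values must be positive")
        if not 0.0 <= self.lambda_c < 1.0:
            raise ValueError("lambda_c must lie in [0, 1)")
        for cuts in (self.cutpoints_balanced, self.cutpoints_imbalanced):
            if list(cuts) != sorted(set(cuts)):
                raise ValueError(f"cut-points must be strictly increasing: {cuts}")
        if not (0.0 < self.imb_low_q < self.imb_high_q < 1.0):
            raise ValueError("imbalance quantiles must satisfy 0 < low < high < 1")
        if not 0.0 <= self.group_prob <= 1.0:
            raise ValueError("group_prob must lie in [0, 1]")

    def sigma_a(self, level: str) -> float:
        try:
            return self.sigma_a_map[level]
        except KeyError:
            raise ValueError(f"unknown AI variance level {level!r}") from None

    def cutpoints(self, imbalance: bool) -> np.ndarray:
        cuts = self.cutpoints_imbalanced if imbalance else self.cutpoints_balanced
        return np.asarray(cuts, dtype=float)

    def with_(self, **overrides) -> "DistortionParams":
        return replace(self, **overrides)


@dataclass(frozen=True)
class Replicate:
    """All score vectors of one replication (continuous and rubric)."""

    theta: NDArray[np.float64]
    h_cont: NDArray[np.float64]
    h2_cont: NDArray[np.float64]
    a_cont: NDArray[np.float64]
    group: NDArray[np.int64]
    h_cat: NDArray[np.int64]
    h2_cat: NDArray[np.int64]
    a_cat: NDArray[np.int64]


def draw_latent(n: int, rng: np.random.Generator) -> NDArray[np.float64]:
    """i.i.d. standard-normal latent ability values."""
    if n < 2:
        raise ValueError("need n >= 2")
    return rng.standard_normal(n)


def gen_human(theta: NDArray[np.float64], sigma_h: float,
              rng: np.random.Generator) -> NDArray[np.float64]:
    """Continuous human score h_i = theta_i + N(0, sigma_h²)."""
    if sigma_h < 0:
        raise ValueError("sigma_h must be non-negative")
    return theta + sigma_h * rng.standard_normal(theta.size)


def gen_ai(theta: NDArray[np.float64], condition: Condition,
           params: DistortionParams,
           rng: np.random.Generator) -> NDArray[np.float64]:
    """Pre-distortion continuous AI score a_i = theta_i + b + N(0, sigma_A²)."""
    sigma_a = params.sigma_a(condition.ai_var_level)
    return theta + condition.bias + sigma_a * rng.standard_normal(theta.size)


def apply_compression(a_cont: NDArray[np.float64],
                      lambda_c: float) -> NDArray[np.float64]:
    """Shrink scores toward the scale centre: a <- (1 - lambda_c)·a."""
    if not 0.0 <= lambda_c < 1.0:
        raise ValueError("lambda_c must lie in [0, 1)")
    return (1.0 - lambda_c) * a_cont


def apply_imbalance(a_cont: NDArray[np.float64],
                    params: DistortionParams) -> NDArray[np.float64]:
    """Reshape the score distribution to skew category prevalence.

    Scores strictly below the empirical ``imb_low_q`` quantile are
    shifted by ``imb_low_shift`` (down by default) and scores strictly
    above the ``imb_high_q`` quantile by ``imb_high_shift`` (up); the
    middle band is untouched.
    """
    q_low, q_high = np.quantile(a_cont, [params.imb_low_q, params.imb_high_q])
    out = a_cont.copy()
    out[a_cont < q_low] += params.imb_low_shift
    out[a_cont > q_high] += params.imb_high_shift
    return out


def apply_fairness(a_cont: NDArray[np.float64], group: NDArray[np.int64],
                   delta: float) -> NDArray[np.float64]:
    """Additive subgroup offset a_i <- a_i + delta·G_i."""
    group = np.asarray(group)
    if not np.isin(group, (0, 1)).all():
        raise ValueError("group indicator must be binary 0/1")
    return a_cont + delta * group


def discretize(x: NDArray[np.float64],
               cutpoints: NDArray[np.float64] | tuple[float, ...]
               ) -> NDArray[np.int64]:
    """Map continuous scores onto rubric categories 0..len(cutpoints).

    category(x) = number of cut-points strictly below x, so intervals
    are left-open and a value exactly on a cut-point falls in the lower
    category.  Monotone by construction.
    """
    cuts = np.asarray(cutpoints, dtype=float)
    if list(cuts) != sorted(set(cuts.tolist())):
        raise ValueError("cut-points must be strictly increasing")
    return np.searchsorted(cuts, x, side="left").astype(np.int64)


def make_replicate(condition: Condition, params: DistortionParams,
                   rng: np.random.Generator) -> Replicate:
    """Generate one full replication under ``condition``.

    Pipeline (fixed order): latent draw -> two human ratings -> AI
    rating -> compression -> imbalance -> fairness (each gated on its
    flag) -> common discretization.  The subgroup indicator is drawn
    unconditionally so the random stream does not depend on the flags.
    """
    theta = draw_latent(condition.n, rng)
    h_cont = gen_human(theta, params.sigma_h, rng)
    h2_cont = gen_human(theta, params.sigma_h, rng)
    a_cont = gen_ai(theta, condition, params, rng)
    group = (rng.random(condition.n) < params.group_prob).astype(np.int64)
    if condition.compression:
        a_cont = apply_compression(a_cont, params.lambda_c)
    if condition.imbalance:
        a_cont = apply_imbalance(a_cont, params)
    if condition.fairness:
        a_cont = apply_fairness(a_cont, group, params.delta)
    cuts = params.cutpoints(condition.imbalance)
    return Replicate(
        theta=theta,
        h_cont=h_cont,
        h2_cont=h2_cont,
        a_cont=a_cont,
        group=group,
        h_cat=discretize(h_cont, cuts),
        h2_cat=discretize(h2_cont, cuts),
        a_cat=discretize(a_cont, cuts),
    )
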