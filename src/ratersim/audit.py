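"""Small-sample audit of real human/AI score tables.

Consumes a long-format score table -- one row per (unit, rater) with a
rater kind (human/ai), an optional teacher-familiarity group and a
numeric score on a declared scale (default 0-70 analytic rubric) -- and
estimates the discrepancy indicators that mirror the simulator's
distortion mechanisms:

* bias: mean(AI - human reference), the additive deviation;
* variance ratio: SD(AI - ref) / pooled SD(teacher - ref), relative
  variability of the AI against the human raters;
* regression slope of AI on the human reference (< 1 indicates
  midpoint compression) with its R²;
* per-familiarity-group mean deviations d_g = AI - teacher_g.

Because such tables are tiny (the motivating design is 6 essays x 3
teachers x 2 AI systems), every statistic is wrapped in a unit-level
percentile bootstrap (B = 2,000 by default) yielding 95% CIs and event
probabilities: Pr(slope < 1) for compression and the probability that
the group deviations follow a declared strict ordering for fairness.
The resulting profile is snapped onto the nearest simulation condition.

A fixture generator produces synthetic score tables with configurable
bias, slope, noise and group offsets so the whole audit path is
testable without any real essay scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datagen import BIAS_LEVELS, N_LEVELS, Condition

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("unit_id", "rater_id", "rater_kind", "system_label",
                    "familiarity_group", "score")
FAMILIARITY_GROUPS = ("direct", "indirect", "unfamiliar")

__all__ = [
    "REQUIRED_COLUMNS", "FAMILIARITY_GROUPS",
    "DiscrepancyStats", "AuditResult", "FixtureConfig", "AISystemConfig",
    "validate_scores", "human_reference", "discrepancy_stats",
    "subgroup_deviations", "bootstrap_audit", "match_condition",
    "make_fixture",
]


@dataclass(frozen=True)
class DiscrepancyStats:
    """Point estimates of the three discrepancy indicators."""

    bias: float
    var_ratio: float
    slope: float
    r_squared: float
    pooled_teacher_sd: float
    n_units: int


@dataclass(frozen=True)
class AuditResult:
    """Bootstrap audit of one AI system against the human reference."""

    system: str
    stats: DiscrepancyStats
    bias_ci: tuple[float, float]
    var_ratio_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    p_compression: float
    p_fairness: float
    group_deviations: dict[str, float]
    matched: Condition | None
    n_boot: int
    n_redrawn: int

    def as_dict(self) -> dict[str, object]:
        s = self.stats
        return {
            "system": self.system,
            "bias": s.bias, "bias_ci": list(self.bias_ci),
            "var_ratio": s.var_ratio, "var_ratio_ci": list(self.var_ratio_ci),
            "slope": s.slope, "slope_ci": list(self.slope_ci),
            "r_squared": s.r_squared,
            "p_compression": self.p_compression,
            "p_fairness": self.p_fairness,
            "group_deviations": dict(self.group_deviations),
            "matched_condition": None if self.matched is None else {
                "n": self.matched.n, "bias": self.matched.bias,
                "ai_var_level": self.matched.ai_var_level,
                "compression": self.matched.compression,
                "imbalance": self.matched.imbalance,
                "fairness": self.matched.fairness,
            },
            "n_boot": self.n_boot, "n_redrawn": self.n_redrawn,
        }


def validate_scores(table: pd.DataFrame,
                    scale: tuple[float, float] = (0.0, 70.0)) -> pd.DataFrame:
    """Check a long-format score table and normalise its dtypes."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table missing columns {missing}")
    t = table.copy()
    t["rater_kind"] = t["rater_kind"].str.lower()
    bad_kind = set(t["rater_kind"]) - {"human", "ai"}
    if bad_kind:
        raise ValueError(f"rater_kind must be 'human' or 'ai', got {bad_kind}")
    t["score"] = pd.to_numeric(t["score"])
    lo, hi = scale
    out_of_range = t[(t["score"] < lo) | (t["score"] > hi)]
    if not out_of_range.empty:
        raise ValueError(f"{len(out_of_range)} scores outside the declared "
                         f"scale [{lo}, {hi}]")
    humans = t[t["rater_kind"] == "human"]
    units_without = set(t["unit_id"]) - set(humans["unit_id"])
    if units_without:
        raise ValueError(f"units without any human score: {sorted(units_without)}")
    return t


def human_reference(table: pd.DataFrame) -> pd.Series:
    """Per-unit human reference: arithmetic mean of the human scores."""
    humans = table[table["rater_kind"] == "human"]
    units_without = set(table["unit_id"]) - set(humans["unit_id"])
    if units_without:
        raise ValueError(f"units without any human score: {sorted(units_without)}")
    return humans.groupby("unit_id")["score"].mean()


def _teacher_residuals(table: pd.DataFrame, ref: pd.Series) -> np.ndarray:
    humans = table[table["rater_kind"] == "human"]
    return (humans["score"] - humans["unit_id"].map(ref)).to_numpy()


def _ai_scores(table: pd.DataFrame, system: str) -> pd.Series:
    ai = table[(table["rater_kind"] == "ai")
               & (table["system_label"] == system)]
    if ai.empty:
        raise ValueError(f"no AI scores for system {system!r}")
    return ai.set_index("unit_id")["score"]


def discrepancy_stats(table: pd.DataFrame, system: str) -> DiscrepancyStats:
    """Bias, variance ratio, regression slope and R² for one AI system."""
    ref = human_reference(table)
    ai = _ai_scores(table, system)
    missing = set(ref.index) - set(ai.index)
    if missing:
        raise ValueError(f"system {system!r} missing scores for units "
                         f"{sorted(missing)}")
    ai = ai.reindex(ref.index)
    diff = (ai - ref).to_numpy()
    bias = float(diff.mean())
    teacher_resid = _teacher_residuals(table, ref)
    pooled_sd = float(np.std(teacher_resid, ddof=1)) if teacher_resid.size > 1 else math.nan
    if not pooled_sd or math.isnan(pooled_sd):
        var_ratio = math.nan
    else:
        var_ratio = float(np.std(diff, ddof=1) / pooled_sd)
    if ref.size < 3 or float(np.std(ref.to_numpy())) == 0.0:
        slope, r2 = math.nan, math.nan
    else:
        fit = stats.linregress(ref.to_numpy(), ai.to_numpy())
        slope, r2 = float(fit.slope), float(fit.rvalue ** 2)
    return DiscrepancyStats(bias=bias, var_ratio=var_ratio, slope=slope,
                            r_squared=r2, pooled_teacher_sd=pooled_sd,
                            n_units=int(ref.size))


def subgroup_deviations(table: pd.DataFrame, system: str) -> dict[str, float]:
    """Mean AI - teacher deviation per familiarity group.

    For each group g, averages (AI score - that group's human score)
    over units.  Groups without human scores are skipped with a
    warning.
    """
    ai = _ai_scores(table, system)
    humans = table[table["rater_kind"] == "human"]
    out: dict[str, float] = {}
    for group, rows in humans.groupby("familiarity_group", dropna=True):
        if rows.empty:
            continue
        dev = (rows["unit_id"].map(ai) - rows["score"]).dropna()
        if dev.empty:
            logger.warning("familiarity group %r has no matched AI scores; "
                           "skipped", group)
            continue
        out[str(group)] = float(dev.mean())
    expected = set(humans["familiarity_group"].dropna())
    for g in expected - set(out):
        logger.warning("familiarity group %r skipped", g)
    return out


def bootstrap_audit(table: pd.DataFrame, system: str, B: int = 2000,
                    rng: np.random.Generator | int | None = None,
                    fairness_order: tuple[str, ...] = FAMILIARITY_GROUPS,
                    match: bool = True,
                    redraw_cap: int = 50) -> AuditResult:
    """Unit-level percentile bootstrap of the audit statistics.

    Units are resampled with replacement ``B`` times; each resample
    yields bias, variance ratio, slope and group deviations, from which
    percentile 95% CIs and the event probabilities are estimated:
    ``p_compression`` is the fraction of bootstrap slopes below 1 and
    ``p_fairness`` the fraction of resamples whose group deviations
    follow ``fairness_order`` strictly ascending in absolute value.
    Degenerate resamples (a single distinct unit, leaving the slope
    undefined) are redrawn up to ``redraw_cap`` times each and logged.
    """
    table = table.reset_index(drop=True)
    point = discrepancy_stats(table, system)
    if point.n_units < 3:
        raise ValueError("bootstrap audit needs at least 3 units")
    rng = np.random.default_rng(rng)

    # Unit-indexed arrays: resampling units with replacement leaves each
    # unit's human reference untouched, so all bootstrap statistics are
    # functions of these per-unit quantities alone.
    ref = human_reference(table)
    units = np.array(sorted(ref.index))
    unit_pos = {u: i for i, u in enumerate(units)}
    ref_v = ref.reindex(units).to_numpy()
    ai_v = _ai_scores(table, system).reindex(units).to_numpy()
    humans = table[table["rater_kind"] == "human"]
    resid_by_unit = [
        (humans.loc[humans["unit_id"] == u, "score"] - ref[u]).to_numpy()
        for u in units]
    has_groups = humans["familiarity_group"].notna().any()
    # per-group, per-unit count and score sum of that group's human rows
    group_cnt: dict[str, np.ndarray] = {}
    group_sum: dict[str, np.ndarray] = {}
    if has_groups:
        for group, rows in humans.groupby("familiarity_group", dropna=True):
            cnt = np.zeros(units.size)
            tot = np.zeros(units.size)
            for _, r in rows.iterrows():
                i = unit_pos[r["unit_id"]]
                cnt[i] += 1
                tot[i] += r["score"]
            group_cnt[str(group)] = cnt
            group_sum[str(group)] = tot

    biases = np.empty(B)
    ratios = np.empty(B)
    slopes = np.empty(B)
    order_ok = np.zeros(B, dtype=bool)
    n_redrawn = 0
    for b in range(B):
        for _attempt in range(redraw_cap + 1):
            idx = rng.integers(0, units.size, size=units.size)
            if np.unique(idx).size > 1:
                break
            n_redrawn += 1
        else:
            raise RuntimeError("bootstrap redraw cap exhausted on a "
                               "degenerate resample")
        r, a = ref_v[idx], ai_v[idx]
        diff = a - r
        biases[b] = diff.mean()
        resid = np.concatenate([resid_by_unit[i] for i in idx])
        pooled = resid.std(ddof=1) if resid.size > 1 else math.nan
        ratios[b] = diff.std(ddof=1) / pooled if pooled else math.nan
        var_r = np.var(r)
        slopes[b] = (np.cov(r, a, bias=True)[0, 1] / var_r
                     if var_r > 0 else math.nan)
        if has_groups and all(g in group_cnt for g in fairness_order):
            mags = []
            for g in fairness_order:
                cnt = group_cnt[g][idx].sum()
                if cnt == 0:
                    break
                dev = (ai_v[idx] * group_cnt[g][idx] - group_sum[g][idx]).sum() / cnt
                mags.append(abs(dev))
            else:
                order_ok[b] = all(x < y for x, y in zip(mags, mags[1:]))
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap resamples", n_redrawn)

    def ci(v: np.ndarray) -> tuple[float, float]:
        v = v[~np.isnan(v)]
        if v.size == 0:
            return (math.nan, math.nan)
        lo, hi = np.percentile(v, [2.5, 97.5])
        return (float(lo), float(hi))

    valid_slopes = slopes[~np.isnan(slopes)]
    p_comp = float((valid_slopes < 1.0).mean()) if valid_slopes.size else math.nan
    p_fair = float(order_ok.mean()) if has_groups else math.nan
    groups = subgroup_deviations(table, system) if has_groups else {}
    matched = None
    if match:
        matched = match_condition(point, p_comp, p_fair)
    return AuditResult(system=system, stats=point,
                       bias_ci=ci(biases), var_ratio_ci=ci(ratios),
                       slope_ci=ci(slopes), p_compression=p_comp,
                       p_fairness=p_fair, group_deviations=groups,
                       matched=matched, n_boot=B, n_redrawn=n_redrawn)


def match_condition(stats: DiscrepancyStats, p_compression: float,
                    p_fairness: float, sigma_h: float = 0.50,
                    var_bounds: tuple[float, float] = (0.75, 1.10),
                    p_comp_cut: float = 0.6,
                    p_fair_cut: float = 0.95) -> Condition:
    """Snap audit statistics onto the nearest simulation condition.

    Point-scale bias is standardised by the pooled teacher-residual SD
    (putting it in human-error-SD units), converted to latent-trait
    units via ``sigma_h``, and snapped to the nearest design bias level.
    The variance ratio maps to low/mid/high via ``var_bounds``; the
    compression and fairness flags fire when their bootstrap
    probabilities reach ``p_comp_cut`` / ``p_fair_cut``.  The imbalance
    flag is never inferred (no audit statistic formalises it).  Raises
    when the variance ratio is undefined.
    """
    if math.isnan(stats.var_ratio):
        raise ValueError(
            "cannot match a simulation condition: variance ratio undefined "
            "(zero pooled teacher-residual SD)")
    std_bias = stats.bias / stats.pooled_teacher_sd * sigma_h
    bias = min(BIAS_LEVELS, key=lambda b: abs(b - std_bias))
    low_hi, mid_hi = var_bounds
    if stats.var_ratio < low_hi:
        var = "low"
    elif stats.var_ratio <= mid_hi:
        var = "mid"
    else:
        var = "high"
    n = min(N_LEVELS, key=lambda lev: abs(lev - stats.n_units))
    return Condition(
        n=n, bias=bias, ai_var_level=var,
        compression=bool(not math.isnan(p_compression)
                         and p_compression >= p_comp_cut),
        imbalance=False,
        fairness=bool(not math.isnan(p_fairness)
                      and p_fairness >= p_fair_cut),
    )


@dataclass(frozen=True)
class AISystemConfig:
    """Linear scoring model of one AI system: score = intercept + slope·true + noise."""

    intercept: float
    slope: float
    noise_sd: float


@dataclass(frozen=True)
class FixtureConfig:
    """Configuration of the synthetic score-table generator.

    Emulates the motivating audit layout -- six essays scored by three
    teachers (one per familiarity group) and two AI systems on a 0-70
    analytic rubric.  ``teacher_offsets`` shift each familiarity
    group's scores, which is what the subgroup-deviation statistics
    pick up; the default AI systems compress (slope < 1) and sit below
    the human reference, the regime the audit is meant to flag.
    """

    n_units: int = 6
    scale: tuple[float, float] = (0.0, 70.0)
    true_mean: float = 45.0
    true_sd: float = 8.0
    teacher_sd: float = 4.0
    teacher_offsets: dict[str, float] = field(
        default_factory=lambda: {"direct": 0.0, "indirect": 0.0,
                                 "unfamiliar": 0.0})
    systems: dict[str, AISystemConfig] = field(
        default_factory=lambda: {
            "gpt": AISystemConfig(intercept=13.5, slope=0.50, noise_sd=3.0),
            "gemini": AISystemConfig(intercept=3.0, slope=0.67, noise_sd=6.0),
        })


def make_fixture(config: FixtureConfig | None = None,
                 rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Generate a synthetic long-format score table.

    One teacher per familiarity group scores every unit as
    ``true + group offset + N(0, teacher_sd²)``; each AI system scores
    ``intercept + slope·true + N(0, noise_sd²)``.  All scores are
    clipped to the declared scale and the table passes
    :func:`validate_scores`.
    """
    config = config or FixtureConfig()
    rng = np.random.default_rng(rng)
    lo, hi = config.scale
    true = config.true_mean + config.true_sd * rng.standard_normal(config.n_units)
    true = np.clip(true, lo, hi)
    rows = []
    for g_idx, (group, offset) in enumerate(sorted(config.teacher_offsets.items())):
        scores = np.clip(
            true + offset + config.teacher_sd * rng.standard_normal(config.n_units),
            lo, hi)
        for u in range(config.n_units):
            rows.append({"unit_id": f"u{u}", "rater_id": f"teacher_{g_idx}",
                         "rater_kind": "human", "system_label": "",
                         "familiarity_group": group,
                         "score": float(scores[u])})
    for system, cfg in config.systems.items():
        scores = np.clip(
            cfg.intercept + cfg.slope * true
            + cfg.noise_sd * rng.standard_normal(config.n_units),
            lo, hi)
        for u in range(config.n_units):
            rows.append({"unit_id": f"u{u}", "rater_id": system,
                         "rater_kind": "ai", "system_label": system,
                         "familiarity_group": None,
                         "score": float(scores[u])})
    return validate_scores(pd.DataFrame(rows), scale=config.scale)
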