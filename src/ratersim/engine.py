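"""Factorial Monte Carlo engine and exceedance aggregation.

Enumerates the fully crossed design (3 sample sizes x 3 bias levels x
3 AI variance levels x 3 binary distortion flags = 216 conditions),
runs seeded replications through the data generator and the agreement
metrics, applies the adequacy-threshold policy per replication, and
aggregates threshold-exceedance proportions with Wilson confidence
intervals and Monte Carlo standard errors.

Replication-level metric values are retained (and optionally persisted
to Parquet or CSV) so that threshold-sensitivity analysis and the
logistic-regression summaries re-threshold without re-simulating.

Seeding: a master seed spawns one independent substream per condition
via ``SeedSequence([master_seed, condition_index])``, so any condition
can be re-run in isolation and reproduces bitwise.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datagen import (BIAS_LEVELS, N_LEVELS, VAR_LEVELS, Condition,
                      DistortionParams, make_replicate)
from .metrics import MetricSet, RatingPair, metric_set, qwk, wilson_interval

logger = logging.getLogger(__name__)

#: metrics that carry an adequacy threshold, in reporting order
FLAG_METRICS: tuple[str, ...] = ("icc", "alpha", "qwk", "tol")

#: per-replication columns stored for re-thresholding
STORE_VALUE_COLUMNS: tuple[str, ...] = (
    "icc", "alpha", "qwk", "hh_qwk", "tol1", "tol2", "ba_bias", "ba_sd")

CONDITION_COLUMNS: tuple[str, ...] = (
    "cond_index", "n", "bias", "ai_var_level",
    "compression", "imbalance", "fairness")

__all__ = [
    "FLAG_METRICS", "ThresholdPolicy", "ConditionSummary", "RunManifest",
    "build_design", "strict_null_conditions", "exceedance_flags",
    "run_condition", "run_design", "threshold_sensitivity", "type_i_table",
    "write_store", "read_store",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    """Per-metric adequacy cut-offs and the QWK human-human gap rule.

    The QWK flag requires both ``qwk >= qwk_threshold`` and that the
    human--AI QWK stays within ``qwk_gap`` of the human--human QWK from
    the auxiliary second human rater.  All comparisons are inclusive
    (``>=``).  Defaults centre on the sensitivity grids (ICC 0.70,
    alpha 0.80, QWK 0.70); :meth:`textual` gives the alternative
    profile from conventional adequacy guidelines (alpha 0.67,
    QWK 0.60).
    """

    icc_threshold: float = 0.70
    alpha_threshold: float = 0.80
    qwk_threshold: float = 0.70
    qwk_gap: float = 0.10
    tol_threshold: float = 0.70
    tol_k: int = 1

    def __post_init__(self) -> None:
        for name in ("icc_threshold", "alpha_threshold", "qwk_threshold",
                     "tol_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1]")
        if self.qwk_gap < 0:
            raise ValueError("qwk_gap must be non-negative")
        if self.tol_k not in (1, 2):
            raise ValueError("tol_k must be 1 or 2 (stored tolerance bands)")

    @classmethod
    def textual(cls) -> "ThresholdPolicy":
        """Conventional-guideline profile: alpha 0.67, QWK 0.60."""
        return cls(alpha_threshold=0.67, qwk_threshold=0.60)

    def threshold(self, metric: str) -> float:
        return {"icc": self.icc_threshold, "alpha": self.alpha_threshold,
                "qwk": self.qwk_threshold, "tol": self.tol_threshold}[metric]


@dataclass(frozen=True)
class ConditionSummary:
    """Aggregated operating characteristics of one design cell."""

    condition: Condition
    reps: int
    exceed: dict[str, float]
    wilson_lower: dict[str, float]
    wilson_upper: dict[str, float]
    mcse: dict[str, float]
    mean: dict[str, float]
    sd: dict[str, float]
    undefined: dict[str, int]

    def as_row(self) -> dict[str, object]:
        c = self.condition
        row: dict[str, object] = {
            "n": c.n, "bias": c.bias, "ai_var_level": c.ai_var_level,
            "compression": c.compression, "imbalance": c.imbalance,
            "fairness": c.fairness, "reps": self.reps,
        }
        for m in FLAG_METRICS:
            row[f"{m}_exceed"] = self.exceed[m]
            row[f"{m}_lower"] = self.wilson_lower[m]
            row[f"{m}_upper"] = self.wilson_upper[m]
            row[f"{m}_mcse"] = self.mcse[m]
            row[f"{m}_undefined"] = self.undefined[m]
        for m in ("icc", "alpha", "qwk", "tol1", "tol2", "ba_bias", "ba_sd"):
            row[f"{m}_mean"] = self.mean[m]
            row[f"{m}_sd"] = self.sd[m]
        return row


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run bitwise."""

    master_seed: int
    reps: int
    n_conditions: int
    policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    params: DistortionParams = field(default_factory=DistortionParams)
    alpha_distance: str = "squared_category"
    icc_form: str = "twoway"
    version: str = "unknown"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


def build_design(
    n_levels: tuple[int, ...] = N_LEVELS,
    bias_levels: tuple[float, ...] = BIAS_LEVELS,
    var_levels: tuple[str, ...] = VAR_LEVELS,
    compression_levels: tuple[bool, ...] = (False, True),
    imbalance_levels: tuple[bool, ...] = (False, True),
    fairness_levels: tuple[bool, ...] = (False, True),
) -> list[Condition]:
    """Cartesian product of the factor levels in a fixed documented order.

    Iteration order is row-major over (n, bias, variance, compression,
    imbalance, fairness) with the last factor varying fastest; the
    default grid yields the full 216-cell design.
    """
    for name, levels in (("n", n_levels), ("bias", bias_levels),
                         ("variance", var_levels),
                         ("compression", compression_levels),
                         ("imbalance", imbalance_levels),
                         ("fairness", fairness_levels)):
        if len(levels) == 0:
            raise ValueError(f"empty level set for factor {name!r}")
    return [
        Condition(n=n, bias=b, ai_var_level=v, compression=c,
                  imbalance=i, fairness=f, strict=False)
        for n, b, v, c, i, f in itertools.product(
            n_levels, bias_levels, var_levels, compression_levels,
            imbalance_levels, fairness_levels)
    ]


def strict_null_conditions(conditions: list[Condition]) -> list[Condition]:
    """The strict-null cells: b = 0, mid variance, all flags off."""
    return [c for c in conditions if c.is_strict_null]


def condition_rng(master_seed: int, cond_index: int) -> np.random.Generator:
    """Independent, individually re-runnable substream for one condition."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, cond_index]))


def exceedance_flags(m: MetricSet, hh_qwk: float,
                     policy: ThresholdPolicy) -> dict[str, float]:
    """Per-metric binary adequacy flags (1.0 / 0.0, ``nan`` if undefined).

    ICC, alpha and tolerance compare inclusively against their
    thresholds; the QWK flag additionally requires
    ``|qwk - hh_qwk| <= qwk_gap``.  An undefined metric (or undefined
    human-human QWK for the gap rule) yields an undefined flag, which
    aggregation excludes from both numerator and denominator.
    """
    tol = m.tol1 if policy.tol_k == 1 else m.tol2
    flags: dict[str, float] = {}
    flags["icc"] = math.nan if math.isnan(m.icc_a1) else float(
        m.icc_a1 >= policy.icc_threshold)
    flags["alpha"] = math.nan if math.isnan(m.kripp_alpha) else float(
        m.kripp_alpha >= policy.alpha_threshold)
    if math.isnan(m.qwk) or math.isnan(hh_qwk):
        flags["qwk"] = math.nan
    else:
        flags["qwk"] = float(m.qwk >= policy.qwk_threshold
                             and abs(m.qwk - hh_qwk) <= policy.qwk_gap)
    flags["tol"] = float(tol >= policy.tol_threshold)
    return flags


def _replication_frame(condition: Condition, reps: int,
                       params: DistortionParams, rng: np.random.Generator,
                       alpha_distance: str, icc_form: str,
                       cond_index: int) -> pd.DataFrame:
    """Per-replication metric values for one condition."""
    rows = np.empty((reps, len(STORE_VALUE_COLUMNS)))
    for r in range(reps):
        rep = make_replicate(condition, params, rng)
        pair = RatingPair(rep.h_cat, rep.a_cat)
        m = metric_set(pair, alpha_distance=alpha_distance, icc_form=icc_form)
        hh = qwk(RatingPair(rep.h_cat, rep.h2_cat))
        rows[r] = (m.icc_a1, m.kripp_alpha, m.qwk, hh,
                   m.tol1, m.tol2, m.ba_bias, m.ba_sd)
    df = pd.DataFrame(rows, columns=list(STORE_VALUE_COLUMNS))
    df.insert(0, "rep", np.arange(reps))
    for col, val in (("cond_index", cond_index), ("n", condition.n),
                     ("bias", condition.bias),
                     ("ai_var_level", condition.ai_var_level),
                     ("compression", condition.compression),
                     ("imbalance", condition.imbalance),
                     ("fairness", condition.fairness)):
        df.insert(0, col, val)
    return df[list(CONDITION_COLUMNS) + ["rep"] + list(STORE_VALUE_COLUMNS)]


def flags_frame(store: pd.DataFrame, policy: ThresholdPolicy) -> pd.DataFrame:
    """Vectorised per-replication adequacy flags for a replication store."""
    out = store[list(CONDITION_COLUMNS) + ["rep"]].copy()
    out["icc"] = _ge_flag(store["icc"], policy.icc_threshold)
    out["alpha"] = _ge_flag(store["alpha"], policy.alpha_threshold)
    gap_ok = (store["qwk"] - store["hh_qwk"]).abs() <= policy.qwk_gap
    qwk_flag = _ge_flag(store["qwk"], policy.qwk_threshold) * gap_ok
    qwk_flag[store["qwk"].isna() | store["hh_qwk"].isna()] = np.nan
    out["qwk"] = qwk_flag
    tol_col = "tol1" if policy.tol_k == 1 else "tol2"
    out["tol"] = _ge_flag(store[tol_col], policy.tol_threshold)
    return out


def _ge_flag(values: pd.Series, threshold: float) -> pd.Series:
    flag = (values >= threshold).astype(float)
    flag[values.isna()] = np.nan
    return flag


def _summarize(condition: Condition, rep_df: pd.DataFrame,
               policy: ThresholdPolicy) -> ConditionSummary:
    flags = flags_frame(rep_df, policy)
    exceed, lower, upper, mcse, undefined = {}, {}, {}, {}, {}
    for m in FLAG_METRICS:
        f = flags[m]
        valid = f.dropna()
        undefined[m] = int(f.isna().sum())
        if undefined[m]:
            logger.info("condition %s: %d undefined %s flags excluded",
                        condition.label, undefined[m], m)
        if valid.empty:
            exceed[m] = lower[m] = upper[m] = mcse[m] = math.nan
            continue
        k, n_valid = int(valid.sum()), int(valid.size)
        p = k / n_valid
        w = wilson_interval(k, n_valid)
        exceed[m], lower[m], upper[m] = p, w.lower, w.upper
        mcse[m] = math.sqrt(p * (1.0 - p) / n_valid)
    mean, sd = {}, {}
    for m in ("icc", "alpha", "qwk", "tol1", "tol2", "ba_bias", "ba_sd"):
        col = rep_df[m]
        mean[m] = float(col.mean())
        sd[m] = float(col.std(ddof=1))
    return ConditionSummary(condition=condition, reps=len(rep_df),
                            exceed=exceed, wilson_lower=lower,
                            wilson_upper=upper, mcse=mcse, mean=mean, sd=sd,
                            undefined=undefined)


def run_condition(condition: Condition, reps: int,
                  policy: ThresholdPolicy | None = None,
                  params: DistortionParams | None = None,
                  seed: int = 0, cond_index: int = 0,
                  alpha_distance: str = "squared_category",
                  icc_form: str = "twoway",
                  ) -> tuple[ConditionSummary, pd.DataFrame]:
    """Run one design cell: seeded replications plus aggregation."""
    if reps < 1:
        raise ValueError("need at least one replication")
    policy = policy or ThresholdPolicy()
    params = params or DistortionParams()
    rng = condition_rng(seed, cond_index)
    rep_df = _replication_frame(condition, reps, params, rng,
                                alpha_distance, icc_form, cond_index)
    return _summarize(condition, rep_df, policy), rep_df


def run_design(conditions: list[Condition] | None = None, reps: int = 5000,
               policy: ThresholdPolicy | None = None,
               params: DistortionParams | None = None,
               master_seed: int = 0, store_path: str | None = None,
               alpha_distance: str = "squared_category",
               icc_form: str = "twoway", progress: bool = False,
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a list of conditions; return (summary table, replication store).

    The summary table has one row per condition with exceedance
    proportions, Wilson bounds, MCSEs and raw-metric means/SDs; the
    store has one row per replication and is what
    :func:`threshold_sensitivity` and the GLM analyses consume.  If
    ``store_path`` is given the store (plus a JSON manifest alongside)
    is persisted via :func:`write_store`.
    """
    conditions = conditions if conditions is not None else build_design()
    policy = policy or ThresholdPolicy()
    params = params or DistortionParams()
    summaries, stores = [], []
    for idx, cond in enumerate(conditions):
        summary, rep_df = run_condition(
            cond, reps, policy, params, seed=master_seed, cond_index=idx,
            alpha_distance=alpha_distance, icc_form=icc_form)
        summaries.append(summary.as_row())
        stores.append(rep_df)
        if progress:
            logger.info("[%d/%d] %s done", idx + 1, len(conditions), cond.label)
    summary_df = pd.DataFrame(summaries)
    store_df = pd.concat(stores, ignore_index=True)
    if store_path is not None:
        manifest = RunManifest(master_seed=master_seed, reps=reps,
                               n_conditions=len(conditions), policy=policy,
                               params=params, alpha_distance=alpha_distance,
                               icc_form=icc_form, version=_version())
        write_store(store_df, store_path, manifest)
    return summary_df, store_df


def _version() -> str:
    from . import __version__
    return __version__


def write_store(store: pd.DataFrame, path: str,
                manifest: RunManifest | None = None) -> None:
    """Persist a replication store (Parquet by default, CSV by suffix)."""
    try:
        if str(path).endswith(".csv"):
            store.to_csv(path, index=False)
        else:
            store.to_parquet(path, index=False)
    except OSError as exc:  # pragma: no cover - I/O environment dependent
        raise OSError(f"failed writing replication store to {path}") from exc
    if manifest is not None:
        with open(str(path) + ".manifest.json", "w") as fh:
            fh.write(manifest.to_json())


def read_store(path: str) -> pd.DataFrame:
    if str(path).endswith(".csv"):
        return pd.read_csv(path)
    return pd.read_parquet(path)


DEFAULT_GRIDS: dict[str, tuple[float, ...]] = {
    "icc": (0.60, 0.65, 0.70, 0.75, 0.80),
    "alpha": (0.70, 0.75, 0.80, 0.85, 0.90),
    "qwk": (0.60, 0.65, 0.70, 0.75, 0.80),
}


def threshold_sensitivity(store: pd.DataFrame,
                          grids: dict[str, tuple[float, ...]] | None = None,
                          policy: ThresholdPolicy | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-threshold a replication store over grids of alternative cut-offs.

    For each metric x candidate threshold, per-condition success
    proportions are recomputed from the stored replication-level values
    (no re-simulation); the output reports their mean and SD across
    conditions, Table-7 style.  The QWK gap rule applies at every
    candidate QWK threshold.

    Also returns a rank-order stability table: for each grid offset
    position, the proportion of conditions whose ordering of the three
    coefficient metrics (by success proportion) differs from the
    baseline ordering at the grid midpoints.
    """
    grids = grids or DEFAULT_GRIDS
    policy = policy or ThresholdPolicy()
    for metric, grid in grids.items():
        for t in grid:
            if not 0.0 < t <= 1.0:
                raise ValueError(
                    f"threshold {t} for {metric!r} outside (0, 1]")
    rows = []
    per_condition: dict[tuple[str, float], pd.Series] = {}
    for metric, grid in grids.items():
        for t in grid:
            if metric == "qwk":
                ok = (store["qwk"] >= t) & \
                     ((store["qwk"] - store["hh_qwk"]).abs() <= policy.qwk_gap)
                flag = ok.astype(float)
                flag[store["qwk"].isna() | store["hh_qwk"].isna()] = np.nan
            else:
                flag = _ge_flag(store[metric], t)
            props = flag.groupby(store["cond_index"]).mean()
            per_condition[(metric, t)] = props
            rows.append({"metric": metric, "threshold": t,
                         "mean_success": float(props.mean()),
                         "sd_success": float(props.std(ddof=1))})
    table = pd.DataFrame(rows)

    stability_rows = []
    offsets = range(min(len(g) for g in grids.values()))
    mid = len(next(iter(grids.values()))) // 2
    base = _ordering(per_condition, grids, mid)
    for pos in offsets:
        cur = _ordering(per_condition, grids, pos)
        changed = float((cur != base).mean())
        stability_rows.append({
            "grid_position": pos,
            "thresholds": {m: grids[m][pos] for m in grids},
            "prop_order_changed": changed,
        })
    return table, pd.DataFrame(stability_rows)


def _ordering(per_condition: dict[tuple[str, float], pd.Series],
              grids: dict[str, tuple[float, ...]], pos: int) -> pd.Series:
    cols = {m: per_condition[(m, grids[m][pos])] for m in grids}
    df = pd.DataFrame(cols)
    return df.apply(lambda r: tuple(r.rank(method="first")), axis=1)


def type_i_table(summary_df: pd.DataFrame) -> pd.DataFrame:
    """Strict-null Type I table: per sample size and metric, the false
    threshold-exceedance proportion with Wilson bounds and MCSE.

    Filters the summary table to the strict-null cells (bias 0, mid
    variance, no distortion flags) and melts to long form.
    """
    null_rows = summary_df[
        (summary_df["bias"] == 0.0) & (summary_df["ai_var_level"] == "mid")
        & ~summary_df["compression"] & ~summary_df["imbalance"]
        & ~summary_df["fairness"]]
    if null_rows.empty:
        raise ValueError("summary table contains no strict-null conditions")
    out = []
    for _, row in null_rows.sort_values("n").iterrows():
        for m in FLAG_METRICS:
            out.append({"n": int(row["n"]), "metric": m,
                        "type_i": row[f"{m}_exceed"],
                        "lower": row[f"{m}_lower"],
                        "upper": row[f"{m}_upper"],
                        "mcse": row[f"{m}_mcse"]})
    return pd.DataFrame(out)
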