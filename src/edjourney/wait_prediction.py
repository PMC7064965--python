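"""Waiting-time ranges via conditional quantiles.

Each procedure gets its own estimator of the conditional 0.15- and
0.85-quantiles of the waiting time, reported to patients as a range
"between X and Y min"; the 0.85 upper bound means that no more than 15%
of realized waits should exceed the displayed range.

Two estimators are provided behind one interface:

* a quantile forest: a random-forest regressor whose leaves retain the
  training waits, so conditional quantiles are weighted empirical
  quantiles of leaf co-inhabitants pooled across trees;
* a stratified empirical-quantile baseline (hour-of-day blocks), used
  for procedures with too few rows and as an independent reference.

The quantile convention everywhere is the ceiling-index order statistic
(inverse empirical CDF): the q-quantile of a sample of size n is the
ceil(q*n)-th order statistic.  With this convention the fraction of
training waits strictly above the fitted per-procedure upper bound is at
most 1-q by construction for the baseline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .queue_mining import FEATURE_COLUMNS, FeatureVector


@dataclass
class TrainParams:
    lower_q: float = 0.15
    upper_q: float = 0.85
    n_estimators: int = 100
    # leaves retain the training waits; ~10 per leaf keeps tail order
    # statistics from tiny leaves from inflating the upper quantile
    min_samples_leaf: int = 10
    min_rows: int = 50  # below this, a procedure uses the empirical baseline
    seed: int = 17

    def validate(self) -> None:
        if not 0.0 < self.lower_q < self.upper_q < 1.0:
            raise ValueError("need 0 < lower_q < upper_q < 1")


@dataclass
class WaitRange:
    lower: float
    point: float
    upper: float
    fallback_applied: bool = False

    def __post_init__(self):
        lo, mid, hi = sorted((self.lower, self.point, self.upper))
        self.lower, self.point, self.upper = lo, mid, hi


def empirical_quantile(values: np.ndarray, q: float) -> float:
    """Ceiling-index order statistic: the ceil(q*n)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("empty sample")
    k = max(1, math.ceil(q * len(v)))
    return float(v[k - 1])


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Smallest value whose cumulative weight reaches q of the total."""
    order = np.argsort(values)
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cw = np.cumsum(w)
    idx = int(np.searchsorted(cw, q * cw[-1] - 1e-12, side="left"))
    return float(v[min(idx, len(v) - 1)])


# ----------------------------------------------------------------------
# Per-procedure estimators
# ----------------------------------------------------------------------

class _EmpiricalBaseline:
    """Empirical quantiles stratified by hour-of-day block (0-5, 6-11,
    12-17, 18-23); empty strata fall back to the pooled sample."""

    kind = "baseline"

    def __init__(self, X: pd.DataFrame, y: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        self.strata: dict[int, np.ndarray] = {}
        blocks = (X["hour_of_day"].to_numpy() // 6).astype(int)
        for b in range(4):
            sample = self.y[blocks == b]
            if len(sample):
                self.strata[b] = np.sort(sample)

    def quantiles(self, row: dict, qs: list[float]) -> list[float]:
        block = int(row["hour_of_day"]) // 6
        sample = self.strata.get(block, self.y)
        return [empirical_quantile(sample, q) for q in qs]


class _QuantileForest:
    """Random forest with per-leaf retention of training waits."""

    kind = "forest"

    def __init__(self, X: pd.DataFrame, y: np.ndarray, params: TrainParams, seed: int):
        self.features = FEATURE_COLUMNS
        self.forest = RandomForestRegressor(
            n_estimators=params.n_estimators,
            min_samples_leaf=params.min_samples_leaf,
            max_features=0.6,
            random_state=seed,
            n_jobs=1,
        )
        Xm = X[self.features].to_numpy(dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.forest.fit(Xm, self.y)
        leaves = self.forest.apply(Xm)  # (n_samples, n_trees)
        # per (tree, leaf): indices of training samples in that leaf
        self.leaf_members: list[dict[int, np.ndarray]] = []
        for tree_idx in range(leaves.shape[1]):
            col = leaves[:, tree_idx]
            order = np.argsort(col, kind="stable")
            sorted_leaves = col[order]
            bounds = np.flatnonzero(np.diff(sorted_leaves)) + 1
            groups = np.split(order, bounds)
            self.leaf_members.append({int(col[g[0]]): g for g in groups})

    def quantiles(self, row: dict, qs: list[float]) -> list[float]:
        x = np.array([[float(row[f]) for f in self.features]])
        leaves = self.forest.apply(x)[0]
        values, weights = [], []
        for tree_idx, leaf in enumerate(leaves):
            members = self.leaf_members[tree_idx].get(int(leaf))
            if members is None:
                continue
            values.append(self.y[members])
            weights.append(np.full(len(members), 1.0 / len(members)))
        v = np.concatenate(values)
        w = np.concatenate(weights)
        return [weighted_quantile(v, w, q) for q in qs]


# ----------------------------------------------------------------------
# WaitModel
# ----------------------------------------------------------------------

@dataclass
class WaitModel:
    """Per-procedure conditional-quantile models plus training metadata.

    The training table is retained on the model; persistence stores the
    parameters and the table, and loading refits deterministically from
    them (the forests are seeded)."""

    params: TrainParams
    table: pd.DataFrame
    estimators: dict = field(default_factory=dict)
    baseline_procedures: set = field(default_factory=set)
    metadata: dict = field(default_factory=dict)


def train(table: pd.DataFrame, params: TrainParams | None = None) -> WaitModel:
    """Fit one range model per procedure found in the training table."""
    params = params or TrainParams()
    params.validate()
    if table is None or len(table) == 0:
        raise ValueError("empty training table")
    missing = [c for c in FEATURE_COLUMNS + ["procedure", "wait_minutes"] if c not in table.columns]
    if missing:
        raise ValueError(f"training table missing columns: {missing}")
    model = WaitModel(params=params, table=table.reset_index(drop=True))
    for i, (proc, group) in enumerate(sorted(table.groupby("procedure"), key=lambda kv: kv[0])):
        y = group["wait_minutes"].to_numpy(dtype=float)
        if len(group) >= params.min_rows:
            model.estimators[proc] = _QuantileForest(group, y, params, seed=params.seed + i)
        else:
            model.estimators[proc] = _EmpiricalBaseline(group, y)
            model.baseline_procedures.add(proc)
    model.metadata = {
        "rows": int(len(table)),
        "procedures": sorted(model.estimators),
        "seed": params.seed,
        "trained_at": datetime.now().strftime("%Y-%m-%dT%H:%M"),
    }
    return model


def _as_row(fv) -> dict:
    return fv.to_row() if isinstance(fv, FeatureVector) else dict(fv)


def predict_range(model: WaitModel, procedure: str, fv) -> WaitRange:
    """Conditional [lower_q, upper_q] range and median point estimate,
    rounded to whole minutes for display."""
    est = model.estimators.get(procedure)
    if est is None:
        raise KeyError(f"no model or baseline for procedure {procedure!r}")
    row = _as_row(fv)
    lo, mid, hi = est.quantiles(row, [model.params.lower_q, 0.5, model.params.upper_q])
    return WaitRange(
        lower=round(max(lo, 0.0)), point=round(max(mid, 0.0)), upper=round(max(hi, 0.0))
    )


LOS_LABEL = "__los__"


def train_los(los_table: pd.DataFrame, params: TrainParams | None = None) -> WaitModel:
    """Fit the total length-of-stay model on ED-level arrival snapshots.

    ``los_table`` has the feature columns plus ``los_minutes``."""
    t = los_table.copy()
    t["procedure"] = LOS_LABEL
    t["wait_minutes"] = t["los_minutes"]
    return train(t, params)


def predict_los(
    los_model: WaitModel,
    fv,
    elapsed_minutes: float,
    realized_minutes: float | None = None,
) -> WaitRange:
    """Total-stay range; never promises less than the stay so far.

    For a discharged patient pass ``realized_minutes``: the range
    collapses onto the realized stay."""
    if realized_minutes is not None:
        m = round(realized_minutes)
        return WaitRange(m, m, m)
    r = predict_range(los_model, LOS_LABEL, fv)
    e = round(max(elapsed_minutes, 0.0))
    return WaitRange(max(r.lower, e), max(r.point, e), max(r.upper, e))


# ----------------------------------------------------------------------
# Evaluation
# ----------------------------------------------------------------------

@dataclass
class EvalReport:
    per_procedure: pd.DataFrame  # procedure, n, exceedance_rate, undershoot_rate, mean_width, point_mae
    pooled: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "pooled": self.pooled,
                "per_procedure": self.per_procedure.to_dict(orient="records"),
            },
            indent=1,
        )


def evaluate(model: WaitModel, table: pd.DataFrame) -> EvalReport:
    """Exceedance (actual strictly above the upper bound — the system's
    "underestimation"), undershoot, interval width and point MAE, by
    direct counting."""
    rows = []
    details = []
    for proc, group in table.groupby("procedure"):
        if proc not in model.estimators:
            continue
        actual = group["wait_minutes"].to_numpy(dtype=float)
        lowers, uppers, points = [], [], []
        for _, r in group.iterrows():
            wr = predict_range(model, proc, r[FEATURE_COLUMNS].to_dict())
            lowers.append(wr.lower)
            uppers.append(wr.upper)
            points.append(wr.point)
        lowers, uppers, points = map(np.array, (lowers, uppers, points))
        n = len(actual)
        exceed = int(np.sum(actual > uppers))
        under = int(np.sum(actual < lowers))
        rows.append(
            {
                "procedure": proc,
                "n": n,
                "exceedance_rate": exceed / n,
                "undershoot_rate": under / n,
                "mean_width": float(np.mean(uppers - lowers)),
                "point_mae": float(np.mean(np.abs(actual - points))),
            }
        )
        details.append((n, exceed, under, np.sum(uppers - lowers), np.sum(np.abs(actual - points))))
    per_proc = pd.DataFrame(
        rows,
        columns=["procedure", "n", "exceedance_rate", "undershoot_rate", "mean_width", "point_mae"],
    )
    n_total = sum(d[0] for d in details)
    pooled = {
        "n": int(n_total),
        "exceedance_rate": (sum(d[1] for d in details) / n_total) if n_total else 0.0,
        "undershoot_rate": (sum(d[2] for d in details) / n_total) if n_total else 0.0,
        "mean_width": (sum(d[3] for d in details) / n_total) if n_total else 0.0,
        "point_mae": (sum(d[4] for d in details) / n_total) if n_total else 0.0,
    }
    return EvalReport(per_procedure=per_proc, pooled=pooled)


def retrain(model: WaitModel, new_rows: pd.DataFrame, mode: str = "append") -> WaitModel:
    """Refit on old+new rows (``mode='append'``) or new rows only
    (``mode='replace'``); lineage recorded in metadata."""
    if mode not in ("append", "replace"):
        raise ValueError("mode must be 'append' or 'replace'")
    if len(new_rows):
        missing = [c for c in FEATURE_COLUMNS + ["procedure", "wait_minutes"] if c not in new_rows.columns]
        if missing:
            raise ValueError(f"new rows missing columns: {missing}")
    if mode == "append":
        combined = (
            pd.concat([model.table, new_rows], ignore_index=True)
            if len(new_rows)
            else model.table
        )
    else:
        combined = new_rows
    fresh = train(combined, replace(model.params))
    fresh.metadata["lineage"] = {
        "parent_rows": int(len(model.table)),
        "new_rows": int(len(new_rows)),
        "mode": mode,
    }
    return fresh


# ----------------------------------------------------------------------
# Persistence: params JSON + training-table CSV; load refits (seeded)
# ----------------------------------------------------------------------

def save_model(model: WaitModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "params.json", "w", encoding="utf-8") as fh:
        json.dump({"params": asdict(model.params), "metadata": model.metadata}, fh, indent=1)
    model.table.to_csv(path / "table.csv", index=False)


def load_model(path: str | Path) -> WaitModel:
    path = Path(path)
    with open(path / "params.json", encoding="utf-8") as fh:
        doc = json.load(fh)
    params = TrainParams(**doc["params"])
    table = pd.read_csv(path / "table.csv")
    model = train(table, params)
    model.metadata.update(doc.get("metadata", {}))
    return model
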