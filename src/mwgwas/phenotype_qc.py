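"""Quality control of electronic-feeder event records and adjusted test intake.

Growing pigs feed ad libitum from single-space electronic feeders that log
one row per visit: animal, pen, day on test, visit duration and feed
disappearance.  Device faults (stuck ID antennas, scale drift, blocked
hoppers) produce physically implausible events, so records are screened
against logical bounds on meal duration, amount consumed and consumption
rate before daily intakes are summed.  Feeder-level faults are caught at the
pen x day level from the aberrant-event load, total feed dispensed and event
count.  Per-animal adjusted test intake over the full test is obtained by
removing fixed effects (gender, group-pen) and imputing missing days from a
per-animal polynomial trajectory in day on test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["animal_id", "pen_id", "day", "duration_s", "amount_kg"]


@dataclass(frozen=True)
class QcThresholds:
    """Bounds on a single feeding event; all comparisons are strict.

    Defaults: 1 s < duration < 3600 s, 0.020 kg < amount < 3.0 kg,
    rate < 2.0 kg/min, with rate recomputed as amount / (duration / 60).
    """

    min_duration_s: float = 1.0
    max_duration_s: float = 3600.0
    min_amount_kg: float = 0.020
    max_amount_kg: float = 3.0
    max_rate_kg_min: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.min_duration_s < self.max_duration_s):
            raise ValueError("duration bounds must satisfy 0 < min < max")
        if not (0 < self.min_amount_kg < self.max_amount_kg):
            raise ValueError("amount bounds must satisfy 0 < min < max")
        if self.max_rate_kg_min <= 0:
            raise ValueError("max rate must be positive")


@dataclass(frozen=True)
class PenDayConfig:
    """Bounds for flagging a (pen, day) cell as a malfunctioning feeder.

    Any bound left at None is not applied.  ``max_aberrant_fraction`` is the
    tolerated share of events failing event-level QC; feed bounds are on the
    total dispensed (sum over all events, retained or not).
    """

    max_aberrant_fraction: float | None = 0.2
    min_total_feed_kg: float | None = None
    max_total_feed_kg: float | None = None
    min_event_count: int | None = 1
    max_event_count: int | None = None


def compute_rate(events: pd.DataFrame) -> pd.Series:
    """Consumption rate in kg/min, recomputed from amount and duration."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return events["amount_kg"] / (events["duration_s"] / 60.0)


def filter_events(
    events: pd.DataFrame, thresholds: QcThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen feeding events against logical bounds.

    An event is retained iff all of (strict inequalities):
    ``min_duration < duration < max_duration``,
    ``min_amount < amount < max_amount`` and ``rate < max_rate``.
    Events with non-finite duration or amount are rejected as unparseable
    rather than raising.

    Returns
    -------
    retained, rejections : (DataFrame, DataFrame)
        ``retained`` is the subset of rows passing all rules;
        ``rejections`` has the rejected rows plus a ``reasons`` column
        (semicolon-joined codes among ``unparseable``, ``duration``,
        ``amount``, ``rate``).
    """
    thresholds = thresholds or QcThresholds()
    ev = events.copy()
    dur = pd.to_numeric(ev["duration_s"], errors="coerce")
    amt = pd.to_numeric(ev["amount_kg"], errors="coerce")

    unparseable = ~(np.isfinite(dur) & np.isfinite(amt))
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = amt / (dur / 60.0)

    bad_dur = ~((dur > thresholds.min_duration_s) & (dur < thresholds.max_duration_s))
    bad_amt = ~((amt > thresholds.min_amount_kg) & (amt < thresholds.max_amount_kg))
    bad_rate = ~(rate < thresholds.max_rate_kg_min)

    reason_masks = {
        "unparseable": unparseable,
        "duration": bad_dur & ~unparseable,
        "amount": bad_amt & ~unparseable,
        "rate": bad_rate & ~unparseable,
    }
    rejected_mask = unparseable | bad_dur | bad_amt | bad_rate

    reasons = pd.Series("", index=ev.index, dtype=object)
    for code, mask in reason_masks.items():
        hit = mask & rejected_mask
        reasons[hit] = reasons[hit].where(reasons[hit] == "", reasons[hit] + ";") + code

    retained = ev.loc[~rejected_mask].copy()
    rejections = ev.loc[rejected_mask].copy()
    rejections["reasons"] = reasons[rejected_mask]
    return retained, rejections


def pen_day_flags(
    events: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    config: PenDayConfig | None = None,
    expected: list | None = None,
) -> pd.DataFrame:
    """Flag (pen, day) cells whose feeder statistics indicate malfunction.

    Statistics per cell: number of aberrant events (failing event-level QC),
    total feed dispensed, and total event count.  A cell is flagged if any
    configured bound is violated.  ``expected`` optionally lists (pen, day)
    pairs that should exist; expected cells with zero events are flagged
    ``no data``.  Returns one row per cell with the three statistics, a
    boolean ``flagged`` and the triggering ``reasons``.
    """
    thresholds = thresholds or QcThresholds()
    config = config or PenDayConfig()
    _, rejections = filter_events(events, thresholds)
    aberrant = events.index.isin(rejections.index)

    stats = (
        events.assign(_aberrant=aberrant)
        .groupby(["pen_id", "day"])
        .agg(
            n_events=("amount_kg", "size"),
            n_aberrant=("_aberrant", "sum"),
            total_feed_kg=("amount_kg", "sum"),
        )
        .reset_index()
    )
    if expected is not None:
        seen = set(zip(stats["pen_id"], stats["day"]))
        missing = [cell for cell in expected if cell not in seen]
        if missing:
            empty = pd.DataFrame(missing, columns=["pen_id", "day"])
            empty["n_events"] = 0
            empty["n_aberrant"] = 0
            empty["total_feed_kg"] = 0.0
            stats = pd.concat([stats, empty], ignore_index=True)

    reasons = []
    for row in stats.itertuples(index=False):
        r = []
        if row.n_events == 0:
            r.append("no data")
        else:
            if (
                config.max_aberrant_fraction is not None
                and row.n_aberrant / row.n_events > config.max_aberrant_fraction
            ):
                r.append("aberrant_fraction")
            if config.min_total_feed_kg is not None and row.total_feed_kg < config.min_total_feed_kg:
                r.append("total_feed_low")
            if config.max_total_feed_kg is not None and row.total_feed_kg > config.max_total_feed_kg:
                r.append("total_feed_high")
            if config.min_event_count is not None and row.n_events < config.min_event_count:
                r.append("event_count_low")
            if config.max_event_count is not None and row.n_events > config.max_event_count:
                r.append("event_count_high")
        reasons.append(";".join(r))
    stats["reasons"] = reasons
    stats["flagged"] = stats["reasons"] != ""
    return stats


def daily_intake(retained: pd.DataFrame) -> pd.DataFrame:
    """Sum retained event amounts to one intake record per (animal, day).

    Days with no retained events are simply absent; they are filled later by
    the trajectory adjustment.
    """
    if len(retained) == 0:
        return pd.DataFrame(columns=["animal_id", "day", "intake_kg"])
    out = (
        retained.groupby(["animal_id", "day"], sort=True)["amount_kg"]
        .sum()
        .reset_index()
        .rename(columns={"amount_kg": "intake_kg"})
    )
    return out


@dataclass
class AdjustedIntake:
    """Per-animal adjusted test intake plus bookkeeping."""

    totals: pd.DataFrame  # animal_id, adjusted_intake_kg, n_observed_days
    excluded: list = field(default_factory=list)
    dropped_effects: list = field(default_factory=list)


def adjusted_test_intake(
    daily: pd.DataFrame,
    animal_meta: pd.DataFrame,
    n_days: int,
    degree: int = 3,
) -> AdjustedIntake:
    """Adjusted total feed intake per animal over an ``n_days`` test.

    Fixed effects of gender and group-pen are estimated by least squares on
    the daily records and removed as deviations from their record-weighted
    mean, so that balanced designs leave totals unchanged.  Missing days are
    imputed from a per-animal polynomial in day on test (degree
    ``min(degree, n_observed - 1)``); observed (adjusted) days are kept
    as-is, so complete-data animals get exactly their adjusted raw sum.

    Parameters
    ----------
    daily : DataFrame with columns animal_id, day, intake_kg (days in 1..n_days)
    animal_meta : DataFrame with columns animal_id, gender, group_pen
    n_days : length of test in days
    degree : maximum polynomial degree for the imputation trajectory
    """
    meta = animal_meta.set_index("animal_id")
    df = daily.merge(animal_meta, on="animal_id", how="left")

    # fixed-effect adjustment: record-weighted deviations so that the grand
    # mean of intakes is preserved
    adj = df["intake_kg"].to_numpy(dtype=float).copy()
    dropped: list[str] = []
    effect_cols = [c for c in ("gender", "group_pen") if c in df.columns]
    use_cols = []
    for c in effect_cols:
        if df[c].nunique(dropna=False) < 2:
            dropped.append(c)
            logger.warning("fixed effect %r constant; dropped", c)
        else:
            use_cols.append(c)
    if use_cols:
        X = pd.get_dummies(df[use_cols].astype(str), drop_first=True, dtype=float)
        X.insert(0, "_const", 1.0)
        Xv = X.to_numpy()
        beta, *_ = np.linalg.lstsq(Xv, adj, rcond=None)
        fitted_fx = Xv @ beta
        adj = adj - (fitted_fx - fitted_fx.mean())
    df["intake_adj"] = adj

    days_full = np.arange(1, n_days + 1, dtype=float)
    rows = []
    excluded: list[str] = []
    for animal, grp in df.groupby("animal_id", sort=True):
        obs_days = grp["day"].to_numpy(dtype=float)
        obs_vals = grp["intake_adj"].to_numpy(dtype=float)
        if len(obs_days) == 0:
            excluded.append(animal)
            continue
        missing = np.setdiff1d(days_full, obs_days)
        total = obs_vals.sum()
        if len(missing) > 0:
            deg = int(min(degree, len(obs_days) - 1))
            if deg >= 1:
                coefs = np.polynomial.polynomial.polyfit(obs_days, obs_vals, deg)
                pred = np.polynomial.polynomial.polyval(missing, coefs)
            else:
                pred = np.full(len(missing), obs_vals.mean())
            total += np.clip(pred, 0.0, None).sum()
        rows.append((animal, total, len(obs_days)))

    no_days = set(meta.index) - set(df["animal_id"])
    for a in sorted(no_days):
        excluded.append(a)
        logger.info("animal %s has zero retained days; excluded", a)

    totals = pd.DataFrame(rows, columns=["animal_id", "adjusted_intake_kg", "n_observed_days"])
    return AdjustedIntake(totals=totals, excluded=excluded, dropped_effects=dropped)
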