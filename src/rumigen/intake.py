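"""Feed intake, growth and residual-feed-intake (RFI) trait construction.

Raw inputs are automated-feeder event logs (one row per visit with entry and
exit times and grams eaten) and twice-weekly liveweights over a 42-day test.
From these the module derives daily and mean intake, metabolizable-energy
intake, growth summaries (average daily gain and metabolic mid-weight),
feeding-behavior traits, and the Koch-style RFI residual from

    energy intake = b0 + b1*MMWT + b2*ADG + Flock + Cohort + Pen + e

where the residual e is the RFI trait (negative = eats less than predicted).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

TEST_DAYS = 42  #: length of the main test period, days


def _parse_times(series: pd.Series) -> pd.Series:
    """ISO-8601 timestamps with or without fractional seconds."""
    if pd.api.types.is_datetime64_any_dtype(series):
        return series
    return pd.to_datetime(series, format="ISO8601")


@dataclasses.dataclass(frozen=True)
class FeedSpec:
    """Pellet composition needed to convert grams eaten to energy intake."""

    dm_frac: float  #: dry-matter fraction, 0-1
    me_mj_per_kg_dm: float  #: metabolizable energy, MJ per kg dry matter
    year: str | int | None = None

    def __post_init__(self):
        if not 0.0 < self.dm_frac <= 1.0:
            raise ValueError(f"dm_frac must be in (0, 1], got {self.dm_frac}")
        if self.me_mj_per_kg_dm <= 0:
            raise ValueError("metabolizable energy must be positive")


@dataclasses.dataclass
class GrowthSummary:
    """Daily weight profile over the test with its ADG and MMWT."""

    days: np.ndarray  #: integer day grid, 0..42
    weights: np.ndarray  #: kg, one per day
    adg: float  #: average daily gain, kg/day
    day21_weight: float  #: kg
    mmwt: float  #: metabolic mid-weight, kg^0.75


def daily_intake(
    events: pd.DataFrame,
    n_days: int = TEST_DAYS,
    period_start: pd.Timestamp | str | None = None,
) -> pd.DataFrame:
    """Sum feeder-event grams per animal per day.

    Events are assigned to days by their entry-time date. Days without any
    event yield 0 g (logged); records with negative grams are rejected with
    a log message.

    Returns a wide table (index = animal, columns = day 0..n_days-1, grams).
    """
    ev = events.copy()
    ev["entry"] = _parse_times(ev["entry"] if "entry" in ev else ev["entry_iso8601"])
    bad = ev["grams"].astype(float) < 0
    if bad.any():
        logger.warning("rejecting %d feeder events with negative grams", int(bad.sum()))
        ev = ev[~bad]
    if period_start is None:
        start = ev["entry"].min().normalize() if len(ev) else pd.Timestamp("1970-01-01")
    else:
        start = pd.Timestamp(period_start).normalize()
    ev["day"] = (ev["entry"].dt.normalize() - start).dt.days
    ev = ev[(ev["day"] >= 0) & (ev["day"] < n_days)]
    animals = sorted(events["animal"].astype(str).unique())
    table = (
        ev.assign(animal=ev["animal"].astype(str))
        .groupby(["animal", "day"])["grams"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(index=animals, columns=range(n_days), fill_value=0.0)
    )
    n_zero = int((table.to_numpy() == 0).sum())
    if n_zero:
        logger.warning("%d animal-days with no feeding events (0 g recorded)", n_zero)
    return table.astype(float)


def mean_intake(daily: pd.DataFrame, method: str = "mean") -> pd.Series:
    """Per-animal mean daily intake (g/day) from the daily-intake table.

    ``method="mean"`` is the plain mean of the 42 daily values (zero days
    included). ``method="lsmeans"`` fits the additive two-way model
    intake ~ animal + day and returns day-adjusted animal least-squares
    means — a repeated-measures style adjustment that only differs from
    the plain mean when animal-day cells are missing or unbalanced.
    """
    if method == "mean":
        return daily.mean(axis=1).rename("mean_intake_g_day")
    if method != "lsmeans":
        raise ValueError(f"unknown method {method!r}")
    long = daily.stack().rename("grams").reset_index()
    long.columns = ["animal", "day", "grams"]
    animals = daily.index.tolist()
    days = list(daily.columns)
    a_idx = long["animal"].map({a: i for i, a in enumerate(animals)}).to_numpy()
    d_idx = long["day"].map({d: i for i, d in enumerate(days)}).to_numpy()
    n = len(long)
    from scipy import sparse as sp
    from scipy.sparse.linalg import lsqr

    rows = np.arange(n)
    X = sp.hstack(
        [
            sp.csr_matrix((np.ones(n), (rows, a_idx)), shape=(n, len(animals))),
            # day effects, sum-coded against the last day
            sp.csr_matrix(
                (np.ones(n), (rows, d_idx)), shape=(n, len(days))
            )[:, :-1],
        ]
    ).tocsr()
    sol = lsqr(X, long["grams"].to_numpy(), atol=1e-12, btol=1e-12)[0]
    day_effects = np.append(sol[len(animals) :], 0.0)
    adj = sol[: len(animals)] + day_effects.mean()
    return pd.Series(adj, index=pd.Index(animals, name="animal"), name="mean_intake_g_day")


def energy_intake(mean_daily_grams: float, spec: FeedSpec) -> float:
    """Convert mean grams of pellets/day to MJ ME/day.

    MJ/day = (kg as-fed * dry-matter fraction) * ME (MJ/kg DM). The product
    form reproduces the study-scale means (~2.5 kg/day of 93% DM, 10.9 MJ ME
    pellets -> ~25.3 MJ/day).
    """
    return (mean_daily_grams / 1000.0) * spec.dm_frac * spec.me_mj_per_kg_dm


def metabolic_midweight(day21_kg: float) -> float:
    """Metabolic mid-weight: day-21 liveweight raised to the 0.75 power."""
    if day21_kg <= 0:
        raise ValueError(f"day-21 weight must be positive, got {day21_kg}")
    return float(day21_kg) ** 0.75


def _check_weights(weights: pd.DataFrame | list[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(weights, pd.DataFrame):
        day = weights["day"].to_numpy(dtype=float)
        kg = weights["kg"].to_numpy(dtype=float)
    else:
        arr = np.asarray(weights, dtype=float)
        day, kg = arr[:, 0], arr[:, 1]
    if len(day) < 2:
        raise ValueError("need at least two weighings to model growth")
    order = np.argsort(day)
    return day[order], kg[order]


def interpolate_growth(weights, n_days: int = TEST_DAYS) -> GrowthSummary:
    """Piecewise-linear daily weights from the observed weighings.

    Weights between consecutive weighings follow the segment's daily gain;
    outside the observed span the nearest segment's slope is extrapolated
    (logged). ADG = (day-42 - day-0 weight)/42; MMWT from the day-21 weight.
    """
    day, kg = _check_weights(weights)
    grid = np.arange(n_days + 1, dtype=float)
    w = np.interp(grid, day, kg)
    # extrapolate by edge-segment slope where the grid extends past the data
    if day[0] > 0:
        slope = (kg[1] - kg[0]) / (day[1] - day[0])
        left = grid < day[0]
        w[left] = kg[0] + slope * (grid[left] - day[0])
        logger.info("extrapolating %d leading days by first-segment slope", int(left.sum()))
    if day[-1] < n_days:
        slope = (kg[-1] - kg[-2]) / (day[-1] - day[-2])
        right = grid > day[-1]
        w[right] = kg[-1] + slope * (grid[right] - day[-1])
        logger.info("extrapolating %d trailing days by last-segment slope", int(right.sum()))
    adg = (w[n_days] - w[0]) / n_days
    return GrowthSummary(
        days=grid.astype(int),
        weights=w,
        adg=float(adg),
        day21_weight=float(w[n_days // 2]),
        mmwt=metabolic_midweight(w[n_days // 2]),
    )


def regression_growth(weights, n_days: int = TEST_DAYS) -> GrowthSummary:
    """OLS line through (day, weight); ADG = slope, MMWT from fitted day 21."""
    day, kg = _check_weights(weights)
    slope, intercept = np.polyfit(day, kg, 1)
    grid = np.arange(n_days + 1, dtype=float)
    w = intercept + slope * grid
    day21 = float(intercept + slope * (n_days // 2))
    return GrowthSummary(
        days=grid.astype(int),
        weights=w,
        adg=float(slope),
        day21_weight=day21,
        mmwt=metabolic_midweight(day21),
    )


def feeding_behavior(events: pd.DataFrame, n_days: int = TEST_DAYS) -> pd.DataFrame:
    """Per-animal feeding-behavior traits.

    Returns events/day, mean event duration (s), mean intake per event (g)
    and mean feeding rate (g/s). The rate is the mean of per-event rates
    (rate during each event), not pooled grams over pooled time;
    zero-duration events are excluded from the rate but still counted.
    """
    ev = events.copy()
    ev["animal"] = ev["animal"].astype(str)
    entry = _parse_times(ev["entry"] if "entry" in ev else ev["entry_iso8601"])
    exit_ = _parse_times(ev["exit"] if "exit" in ev else ev["exit_iso8601"])
    ev["duration_s"] = (exit_ - entry).dt.total_seconds()
    if (ev["duration_s"] < 0).any():
        raise ValueError("feeder event with exit before entry")
    ev["grams"] = ev["grams"].astype(float)

    rows = []
    for animal, grp in ev.groupby("animal"):
        timed = grp[grp["duration_s"] > 0]
        if len(timed) < len(grp):
            logger.info(
                "animal %s: %d zero-duration events excluded from rate",
                animal,
                len(grp) - len(timed),
            )
        rate = (timed["grams"] / timed["duration_s"]).mean() if len(timed) else np.nan
        rows.append(
            {
                "animal": animal,
                "events_per_day": len(grp) / n_days,
                "mean_duration_s": grp["duration_s"].mean(),
                "mean_intake_per_event_g": grp["grams"].mean(),
                "mean_rate_g_per_s": rate,
            }
        )
    if not rows:
        logger.warning("empty feeder log: no behavior traits derivable")
        return pd.DataFrame(
            columns=[
                "animal",
                "events_per_day",
                "mean_duration_s",
                "mean_intake_per_event_g",
                "mean_rate_g_per_s",
            ]
        ).set_index("animal")
    return pd.DataFrame(rows).set_index("animal")


@dataclasses.dataclass
class RFIModelFit:
    """OLS fit of the energy-intake model; residuals are the RFI trait."""

    coef: pd.Series  #: estimates for intercept, MMWT, ADG and factor levels
    residuals: pd.Series  #: RFI, MJ/day, indexed by animal
    fitted: pd.Series
    r2: float
    r2_by_cohort: dict[str, float]
    dropped_columns: list[str]
    design_columns: list[str]
    design: np.ndarray


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove rank-deficient columns via pivoted QR (keeps leading columns)."""
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [names[j] for j in sorted(piv[rank:])]
    if dropped:
        logger.warning("dropping aliased design columns: %s", ", ".join(dropped))
    return X[:, keep], [names[j] for j in keep], dropped


def fit_rfi(data: pd.DataFrame) -> RFIModelFit:
    """Fit the RFI model and return residuals as the RFI trait.

    ``data`` needs columns ``animal, energy_intake, mmwt, adg, flock,
    cohort, pen``. Pen is nested within cohort (a cohort:pen factor). The
    fit is OLS with dummy-coded factors; aliased columns are dropped with a
    log message. R-squared is reported overall and per cohort.
    """
    df = data.copy()
    for col in ("animal", "energy_intake", "mmwt", "adg", "flock", "cohort", "pen"):
        if col not in df:
            raise ValueError(f"fit_rfi input lacks column {col!r}")
    df["animal"] = df["animal"].astype(str)
    df["cohort_pen"] = df["cohort"].astype(str) + ":" + df["pen"].astype(str)

    y = df["energy_intake"].to_numpy(dtype=float)
    parts = [np.ones((len(df), 1)), df[["mmwt", "adg"]].to_numpy(dtype=float)]
    names = ["intercept", "mmwt", "adg"]
    for factor in ("flock", "cohort", "cohort_pen"):
        dummies = pd.get_dummies(df[factor].astype(str), prefix=factor, drop_first=True)
        parts.append(dummies.to_numpy(dtype=float))
        names.extend(dummies.columns.tolist())
    X = np.hstack(parts)
    X, names, dropped = _drop_aliased(X, names)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else np.nan
    r2_by_cohort: dict[str, float] = {}
    for cohort, grp in df.groupby(df["cohort"].astype(str)):
        idx = grp.index.to_numpy()
        loc = df.index.get_indexer(idx)
        yc = y[loc]
        rc = resid[loc]
        sst_c = float(np.sum((yc - yc.mean()) ** 2))
        r2_by_cohort[cohort] = 1.0 - float(rc @ rc) / sst_c if sst_c > 0 else np.nan

    return RFIModelFit(
        coef=pd.Series(beta, index=names),
        residuals=pd.Series(resid, index=df["animal"].to_numpy(), name="rfi"),
        fitted=pd.Series(fitted, index=df["animal"].to_numpy(), name="fitted"),
        r2=r2,
        r2_by_cohort=r2_by_cohort,
        dropped_columns=dropped,
        design_columns=names,
        design=X,
    )
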