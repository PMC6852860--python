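"""Derivation of fattening-performance phenotypes from raw weigh and feed records.

Each animal carries a series of dated body weights (weighed on a roughly
monthly cadence) and one dry-matter-intake (DMI) record per day.  Traits are
anchored at target body weights W1..W5 (by default 100/200/300/400/450 kg):

* DTR_Wk - fractional day on which the weight trajectory first crosses Wk,
  found by linear interpolation between the two bracketing weigh records;
* per interval Wa-Wb: FP (fattening period, days), DMI (kg, with boundary
  days pro-rated by fractional coverage), DDMI = DMI/FP, ADWG = (Wb-Wa)/FP
  and FCR = DMI/(Wb-Wa), so that FCR * ADWG = DDMI identically;
* totals over [DTR_W1, last weigh day]: TDMI, TDDMI = TDMI/days,
  TADWG = (FW - W1)/days, TFCR = TDMI/(FW - W1), with FW the last recorded
  weight.

No extrapolation is performed: an animal whose records never reach a target
is excluded from that target's traits (NaN in the table).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeighSeries",
    "FeedSeries",
    "TargetScheme",
    "TargetNotReachedError",
    "TargetBeforeStartError",
    "DegenerateIntervalError",
    "days_to_reach",
    "interval_traits",
    "total_traits",
    "season_at",
    "derive_traits",
    "DEFAULT_TARGETS",
]

DEFAULT_TARGETS = (100.0, 200.0, 300.0, 400.0, 450.0)

SEASONS = ("winter", "spring", "summer", "autumn")


class TargetNotReachedError(ValueError):
    """The target weight lies above the final recorded weight."""


class TargetBeforeStartError(ValueError):
    """The target weight lies below the initial recorded weight."""


class DegenerateIntervalError(ValueError):
    """Two targets are reached on the same (fractional) day."""


@dataclass(frozen=True)
class WeighSeries:
    """Ordered body-weight records (day since fattening start, kg)."""

    animal_id: str
    days: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "weights", weights)
        if days.size < 2:
            raise ValueError(f"animal {self.animal_id}: need at least 2 weigh records")
        if np.any(np.diff(days) <= 0):
            raise ValueError(f"animal {self.animal_id}: weigh days must strictly increase")
        if np.any(weights <= 0):
            raise ValueError(f"animal {self.animal_id}: weights must be positive")


@dataclass(frozen=True)
class FeedSeries:
    """Daily dry-matter-intake records, contiguous over the fattening window."""

    animal_id: str
    days: np.ndarray
    dmi: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        dmi = np.asarray(self.dmi, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "dmi", dmi)
        if days.size and np.any(np.diff(days) != 1):
            raise ValueError(f"animal {self.animal_id}: feed days must be contiguous")
        if np.any(dmi < 0):
            raise ValueError(f"animal {self.animal_id}: DMI must be nonnegative")

    def cumulative_intake(self, t: float) -> float:
        """Integral of the daily-intake step function from the first feed day to t.

        Record on day d covers [d, d+1); a fractional endpoint pro-rates
        that day's intake.
        """
        if self.days.size == 0:
            return 0.0
        start = float(self.days[0])
        t = min(max(t, start), float(self.days[-1]) + 1.0)
        whole = int(np.floor(t - start))
        total = float(self.dmi[:whole].sum())
        if whole < self.dmi.size:
            total += (t - start - whole) * float(self.dmi[whole])
        return total


@dataclass(frozen=True)
class TargetScheme:
    """Ordered target body weights W1..Wk in kg."""

    targets: tuple[float, ...] = DEFAULT_TARGETS

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.targets)
        object.__setattr__(self, "targets", t)
        if any(x <= 0 for x in t):
            raise ValueError("target weights must be positive")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("target weights must strictly increase")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"W{i + 1}" for i in range(len(self.targets)))


def days_to_reach(weights: WeighSeries, target: float) -> float:
    """Fractional day of the first upward crossing of ``target``.

    Linear interpolation between the two records bracketing the crossing;
    an exact hit returns that record's day.  Raises
    :class:`TargetBeforeStartError` if the series starts above the target and
    :class:`TargetNotReachedError` if it never attains it (no extrapolation).
    """
    w = weights.weights
    d = weights.days
    hit = np.nonzero(w >= target)[0]
    if hit.size == 0:
        raise TargetNotReachedError(
            f"animal {weights.animal_id}: target {target} kg above final weight {w[-1]} kg"
        )
    i = int(hit[0])
    if w[i] == target or i == 0:
        if i == 0 and w[0] > target:
            raise TargetBeforeStartError(
                f"animal {weights.animal_id}: target {target} kg below initial weight {w[0]} kg"
            )
        return float(d[i])
    # first upward crossing: records i-1 (below) and i (at or above)
    frac = (target - w[i - 1]) / (w[i] - w[i - 1])
    return float(d[i - 1] + frac * (d[i] - d[i - 1]))


def interval_traits(
    weights: WeighSeries,
    feed: FeedSeries,
    scheme: TargetScheme,
    a: int,
    b: int,
) -> tuple[float, float, float, float, float]:
    """(FP, DMI, DDMI, FCR, ADWG) for the interval between targets a and b.

    Indices are 0-based into ``scheme.targets``.  The gain denominator is the
    target-weight difference (exactly Wb - Wa), per the trait definitions.
    """
    wa, wb = scheme.targets[a], scheme.targets[b]
    ta = days_to_reach(weights, wa)
    tb = days_to_reach(weights, wb)
    fp = tb - ta
    if fp <= 0:
        raise DegenerateIntervalError(
            f"animal {weights.animal_id}: interval {wa}-{wb} kg has zero length"
        )
    dmi = feed.cumulative_intake(tb) - feed.cumulative_intake(ta)
    gain = wb - wa
    return fp, dmi, dmi / fp, dmi / gain, gain / fp


def total_traits(
    weights: WeighSeries, feed: FeedSeries, scheme: TargetScheme
) -> tuple[float, float, float, float, float, float]:
    """(FW, total FP, TDMI, TDDMI, TFCR, TADWG) over [DTR_W1, last weigh day]."""
    w1 = scheme.targets[0]
    t1 = days_to_reach(weights, w1)
    t_end = float(weights.days[-1])
    fw = float(weights.weights[-1])
    days = t_end - t1
    if days <= 0:
        raise DegenerateIntervalError(
            f"animal {weights.animal_id}: no fattening window beyond {w1} kg"
        )
    tdmi = feed.cumulative_intake(t_end) - feed.cumulative_intake(t1)
    gain = fw - w1
    if gain <= 0:
        raise DegenerateIntervalError(
            f"animal {weights.animal_id}: final weight {fw} kg not above W1 {w1} kg"
        )
    return fw, days, tdmi, tdmi / days, tdmi / gain, gain / days


def season_at(start_date: date, day: float) -> str:
    """Meteorological season of ``start_date + day``.

    Dec-Feb winter, Mar-May spring, Jun-Aug summer, Sep-Nov autumn.
    """
    when = start_date + timedelta(days=float(day))
    m = when.month
    if m in (12, 1, 2):
        return "winter"
    if m in (3, 4, 5):
        return "spring"
    if m in (6, 7, 8):
        return "summer"
    return "autumn"


def _interval_label(scheme: TargetScheme, a: int, b: int) -> str:
    return f"W{a + 1}-W{b + 1}"


def derive_traits(
    weights_df: pd.DataFrame,
    feed_df: pd.DataFrame,
    animals_df: pd.DataFrame,
    scheme: TargetScheme | None = None,
) -> pd.DataFrame:
    """Per-animal trait table from the raw herd CSV tables.

    Parameters
    ----------
    weights_df
        Columns animal_id, day, weight_kg.
    feed_df
        Columns animal_id, day, dmi_kg.
    animals_df
        Columns animal_id, start_date (ISO-8601), optionally
        age_at_start_days (defaults to 0, making 'age' days-on-feed).

    Returns
    -------
    One row per animal with DTRWk, per-interval FP/DMI/DDMI/FCR/ADWG,
    FW/TDMI/TDDMI/TFCR/TADWG, plus the season and age covariate columns
    (season_at_Wk / age_at_Wk and season/age at the final weighing) used by
    the association stage.  Targets an animal never reached yield NaN in
    every trait anchored on them.
    """
    scheme = scheme or TargetScheme()
    k = len(scheme.targets)
    animals = animals_df.set_index(animals_df["animal_id"].astype(str))
    has_age = "age_at_start_days" in animals.columns

    w_groups = {str(aid): g for aid, g in weights_df.groupby("animal_id")}
    f_groups = {str(aid): g for aid, g in feed_df.groupby("animal_id")}

    rows = []
    for aid in animals.index:
        rec: dict[str, object] = {"animal_id": aid}
        wg = w_groups.get(aid)
        fg = f_groups.get(aid)
        if wg is None or len(wg) < 2:
            continue
        wg = wg.sort_values("day")
        ws = WeighSeries(aid, wg["day"].to_numpy(), wg["weight_kg"].to_numpy())
        if fg is not None and len(fg):
            fg = fg.sort_values("day")
            fs = FeedSeries(aid, fg["day"].to_numpy(), fg["dmi_kg"].to_numpy())
        else:
            fs = FeedSeries(aid, np.array([], dtype=int), np.array([], dtype=float))
        start = date.fromisoformat(str(animals.loc[aid, "start_date"]))
        age0 = float(animals.loc[aid, "age_at_start_days"]) if has_age else 0.0

        dtr: list[float] = []
        for i, target in enumerate(scheme.targets):
            label = scheme.labels[i]
            try:
                t = days_to_reach(ws, target)
            except (TargetNotReachedError, TargetBeforeStartError):
                t = np.nan
            dtr.append(t)
            rec[f"DTR{label}"] = t
            rec[f"season_at_{label}"] = season_at(start, t) if np.isfinite(t) else None
            rec[f"age_at_{label}"] = age0 + t if np.isfinite(t) else np.nan

        for a, b in zip(range(k - 1), range(1, k)):
            label = _interval_label(scheme, a, b)
            if np.isfinite(dtr[a]) and np.isfinite(dtr[b]):
                fp, dmi, ddmi, fcr, adwg = interval_traits(ws, fs, scheme, a, b)
            else:
                fp = dmi = ddmi = fcr = adwg = np.nan
            rec[f"{label} FP"] = fp
            rec[f"{label} DMI"] = dmi
            rec[f"{label} DDMI"] = ddmi
            rec[f"{label} FCR"] = fcr
            rec[f"{label} ADWG"] = adwg

        if np.isfinite(dtr[0]):
            fw, days, tdmi, tddmi, tfcr, tadwg = total_traits(ws, fs, scheme)
        else:
            fw = float(ws.weights[-1])
            days = tdmi = tddmi = tfcr = tadwg = np.nan
        rec["FW"] = fw
        rec["total FP"] = days
        rec["TDMI"] = tdmi
        rec["TDDMI"] = tddmi
        rec["TFCR"] = tfcr
        rec["TADWG"] = tadwg
        final_day = float(ws.days[-1])
        rec["season_at_final"] = season_at(start, final_day)
        rec["age_at_final"] = age0 + final_day
        rows.append(rec)
    return pd.DataFrame(rows)


def covariate_columns_for(trait: str) -> tuple[str, str]:
    """(age column, season column) anchoring the model covariates for a trait.

    DTR traits anchor at their own target; interval traits at the interval
    end; totals and FW at the final weighing.
    """
    if trait.startswith("DTR"):
        label = trait[3:]
        return f"age_at_{label}", f"season_at_{label}"
    if trait[0] == "W" and "-" in trait.split(" ")[0]:
        end = trait.split(" ")[0].split("-")[1]
        return f"age_at_{end}", f"season_at_{end}"
    return "age_at_final", "season_at_final"
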