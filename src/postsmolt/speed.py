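"""Migration speed between receiver arrays and its linear model.

Speed is minimum travel distance by water divided by the time elapsed
between first detections at two arrays (km/h). The default segment runs
from the marine-inlet exit array to the coastal array. Speeds are
modelled with a Gaussian linear model fitted by maximum likelihood with
year, river and marine-entry day of year (plus pairwise interactions) as
candidate terms, assessed by likelihood-ratio tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


def compute_speeds(
    arrivals: pd.DataFrame,
    distances_km: pd.DataFrame,
    segments: dict[str, tuple[str, str]],
    marine_entry_array: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-fish migration speed over a river-specific array segment.

    Parameters
    ----------
    arrivals
        Output of :func:`postsmolt.timing.arrival_table`.
    distances_km
        Symmetric by-water distance matrix (labels = array ids).
    segments
        Mapping river -> (from_array, to_array); fish are skipped unless
        detected at both.
    marine_entry_array
        Mapping river -> array whose first detection defines the marine
        entry day (defaults to the segment's from_array).

    Returns one row per qualifying fish with distance, elapsed hours,
    speed (km/h) and marine entry day; non-positive elapsed times are
    rejected with a log entry.
    """
    rows = []
    piv = arrivals.set_index(["tag_id", "array_id"])
    for (tag, river, year), grp in arrivals.groupby(["tag_id", "river", "year"]):
        if river not in segments:
            continue
        a, b = segments[river]
        have = set(grp["array_id"])
        if a not in have or b not in have:
            continue
        t0 = piv.loc[(tag, a), "arrival_time"]
        t1 = piv.loc[(tag, b), "arrival_time"]
        hours = (t1 - t0).total_seconds() / 3600.0
        if hours <= 0:
            logger.info("tag %s: non-positive elapsed time %s -> %s", tag, a, b)
            continue
        d = float(distances_km.loc[a, b])
        if not np.isfinite(d):
            continue
        entry_arr = (marine_entry_array or {}).get(river, a)
        if entry_arr in have:
            entry_day = int(piv.loc[(tag, entry_arr), "arrival_day"])
        else:
            entry_day = int(piv.loc[(tag, a), "arrival_day"])
        rows.append({"tag_id": tag, "river": river, "year": int(year),
                     "from_array": a, "to_array": b, "distance_km": d,
                     "elapsed_h": hours, "speed_kmh": d / hours,
                     "marine_entry_day": entry_day})
    return pd.DataFrame(rows, columns=[
        "tag_id", "river", "year", "from_array", "to_array", "distance_km",
        "elapsed_h", "speed_kmh", "marine_entry_day"])


FULL_TERMS = ("C(year)", "C(river)", "entry_day",
              "C(year):C(river)", "C(year):entry_day", "C(river):entry_day")


def _ols_ml(formula: str, data: pd.DataFrame):
    res = sm.OLS.from_formula(formula, data).fit()
    # Gaussian ML log-likelihood (statsmodels OLS llf is already the ML value)
    return res


def _formula(terms) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"speed_kmh ~ {rhs}"


@dataclass
class SpeedModel:
    terms: tuple[str, ...]
    result: object = field(repr=False, default=None)
    lrt_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    river_means: pd.DataFrame = field(default_factory=pd.DataFrame)


def lrt(full_res, reduced_res) -> tuple[float, int, float]:
    stat = max(2.0 * (full_res.llf - reduced_res.llf), 0.0)
    df = int(full_res.df_model - reduced_res.df_model)
    return float(stat), df, float(stats.chi2.sf(stat, max(df, 1)))


def _droppable(terms):
    """Terms whose removal respects marginality (no retained interaction uses them)."""
    out = []
    for t in terms:
        if ":" in t:
            out.append(t)
        else:
            if not any(":" in u and t in u.split(":") for u in terms):
                out.append(t)
    return out


def fit_speed_model(
    speeds: pd.DataFrame,
    alpha: float = 0.05,
    backward: bool = True,
) -> SpeedModel:
    """Fit the speed model and assess terms by likelihood-ratio tests.

    With ``backward=True``, terms are eliminated one at a time (respecting
    marginality, largest p first) while their LRT p-value exceeds
    ``alpha``; every test is recorded. Per-river predicted mean speeds
    with 95% confidence intervals are computed from the final model.
    """
    data = speeds.rename(columns={"marine_entry_day": "entry_day"}).copy()
    if data["river"].nunique() < 2:
        raise ValueError("need at least 2 rivers to estimate a river effect")
    data["entry_day"] = data["entry_day"] - data["entry_day"].mean()

    terms = [t for t in FULL_TERMS]
    if data["year"].nunique() < 2:
        terms = [t for t in terms if "C(year)" not in t]
    trail = []
    current = _ols_ml(_formula(terms), data)
    while backward and terms:
        tests = []
        for t in _droppable(terms):
            reduced_terms = [u for u in terms if u != t]
            red = _ols_ml(_formula(reduced_terms), data)
            stat, df, p = lrt(current, red)
            tests.append((t, stat, df, p, red, reduced_terms))
        tests.sort(key=lambda r: -r[3])
        t, stat, df, p, red, reduced_terms = tests[0]
        trail.append({"dropped": t, "chi2": stat, "df": df, "p": p,
                      "removed": p > alpha})
        if p > alpha:
            terms, current = reduced_terms, red
        else:
            break
    # final-model term tests (single-term deletions from the final model)
    final_tests = []
    for t in _droppable(terms):
        red = _ols_ml(_formula([u for u in terms if u != t]), data)
        stat, df, p = lrt(current, red)
        final_tests.append({"term": t, "chi2": stat, "df": df, "p": p})
    lrt_table = pd.DataFrame(trail + [{"dropped": None, **ft}
                                      for ft in final_tests]) \
        if (trail or final_tests) else pd.DataFrame()

    # predicted per-river means at entry_day = 0 (sample mean), averaged
    # over the observed year mix
    rows = []
    for river in sorted(data["river"].unique()):
        grid = data[["year"]].drop_duplicates().assign(
            river=river, entry_day=0.0)
        pred = current.get_prediction(grid).summary_frame(alpha=0.05)
        rows.append({"river": river,
                     "mean_speed_kmh": float(pred["mean"].mean()),
                     "lcl": float(pred["mean_ci_lower"].mean()),
                     "ucl": float(pred["mean_ci_upper"].mean())})
    return SpeedModel(terms=tuple(terms), result=current,
                      lrt_table=lrt_table, river_means=pd.DataFrame(rows))


def river_effect_lrt(speeds: pd.DataFrame) -> dict:
    """LRT for the river main effect in the main-effects speed model."""
    data = speeds.rename(columns={"marine_entry_day": "entry_day"}).copy()
    data["entry_day"] = data["entry_day"] - data["entry_day"].mean()
    base_terms = ["entry_day"]
    if data["year"].nunique() > 1:
        base_terms = ["C(year)"] + base_terms
    full = _ols_ml(_formula(base_terms + ["C(river)"]), data)
    red = _ols_ml(_formula(base_terms), data)
    stat, df, p = lrt(full, red)
    return {"chi2": stat, "df": df, "p": p}
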