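"""Migration timing: arrival days, mixed model and migration windows.

The arrival day of a fish at an array is the day of year of its first
detection there. Arrival days are modelled with a linear mixed-effects
model fitted by maximum likelihood:

    arrival_day ~ year * river + (1 | array) + (1 | tag)

with crossed random intercepts for receiver array and individual fish
(every fish can appear at every array). 95% prediction intervals per
array x river x year combination are obtained by simulation from the
fitted model, propagating fixed-effect uncertainty, both random-intercept
variances and the residual variance. The migration window of a river-year
spans from the smallest lower to the largest upper interval limit over its
arrays.
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


def arrival_table(
    cleaned: pd.DataFrame,
    receivers: pd.DataFrame,
    deployments: pd.DataFrame,
) -> pd.DataFrame:
    """First-detection day of year per tag x array.

    Columns: ``tag_id, array_id, river, year, arrival_day, arrival_time``.
    Arrival day is the integer (floored) day of year of the first detection.
    A detection earlier than the tag's release time is an error.
    """
    df = cleaned.merge(receivers[["receiver_id", "array_id"]], on="receiver_id")
    df = df.merge(
        deployments[["tag_id", "river", "year", "release_time"]], on="tag_id")
    if (df["timestamp"] < df["release_time"]).any():
        bad = df[df["timestamp"] < df["release_time"]]["tag_id"].unique()
        raise ValueError(f"detections before release time for tags {bad[:5]}")
    firsts = (df.sort_values("timestamp")
                .groupby(["tag_id", "array_id"], as_index=False)
                .first())
    firsts["arrival_day"] = firsts["timestamp"].dt.dayofyear.astype(int)
    firsts["year"] = firsts["year"].astype(int)
    out = firsts[["tag_id", "array_id", "river", "year", "arrival_day",
                  "timestamp"]].rename(columns={"timestamp": "arrival_time"})
    return out.reset_index(drop=True)


@dataclass
class TimingFit:
    fixed_effects: pd.DataFrame       # term, estimate, se
    var_array: float
    var_tag: float
    var_resid: float
    loglik: float
    r2_marginal: float
    r2_conditional: float
    singular: bool
    result: object = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)
    formula: str = "arrival_day ~ C(year) * C(river)"


def fit_timing_lmm(arrivals: pd.DataFrame,
                   formula: str = "arrival_day ~ C(year) * C(river)") -> TimingFit:
    """ML fit of the crossed random-intercept arrival-day model.

    Implemented as a single-group mixed model with two variance components
    (array and tag indicator blocks), which realises crossed random
    intercepts. A variance component estimated at (numerical) zero flags
    the fit as singular but the fit is retained.
    """
    if arrivals["river"].nunique() < 2 or arrivals["array_id"].nunique() < 2:
        raise ValueError("need at least 2 rivers and 2 arrays")
    data = arrivals.copy().reset_index(drop=True)
    data["_group"] = 1
    vc = {"array": "0 + C(array_id)", "tag": "0 + C(tag_id)"}
    model = sm.MixedLM.from_formula(
        formula, groups="_group", vc_formula=vc, re_formula="0", data=data)
    result = model.fit(reml=False, method="lbfgs", maxiter=500)

    vcomp = dict(zip(model.exog_vc.names, result.vcomp))
    var_array = float(vcomp.get("array", 0.0))
    var_tag = float(vcomp.get("tag", 0.0))
    var_resid = float(result.scale)
    singular = min(var_array, var_tag) < 1e-6 * max(var_resid, 1e-12)
    if singular:
        logger.warning("singular variance component estimate (near zero)")

    fe = pd.DataFrame({"term": result.fe_params.index,
                       "estimate": result.fe_params.values,
                       "se": result.bse_fe.values})
    # variance-partition R2: fixed-effect variance over total
    X = patsy.dmatrix(formula.split("~", 1)[1], data, return_type="dataframe")
    fitted_fixed = X.to_numpy() @ result.fe_params.values
    var_fixed = float(np.var(fitted_fixed, ddof=0))
    total = var_fixed + var_array + var_tag + var_resid
    r2m = var_fixed / total
    r2c = (var_fixed + var_array + var_tag) / total
    return TimingFit(fixed_effects=fe, var_array=var_array, var_tag=var_tag,
                     var_resid=var_resid, loglik=float(result.llf),
                     r2_marginal=r2m, r2_conditional=r2c,
                     singular=singular, result=result, data=data,
                     formula=formula)


def lrt_interaction(arrivals: pd.DataFrame) -> dict:
    """Likelihood-ratio test of the year x river interaction (ML fits)."""
    full = fit_timing_lmm(arrivals, "arrival_day ~ C(year) * C(river)")
    reduced = fit_timing_lmm(arrivals, "arrival_day ~ C(year) + C(river)")
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    df = len(full.fixed_effects) - len(reduced.fixed_effects)
    p = float(stats.chi2.sf(stat, df))
    return {"chi2": float(stat), "df": int(df), "p": p}


def prediction_intervals(
    fit: TimingFit,
    n_sim: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulation-based prediction intervals per array x river x year.

    For each combination observed in the data, new observations are drawn
    as fixed-effect draws (from the estimated sampling distribution) plus
    the array's conditional random intercept draw, a fresh individual
    intercept and residual noise; the interval is the (2.5, 97.5)%
    quantile band at the default level.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    result = fit.result
    data = fit.data
    fe = result.fe_params.values
    cov_fe = np.asarray(result.cov_params())[:len(fe), :len(fe)]
    # conditional means of the array intercepts
    re = result.random_effects[1]
    array_blup = {}
    for name, val in re.items():
        if name.startswith("array["):
            lab = name[len("array[C(array_id)["):-2]
            array_blup[lab] = float(val)

    combos = (data[["array_id", "river", "year"]]
              .drop_duplicates().reset_index(drop=True))
    X = patsy.dmatrix(fit.formula.split("~", 1)[1],
                      combos.assign(arrival_day=0.0), return_type="dataframe")
    Xm = X.to_numpy()

    beta_draws = rng.multivariate_normal(fe, cov_fe, size=n_sim)
    alpha = (1.0 - level) / 2.0
    rows = []
    sd_arr = np.sqrt(fit.var_array)
    sd_tag = np.sqrt(fit.var_tag)
    sd_res = np.sqrt(fit.var_resid)
    for k in range(len(combos)):
        mu = beta_draws @ Xm[k]
        b_arr = array_blup.get(str(combos.loc[k, "array_id"]), 0.0)
        sims = (mu + b_arr
                + rng.normal(0.0, sd_tag, n_sim)
                + rng.normal(0.0, sd_res, n_sim))
        lo, hi = np.quantile(sims, [alpha, 1.0 - alpha])
        rows.append({"array_id": combos.loc[k, "array_id"],
                     "river": combos.loc[k, "river"],
                     "year": int(combos.loc[k, "year"]),
                     "fit": float(np.mean(mu) + b_arr),
                     "lower": float(lo), "upper": float(hi)})
    return pd.DataFrame(rows)


def migration_windows(intervals: pd.DataFrame) -> pd.DataFrame:
    """Migration window per river x year: min lower to max upper over arrays."""
    rows = []
    for (river, year), grp in intervals.groupby(["river", "year"]):
        lower = float(grp["lower"].min())
        upper = float(grp["upper"].max())
        rows.append({"river": river, "year": int(year),
                     "lower_day": lower, "upper_day": upper,
                     "duration_days": upper - lower})
    out = pd.DataFrame(rows)
    return out.sort_values(["river", "year"]).reset_index(drop=True)


def window_overlap(windows: pd.DataFrame) -> tuple[float, float] | None:
    """Interval common to every river-year window, or None if empty."""
    lo = float(windows["lower_day"].max())
    hi = float(windows["upper_day"].min())
    return (lo, hi) if lo <= hi else None
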