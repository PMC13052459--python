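"""Passage points across a ranked receiver array and their beta regression.

The receiver first detecting a fish at an array is its passage point,
expressed as the receiver's south-to-north rank (1..b). Ranks are mapped
to the open unit interval in two steps,

    y' = (y - a) / (b - a)
    y'' = (y' (n - 1) + 0.5) / n

with a, b the minimum and maximum possible rank and n the sample size, so
that y'' never touches 0 or 1. The scaled passage point is modelled with
a variable-dispersion beta regression: location mu (logit link) and
precision tau (log link), density Beta(mu * tau, (1 - mu) * tau), each
parameter a function of year, river, arrival day of year and their
pairwise interactions, reduced by backward likelihood-ratio tests.

Corridor widths are the central 50% and 90% quantile bands of the
predicted beta distribution mapped back to receiver ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from statsmodels.othermod.betareg import BetaModel

logger = logging.getLogger(__name__)

SMALL_GROUP_WARN = 5


# ---------------------------------------------------------------------------
# rank scaling
# ---------------------------------------------------------------------------

def scale_rank(y, a: int = 1, b: int = 127, n: int = 1):
    """Map receiver rank(s) y in [a, b] to the open unit interval."""
    y = np.asarray(y, dtype=float)
    if a >= b:
        raise ValueError("need a < b")
    if n < 1:
        raise ValueError("n must be at least 1")
    if np.any((y < a) | (y > b)):
        raise ValueError(f"rank outside [{a}, {b}]")
    yp = (y - a) / (b - a)
    ypp = (yp * (n - 1) + 0.5) / n
    return ypp if ypp.shape else float(ypp)


def unscale(ypp, a: int = 1, b: int = 127, n: int = 1):
    """Invert :func:`scale_rank` and round to the nearest rank in [a, b]."""
    ypp = np.asarray(ypp, dtype=float)
    if np.any((ypp <= 0) | (ypp >= 1)):
        raise ValueError("scaled value must lie strictly inside (0, 1)")
    yp = (ypp * n - 0.5) / (n - 1) if n > 1 else np.full_like(ypp, 0.5)
    y = np.clip(np.rint(yp * (b - a) + a), a, b).astype(int)
    return y if y.shape else int(y)


def passage_points(
    arrivals: pd.DataFrame,
    receivers: pd.DataFrame,
    cleaned: pd.DataFrame,
    array_id: str,
) -> pd.DataFrame:
    """Passage point (first-detection receiver rank) per fish at one array."""
    recs = receivers[receivers["array_id"] == array_id]
    det = cleaned[cleaned["receiver_id"].isin(recs["receiver_id"])]
    first = (det.sort_values("timestamp")
                .groupby("tag_id", as_index=False).first())
    first = first.merge(recs[["receiver_id", "rank"]], on="receiver_id")
    meta = arrivals[arrivals["array_id"] == array_id][
        ["tag_id", "river", "year", "arrival_day"]]
    out = first.merge(meta, on="tag_id")
    out["array_id"] = array_id
    return out[["tag_id", "array_id", "rank", "river", "year",
                "arrival_day"]].reset_index(drop=True)


def empirical_corridor(points: pd.DataFrame) -> pd.DataFrame:
    """Median, quartile and 5/95% passage ranks per river x year x array.

    Quantiles use linear interpolation and are rounded to the nearest
    integer rank.
    """
    rows = []
    for (river, year, arr), grp in points.groupby(["river", "year", "array_id"]):
        q = np.quantile(grp["rank"].to_numpy(dtype=float),
                        [0.05, 0.25, 0.5, 0.75, 0.95])
        rows.append({"river": river, "year": int(year), "array_id": arr,
                     "n": len(grp),
                     "q05": int(np.rint(q[0])), "q25": int(np.rint(q[1])),
                     "median": int(np.rint(q[2])),
                     "q75": int(np.rint(q[3])), "q95": int(np.rint(q[4]))})
        if len(grp) < SMALL_GROUP_WARN:
            logger.warning("only %d fish for %s %s at %s: summaries unstable",
                           len(grp), river, year, arr)
    return pd.DataFrame(rows).sort_values(
        ["array_id", "river", "year"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# variable-dispersion beta regression
# ---------------------------------------------------------------------------

def betareg_loglik(
    y: np.ndarray, mu: np.ndarray, tau: np.ndarray
) -> float:
    """Beta log-likelihood with shapes (mu tau, (1 - mu) tau)."""
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("responses must lie strictly inside (0, 1)")
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    tau = np.broadcast_to(np.asarray(tau, dtype=float), y.shape)
    return float(np.sum(stats.beta.logpdf(y, mu * tau, (1.0 - mu) * tau)))


_MU_TERMS = ("C(year)", "C(river)", "arrival_c",
             "C(year):C(river)", "C(year):arrival_c", "C(river):arrival_c")
_TAU_TERMS = _MU_TERMS


@dataclass
class BetaRegFit:
    mu_terms: tuple[str, ...]
    tau_terms: tuple[str, ...]
    loglik: float
    K: int
    converged: bool
    result: object = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)
    arrival_mean: float = 0.0

    def predict(self, newdata: pd.DataFrame) -> pd.DataFrame:
        """Predicted (mu, tau) for new rows with river, year, arrival_day."""
        nd = newdata.copy()
        nd["arrival_c"] = nd["arrival_day"] - self.arrival_mean
        Xm = patsy.build_design_matrices(
            [self._mu_design_info], nd, return_type="dataframe")[0].to_numpy()
        Xt = patsy.build_design_matrices(
            [self._tau_design_info], nd, return_type="dataframe")[0].to_numpy()
        k = Xm.shape[1]
        beta = self.result.params[:k]
        gamma = self.result.params[k:]
        from scipy.special import expit
        mu = expit(Xm @ beta)
        tau = np.exp(Xt @ gamma)
        out = nd.copy()
        out["mu"] = mu
        out["tau"] = tau
        return out

    _mu_design_info: object = field(repr=False, default=None)
    _tau_design_info: object = field(repr=False, default=None)


def _design(terms, data):
    rhs = " + ".join(terms) if terms else "1"
    return patsy.dmatrix(rhs, data, return_type="dataframe")


def fit_betareg(
    data: pd.DataFrame,
    mu_terms=_MU_TERMS,
    tau_terms=_TAU_TERMS,
) -> BetaRegFit:
    """ML fit of the variable-dispersion beta regression.

    ``data`` needs columns ``y`` (the scaled passage point), ``river``,
    ``year`` and ``arrival_day``; the arrival-day covariate is centred at
    its sample mean before fitting. Terms whose factor has a single level
    are dropped automatically.
    """
    df = data.copy()
    mean_day = float(df["arrival_day"].mean())
    df["arrival_c"] = df["arrival_day"] - mean_day

    def usable(term):
        if "C(year)" in term and df["year"].nunique() < 2:
            return False
        if "C(river)" in term and df["river"].nunique() < 2:
            return False
        return True

    mu_terms = tuple(t for t in mu_terms if usable(t))
    tau_terms = tuple(t for t in tau_terms if usable(t))
    Xm = _design(mu_terms, df)
    Xt = _design(tau_terms, df)
    if np.linalg.matrix_rank(Xm.to_numpy()) < Xm.shape[1]:
        raise ValueError("mean design is rank deficient")
    # defaults: logit link for the mean, log link for the precision
    model = BetaModel(df["y"].to_numpy(), Xm, exog_precision=Xt)
    res = model.fit(maxiter=2000, disp=False)
    if not res.mle_retvals.get("converged", True):
        res = model.fit(start_params=res.params, method="bfgs",
                        maxiter=2000, disp=False)
    fit = BetaRegFit(
        mu_terms=mu_terms, tau_terms=tau_terms,
        loglik=float(res.llf), K=len(res.params),
        converged=bool(res.mle_retvals.get("converged", True)),
        result=res, data=df, arrival_mean=mean_day)
    fit._mu_design_info = Xm.design_info
    fit._tau_design_info = Xt.design_info
    if not fit.converged:
        logger.warning("beta regression did not converge: mu ~ %s",
                       " + ".join(mu_terms) or "1")
    return fit


def lrt_betareg(full: BetaRegFit, reduced: BetaRegFit) -> dict:
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    df = full.K - reduced.K
    return {"chi2": float(stat), "df": int(df),
            "p": float(stats.chi2.sf(stat, max(df, 1)))}


def _droppable(terms):
    out = []
    for t in terms:
        if ":" in t:
            out.append(t)
        elif not any(":" in u and t in u.split(":") for u in terms):
            out.append(t)
    return out


def backward_select(
    data: pd.DataFrame,
    mu_terms=_MU_TERMS,
    tau_terms=_TAU_TERMS,
    alpha: float = 0.05,
) -> tuple[BetaRegFit, pd.DataFrame]:
    """Backward LRT elimination over both submodels, respecting marginality.

    At each step the droppable term (from either submodel) with the
    largest LRT p-value above ``alpha`` is removed; the trail records every
    test. Returns the final fit and the trail.
    """
    full = fit_betareg(data, mu_terms, tau_terms)
    trail = []
    current = full
    while True:
        candidates = ([("mu", t) for t in _droppable(current.mu_terms)]
                      + [("tau", t) for t in _droppable(current.tau_terms)])
        if not candidates:
            break
        tests = []
        for sub, t in candidates:
            mu_t = tuple(u for u in current.mu_terms if not (sub == "mu" and u == t))
            tau_t = tuple(u for u in current.tau_terms if not (sub == "tau" and u == t))
            try:
                red = fit_betareg(data, mu_t, tau_t)
            except Exception:  # pragma: no cover - rank issues in reduced fits
                continue
            res = lrt_betareg(current, red)
            tests.append((sub, t, res, red))
        if not tests:
            break
        tests.sort(key=lambda r: -r[2]["p"])
        sub, t, res, red = tests[0]
        trail.append({"submodel": sub, "term": t, **res,
                      "removed": res["p"] > alpha})
        if res["p"] > alpha:
            current = red
        else:
            break
    return current, pd.DataFrame(trail)


def corridor_bounds(
    mu: float, tau: float,
    a: int = 1, b: int = 127, n: int = 1,
    levels=(0.5, 0.9),
) -> dict[float, tuple[int, int]]:
    """Central quantile bands of Beta(mu tau, (1-mu) tau) as receiver ranks."""
    out = {}
    for lev in levels:
        alpha = (1.0 - lev) / 2.0
        lo, hi = stats.beta.ppf([alpha, 1.0 - alpha],
                                mu * tau, (1.0 - mu) * tau)
        lo = min(max(lo, 1e-12), 1 - 1e-12)
        hi = min(max(hi, 1e-12), 1 - 1e-12)
        out[lev] = (unscale(lo, a, b, n), unscale(hi, a, b, n))
    return out


def model_corridors(
    fit: BetaRegFit,
    a: int = 1, b: int = 127, n: int | None = None,
) -> pd.DataFrame:
    """Model-predicted 50% and 90% corridor rank bounds per river x year.

    Predictions are made at the mean arrival day of each river x year
    group; ``n`` defaults to the number of observations in the fit.
    """
    n = n if n is not None else len(fit.data)
    grid = (fit.data.groupby(["river", "year"], as_index=False)
            ["arrival_day"].mean())
    pred = fit.predict(grid)
    rows = []
    for _, r in pred.iterrows():
        bounds = corridor_bounds(r["mu"], r["tau"], a, b, n)
        med = unscale(float(stats.beta.ppf(0.5, r["mu"] * r["tau"],
                                           (1 - r["mu"]) * r["tau"])), a, b, n)
        rows.append({"river": r["river"], "year": int(r["year"]),
                     "mu": float(r["mu"]), "tau": float(r["tau"]),
                     "median_rank": med,
                     "lo50": bounds[0.5][0], "hi50": bounds[0.5][1],
                     "lo90": bounds[0.9][0], "hi90": bounds[0.9][1]})
    return pd.DataFrame(rows).sort_values(["river", "year"]).reset_index(drop=True)
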