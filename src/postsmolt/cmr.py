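"""Distance-scaled Cormack-Jolly-Seber survival estimation.

Tagged fish are released in their natal river and re-detected (or not) at a
fixed sequence of receiver arrays. Each fish contributes a binary encounter
history over the ordered occasions; the CJS product-multinomial likelihood
separates migration success from array detection efficiency.

Migration success is expressed as a *per-kilometre* rate ``s``: the
probability of completing a segment of length ``d`` km is ``s**d``, so
``s = 0.9`` means a 90% probability of migrating 1 km. ``s`` lives on a
logit link with optional habitat and year covariates; detection efficiency
``p`` lives on a logit link with optional array and year covariates.
Freshwater passage survival is fixed to 1 (every fish in a model entered
the study alive at the freshwater receiver) and detection at the final
array is fixed to 1 (beyond it only the product of survival and detection
is identifiable).

Overdispersion is handled by a parametric-bootstrap ``c-hat`` (mean of
three resampling estimators), information criteria by AICc/QAICc, and
inference by model averaging over all candidate models within
``delta <= 13.044`` of the best.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

DELTA_MAX_DEFAULT = 13.044
Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class PathwayGroup:
    """One expected migration pathway: ordered occasions with distances.

    ``occasions[0]`` is the river (release/entry) receiver; subsequent
    occasions are the arrays the pathway crosses. ``habitats[t]`` and
    ``distances_km[t]`` describe the transition from occasion ``t`` to
    ``t + 1``. Freshwater transitions carry fixed survival 1.
    """

    name: str
    rivers: tuple[str, ...]
    occasions: tuple[str, ...]
    habitats: tuple[str, ...]
    distances_km: tuple[float, ...]

    def __post_init__(self):
        self.rivers = tuple(self.rivers)
        self.occasions = tuple(self.occasions)
        self.habitats = tuple(self.habitats)
        self.distances_km = tuple(float(d) for d in self.distances_km)
        T = len(self.occasions)
        if T < 2:
            raise ValueError("a pathway needs at least 2 occasions")
        if len(self.habitats) != T - 1 or len(self.distances_km) != T - 1:
            raise ValueError("need one habitat and distance per transition")
        if any(d <= 0 for d in self.distances_km):
            raise ValueError("segment distances must be positive")
        bad = set(self.habitats) - {"freshwater", "marine_inlet", "coastal"}
        if bad:
            raise ValueError(f"unknown habitats: {sorted(bad)}")

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def free_transitions(self) -> list[int]:
        return [t for t, h in enumerate(self.habitats) if h != "freshwater"]

    @property
    def free_p_occasions(self) -> list[int]:
        # p at the final occasion is fixed to 1; occasion 0 is the release
        return list(range(1, self.n_occasions - 1))


@dataclass(frozen=True)
class CJSModelSpec:
    """Covariate design: which terms enter the s and p linear predictors."""

    phi_terms: tuple[str, ...] = ()
    p_terms: tuple[str, ...] = ()

    def __post_init__(self):
        if set(self.phi_terms) - {"habitat", "year"}:
            raise ValueError("phi terms must be within {habitat, year}")
        if set(self.p_terms) - {"array", "year"}:
            raise ValueError("p terms must be within {array, year}")

    @property
    def name(self) -> str:
        phi = "+".join(self.phi_terms) if self.phi_terms else "1"
        p = "+".join(self.p_terms) if self.p_terms else "1"
        return f"Phi(~{phi}) p(~{p})"


def build_encounter_histories(
    cleaned: pd.DataFrame,
    deployments: pd.DataFrame,
    receivers: pd.DataFrame,
    group: PathwayGroup,
) -> pd.DataFrame:
    """Encounter histories for every group fish detected at the entry occasion.

    Returns one row per tag with columns ``tag_id, river, year, history``
    where ``history`` is a 0/1 string over the group occasions; its first
    character is always ``1``.
    """
    det_tags = set(cleaned["tag_id"].astype(str))
    known = set(deployments["tag_id"].astype(str))
    orphans = det_tags - known
    if orphans:
        raise ValueError(
            f"{len(orphans)} detected tags have no deployment row "
            f"(e.g. {sorted(orphans)[:3]})")
    dep = deployments[deployments["river"].isin(group.rivers)]
    df = cleaned.merge(receivers[["receiver_id", "array_id"]], on="receiver_id")
    seen = df.groupby("tag_id")["array_id"].agg(set)
    occ0 = group.occasions[0]
    entry = (occ0,) if isinstance(occ0, str) else tuple(occ0)
    rows = []
    for _, d in dep.iterrows():
        arrays = seen.get(str(d["tag_id"]), set())
        if not set(entry) & arrays:
            continue  # never entered the study
        h = "1" + "".join("1" if occ in arrays else "0"
                          for occ in group.occasions[1:])
        rows.append({"tag_id": str(d["tag_id"]), "river": d["river"],
                     "year": int(d["year"]), "history": h})
    return pd.DataFrame(rows, columns=["tag_id", "river", "year", "history"])


def min_migration_success(histories: pd.DataFrame, transition: int) -> float:
    """Raw minimum success over one transition, as a percentage.

    The number of fish detected at occasion ``transition + 1`` as a
    proportion of fish detected at occasion ``transition``; no correction
    for detection efficiency or distance. NaN when the denominator is zero.
    """
    at_j = histories["history"].str[transition] == "1"
    n_j = int(at_j.sum())
    if n_j == 0:
        logger.warning("no fish detected at occasion %d", transition)
        return float("nan")
    n_next = int((at_j & (histories["history"].str[transition + 1] == "1")).sum())
    return 100.0 * n_next / n_j


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _history_log_prob(h: tuple[int, ...], phi: np.ndarray, p: np.ndarray) -> float:
    """Log-probability of one encounter history given segment survival and p.

    ``phi[t]`` is survival over transition t; ``p[j]`` is detection at
    occasion j+1 (length T-1). ``h[0]`` must be 1 (conditioning on release).
    """
    T = len(h)
    last = max(i for i in range(T) if h[i] == 1)
    logp = 0.0
    for t in range(last):
        det = h[t + 1]
        logp += np.log(phi[t]) + (np.log(p[t]) if det else np.log1p(-p[t]))
    # chi: probability of never being seen after occasion `last`
    chi = 1.0
    for t in range(T - 2, last - 1, -1):
        chi = (1.0 - phi[t]) + phi[t] * (1.0 - p[t]) * chi
    return logp + np.log(chi)


def _all_histories(T: int):
    for tail in itertools.product((0, 1), repeat=T - 1):
        yield (1, *tail)


class _Design:
    """Maps the free parameter vector to per-(transition, year) s and p."""

    def __init__(self, group: PathwayGroup, years: list[int], spec: CJSModelSpec):
        self.group = group
        self.years = sorted(int(y) for y in years)
        self.spec = spec
        T = group.n_occasions

        self.free_phi = group.free_transitions
        self.free_p = group.free_p_occasions
        habs = sorted({group.habitats[t] for t in self.free_phi})
        arrays = [group.occasions[j] for j in self.free_p]

        self.phi_cols = ["phi:(Intercept)"]
        if "habitat" in spec.phi_terms:
            self.phi_cols += [f"phi:habitat[{h}]" for h in habs[1:]]
        if "year" in spec.phi_terms:
            self.phi_cols += [f"phi:year[{y}]" for y in self.years[1:]]

        self.p_cols = []
        if self.free_p:
            self.p_cols = ["p:(Intercept)"]
            if "array" in spec.p_terms:
                self.p_cols += [f"p:array[{a}]" for a in arrays[1:]]
            if "year" in spec.p_terms:
                self.p_cols += [f"p:year[{y}]" for y in self.years[1:]]

        def phi_row(t, y):
            x = [1.0]
            if "habitat" in spec.phi_terms:
                x += [1.0 if group.habitats[t] == h else 0.0 for h in habs[1:]]
            if "year" in spec.phi_terms:
                x += [1.0 if y == yy else 0.0 for yy in self.years[1:]]
            return x

        def p_row(j, y):
            x = [1.0]
            if "array" in spec.p_terms:
                x += [1.0 if group.occasions[j] == a else 0.0 for a in arrays[1:]]
            if "year" in spec.p_terms:
                x += [1.0 if y == yy else 0.0 for yy in self.years[1:]]
            return x

        self.phi_rows = [(t, y) for y in self.years for t in self.free_phi]
        self.X_phi = np.array([phi_row(t, y) for t, y in self.phi_rows]) \
            if self.phi_rows else np.empty((0, len(self.phi_cols)))
        self.p_rows = [(j, y) for y in self.years for j in self.free_p]
        self.X_p = np.array([p_row(j, y) for j, y in self.p_rows]) \
            if self.p_rows else np.empty((0, max(len(self.p_cols), 1)))

        self.n_phi = len(self.phi_cols)
        self.n_p = len(self.p_cols)
        self.K = self.n_phi + self.n_p
        self.T = T

    @property
    def param_names(self) -> list[str]:
        return self.phi_cols + self.p_cols

    def natural(self, params: np.ndarray):
        """Per-year segment survival and detection arrays from link params.

        Returns ``{year: (phi, p)}`` with ``phi[t] = s_t ** d_t`` and
        ``p[j-1]`` the detection probability at occasion ``j``.
        """
        beta_phi = params[:self.n_phi]
        beta_p = params[self.n_phi:]
        s_link = self.X_phi @ beta_phi if self.n_phi else np.empty(0)
        p_link = self.X_p @ beta_p if self.n_p else np.empty(0)
        out = {}
        d = np.asarray(self.group.distances_km)
        for y in self.years:
            phi = np.ones(self.T - 1)
            for (t, yy), lk in zip(self.phi_rows, s_link):
                if yy == y:
                    phi[t] = expit(lk) ** d[t]
            p = np.ones(self.T - 1)  # final occasion fixed at 1
            for (j, yy), lk in zip(self.p_rows, p_link):
                if yy == y:
                    p[j - 1] = expit(lk)
            out[y] = (phi, p)
        return out


def _aggregate(histories: pd.DataFrame) -> dict[int, dict[tuple, int]]:
    agg: dict[int, dict[tuple, int]] = {}
    for (year, h), n in histories.groupby(["year", "history"]).size().items():
        agg.setdefault(int(year), {})[tuple(int(c) for c in h)] = int(n)
    return agg


def cjs_neg_loglik(
    params: np.ndarray,
    counts: dict[int, dict[tuple, int]],
    design: _Design,
) -> float:
    """Negative log-likelihood of aggregated histories (inf if non-finite)."""
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        return np.inf
    nat = design.natural(params)
    nll = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        for year, hist_counts in counts.items():
            phi, p = nat[year]
            for h, n in hist_counts.items():
                lp = _history_log_prob(h, phi, p)
                if not np.isfinite(lp):
                    return np.inf
                nll -= n * lp
    return float(nll)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class CJSFit:
    group: PathwayGroup
    spec: CJSModelSpec
    design: _Design
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    K: int
    n_eff: int
    converged: bool
    boundary: bool
    aicc: float = np.nan
    qaicc: float = np.nan
    real: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def deviance_df(self) -> int:
        n_cells = len(self.design.years) * (2 ** (self.group.n_occasions - 1) - 1)
        return max(n_cells - self.K, 1)


def _num_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def _real_table(design: _Design, params: np.ndarray, cov: np.ndarray) -> pd.DataFrame:
    """Natural-scale estimates: per-km s per (transition, year), p per (array, year)."""
    group = design.group
    rows = []
    bphi = params[:design.n_phi]
    Vphi = cov[:design.n_phi, :design.n_phi]
    for i, (t, y) in enumerate(design.phi_rows):
        x = design.X_phi[i]
        lk = float(x @ bphi)
        se = float(np.sqrt(max(x @ Vphi @ x, 0.0)))
        rows.append({"kind": "s_per_km", "index": t,
                     "label": group.habitats[t], "year": y,
                     "estimate": expit(lk), "se_link": se,
                     "lcl": expit(lk - Z95 * se), "ucl": expit(lk + Z95 * se),
                     "fixed": False})
    bp = params[design.n_phi:]
    Vp = cov[design.n_phi:, design.n_phi:]
    for i, (j, y) in enumerate(design.p_rows):
        x = design.X_p[i]
        lk = float(x @ bp)
        se = float(np.sqrt(max(x @ Vp @ x, 0.0)))
        rows.append({"kind": "p", "index": j,
                     "label": group.occasions[j], "year": y,
                     "estimate": expit(lk), "se_link": se,
                     "lcl": expit(lk - Z95 * se), "ucl": expit(lk + Z95 * se),
                     "fixed": False})
    # fixed cells, for completeness of the real-parameter surface
    for y in design.years:
        for t, h in enumerate(group.habitats):
            if h == "freshwater":
                rows.append({"kind": "s_per_km", "index": t, "label": h,
                             "year": y, "estimate": 1.0, "se_link": 0.0,
                             "lcl": 1.0, "ucl": 1.0, "fixed": True})
        rows.append({"kind": "p", "index": group.n_occasions - 1,
                     "label": group.occasions[-1], "year": y,
                     "estimate": 1.0, "se_link": 0.0,
                     "lcl": 1.0, "ucl": 1.0, "fixed": True})
    df = pd.DataFrame(rows)
    # natural-scale delta-method SE: d expit / d eta = p (1 - p)
    df["se"] = df["se_link"] * df["estimate"] * (1 - df["estimate"])
    return df.sort_values(["kind", "index", "year"]).reset_index(drop=True)


def fit_cjs(
    histories: pd.DataFrame,
    group: PathwayGroup,
    spec: CJSModelSpec,
    n_starts: int = 5,
    seed: int = 0,
) -> CJSFit:
    """Maximum-likelihood fit by quasi-Newton search from multiple starts."""
    years = sorted(histories["year"].unique().astype(int))
    design = _Design(group, years, spec)
    counts = _aggregate(histories)
    n_eff = int(len(histories))

    rng = np.random.default_rng(seed)
    starts = [np.zeros(design.K)]
    starts += [rng.normal(0.0, 1.5, design.K) for _ in range(n_starts - 1)]

    # capped objective keeps quasi-Newton finite differencing clean
    obj = lambda p: min(cjs_neg_loglik(p, counts, design), 1e12)  # noqa: E731
    best = None
    for x0 in starts:
        try:
            res = minimize(obj, x0, method="BFGS",
                           options={"gtol": 1e-8, "maxiter": 500})
        except (FloatingPointError, ValueError):  # pragma: no cover
            continue
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None or not np.isfinite(best.fun):
        return CJSFit(group, spec, design, np.full(design.K, np.nan),
                      np.full((design.K, design.K), np.nan),
                      -np.inf, design.K, n_eff, False, False)

    params = best.x
    boundary = bool(np.any(np.abs(params) > 12.0))
    H = _num_hessian(obj, params)
    try:
        cov = np.linalg.pinv(H)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.full_like(H, np.nan)
    fit = CJSFit(group, spec, design, params, cov, -float(best.fun),
                 design.K, n_eff, bool(best.success or best.fun < np.inf),
                 boundary)
    fit.real = _real_table(design, params, cov)
    fit.aicc, _ = information_criteria(fit.loglik, fit.K, fit.n_eff)
    return fit


def information_criteria(
    loglik: float, K: int, n_eff: int, chat: float = 1.0
) -> tuple[float, float]:
    """Small-sample (quasi-)information criteria.

    AICc = -2l + 2K + 2K(K+1)/(n-K-1). For QAICc the deviance is scaled by
    c-hat and K is incremented by 1 for the estimated dispersion. A c-hat
    at or below 1 leaves the criterion as the AICc (c-hat floored at 1).
    """
    if n_eff <= K + 1:
        raise ValueError("n_eff must exceed K + 1 for AICc")
    aicc = -2.0 * loglik + 2 * K + 2 * K * (K + 1) / (n_eff - K - 1)
    c = max(chat, 1.0)
    Kq = K + 1
    if n_eff <= Kq + 1:
        raise ValueError("n_eff must exceed K + 2 for QAICc")
    qaicc = -2.0 * loglik / c + 2 * Kq + 2 * Kq * (Kq + 1) / (n_eff - Kq - 1)
    return float(aicc), float(qaicc)


# ---------------------------------------------------------------------------
# overdispersion (c-hat)
# ---------------------------------------------------------------------------

def _saturated_loglik(counts: dict[int, dict[tuple, int]]) -> float:
    ll = 0.0
    for _, hist_counts in counts.items():
        N = sum(hist_counts.values())
        for _, n in hist_counts.items():
            ll += n * np.log(n / N)
    return float(ll)


def deviance(fit_loglik: float, counts: dict[int, dict[tuple, int]]) -> float:
    """Deviance against the saturated per-cohort multinomial model."""
    return 2.0 * (_saturated_loglik(counts) - fit_loglik)


def simulate_histories(
    rng: np.random.Generator,
    group: PathwayGroup,
    natural: dict[int, tuple[np.ndarray, np.ndarray]],
    n_by_year: dict[int, int],
) -> pd.DataFrame:
    """Simulate encounter histories from segment survival and detection arrays."""
    T = group.n_occasions
    rows = []
    for year, n in n_by_year.items():
        phi, p = natural[year]
        alive = np.ones(n, dtype=bool)
        hist = np.zeros((n, T), dtype=int)
        hist[:, 0] = 1
        for t in range(T - 1):
            alive = alive & (rng.random(n) < phi[t])
            det = alive & (rng.random(n) < p[t])
            hist[alive & det, t + 1] = 1
        for i in range(n):
            rows.append({"tag_id": f"sim{year}_{i}", "river": group.rivers[0],
                         "year": year,
                         "history": "".join(map(str, hist[i]))})
    return pd.DataFrame(rows)


@dataclass
class ChatEstimate:
    chat: float                     # mean of the three estimators (raw)
    chat_for_ic: float              # floored at 1
    deviance_ratio: float
    deviance_chat_ratio: float
    median_chat: float
    n_failed: int = 0
    flagged: bool = False


def estimate_chat(
    fit: CJSFit,
    histories: pd.DataFrame,
    n_boot: int = 1000,
    median_points: int = 10,
    median_reps: int = 100,
    chat_upper: float = 3.0,
    seed: int = 0,
) -> ChatEstimate:
    """Resampling-based overdispersion estimate for a fitted CJS model.

    Mean of three estimators: observed deviance over mean parametric-
    bootstrap deviance; observed deviance-c-hat (deviance/df) over its mean
    bootstrap value; and a median-c-hat obtained by simulating datasets at
    ``median_points`` dispersion levels between 1 and ``chat_upper``
    (``median_reps`` replicates each, dispersion induced by cluster
    resampling) and logistic-regressing the exceedance indicator on the
    dispersion level. The final estimate is floored at 1 for use in QAICc.
    """
    rng = np.random.default_rng(seed)
    counts_obs = _aggregate(histories)
    dev_obs = deviance(fit.loglik, counts_obs)
    n_cells = len(fit.design.years) * (2 ** (fit.group.n_occasions - 1) - 1)
    if n_cells - fit.K <= 0 or dev_obs < 1e-9:
        # saturated (or better) model: no information about dispersion
        logger.warning("model is saturated; c-hat fixed at 1")
        return ChatEstimate(chat=1.0, chat_for_ic=1.0,
                            deviance_ratio=np.nan,
                            deviance_chat_ratio=np.nan,
                            median_chat=np.nan, flagged=True)
    df_dev = fit.deviance_df
    chat_obs = dev_obs / df_dev
    nat = fit.design.natural(fit.params)
    n_by_year = {int(y): int(n) for y, n in histories["year"].value_counts().items()}

    def _refit_nll(h: pd.DataFrame) -> float | None:
        c = _aggregate(h)
        res = minimize(lambda p: min(cjs_neg_loglik(p, c, fit.design), 1e12),
                       fit.params,
                       method="BFGS", options={"gtol": 1e-6, "maxiter": 300})
        if not np.isfinite(res.fun):
            return None
        return deviance(-float(res.fun), c)

    boot_dev, failed = [], 0
    for _ in range(n_boot):
        sim = simulate_histories(rng, fit.group, nat, n_by_year)
        d = _refit_nll(sim)
        if d is None:
            failed += 1
        else:
            boot_dev.append(d)
    boot_dev = np.asarray(boot_dev)
    r1 = dev_obs / boot_dev.mean() if len(boot_dev) else np.nan
    r2 = chat_obs / (boot_dev / df_dev).mean() if len(boot_dev) else np.nan

    # median c-hat: cluster-resampling at a grid of dispersion levels
    grid = np.linspace(1.0, chat_upper, median_points)
    cs, exceeds = [], []
    for c in grid:
        for _ in range(median_reps):
            m_by_year = {y: max(2, int(round(n / c))) for y, n in n_by_year.items()}
            base = simulate_histories(rng, fit.group, nat, m_by_year)
            parts = []
            for y, n in n_by_year.items():
                sub = base[base["year"] == y]
                idx = rng.integers(0, len(sub), n)
                parts.append(sub.iloc[idx])
            sim = pd.concat(parts, ignore_index=True)
            d = _refit_nll(sim)
            if d is None:
                failed += 1
                continue
            cs.append(c)
            exceeds.append(1.0 if d / df_dev > chat_obs else 0.0)
    median_chat = _median_chat_from_grid(np.asarray(cs), np.asarray(exceeds),
                                         chat_upper)

    total = n_boot + median_points * median_reps
    flagged = failed > 0.1 * total
    if flagged:
        logger.warning("c-hat bootstrap failure rate %.1f%%",
                       100.0 * failed / total)
    vals = [v for v in (r1, r2, median_chat) if np.isfinite(v)]
    chat = float(np.mean(vals)) if vals else 1.0
    return ChatEstimate(chat=chat, chat_for_ic=max(chat, 1.0),
                        deviance_ratio=float(r1),
                        deviance_chat_ratio=float(r2),
                        median_chat=float(median_chat),
                        n_failed=failed, flagged=flagged)


def _median_chat_from_grid(cs: np.ndarray, exceeds: np.ndarray,
                           chat_upper: float) -> float:
    """50% point of P(simulated deviance-c-hat > observed) against c."""
    if len(cs) == 0:
        return np.nan
    if exceeds.mean() >= 1.0:
        return 1.0          # observed c-hat below every simulation
    if exceeds.mean() <= 0.0:
        return chat_upper   # observed beyond the simulated range
    import statsmodels.api as sm
    X = sm.add_constant(cs)
    try:
        res = sm.GLM(exceeds, X, family=sm.families.Binomial()).fit()
        b0, b1 = res.params
        if abs(b1) < 1e-12:
            return np.nan
        c50 = -b0 / b1
    except Exception:  # pragma: no cover - perfect separation etc.
        return np.nan
    return float(np.clip(c50, 1.0, chat_upper))


# ---------------------------------------------------------------------------
# candidate sets and model averaging
# ---------------------------------------------------------------------------

def candidate_set(group: PathwayGroup, years: list[int]) -> list[CJSModelSpec]:
    """All nested combinations of the additive global model's terms.

    Two-zone pathways: s ~ {1, habitat, year, habitat+year} crossed with
    p ~ {1, array, year, array+year}. Pathways with a single marine zone
    (and a single estimable array) use year-only combinations. Terms that
    cannot vary (one year, one habitat, one estimable array) are dropped,
    and duplicate specs removed.
    """
    multi_year = len(set(years)) > 1
    habs = {group.habitats[t] for t in group.free_transitions}
    multi_hab = len(habs) > 1
    multi_array = len(group.free_p_occasions) > 1

    phi_pool = []
    if multi_hab:
        phi_pool.append("habitat")
    if multi_year:
        phi_pool.append("year")
    p_pool = []
    if multi_array:
        p_pool.append("array")
    if multi_year:
        p_pool.append("year")

    def subsets(pool):
        out = []
        for r in range(len(pool) + 1):
            out += [tuple(c) for c in itertools.combinations(pool, r)]
        return out

    specs = []
    seen = set()
    for phi_t in subsets(phi_pool):
        for p_t in subsets(p_pool):
            s = CJSModelSpec(phi_terms=phi_t, p_terms=p_t)
            if s.name not in seen:
                seen.add(s.name)
                specs.append(s)
    return specs


@dataclass
class ModelSetResult:
    group: PathwayGroup
    table: pd.DataFrame          # model, K, loglik, IC, delta, weight, retained
    chat: ChatEstimate | None
    averaged: pd.DataFrame       # real parameters with unconditional SE
    fits: list[CJSFit]
    criterion: str               # "AICc" or "QAICc"


def model_average(
    fits: list[CJSFit],
    chat: ChatEstimate | None = None,
    delta_max: float = DELTA_MAX_DEFAULT,
) -> ModelSetResult:
    """Rank fits by (Q)AICc and average real parameters over the retained set.

    Weights are ``exp(-delta/2)`` renormalised over models within
    ``delta_max`` of the best. The unconditional standard error follows the
    Buckland form, adding the between-model spread to each model's
    conditional variance. Models with non-positive coefficient variances
    remain in the averaging set.
    """
    ok = [f for f in fits if f.converged and np.isfinite(f.loglik)]
    if not ok:
        raise ValueError("no converged models to average")
    c = chat.chat_for_ic if chat is not None else 1.0
    use_q = c > 1.0
    ics = []
    for f in ok:
        aicc, qaicc = information_criteria(f.loglik, f.K, f.n_eff, c)
        f.aicc, f.qaicc = aicc, qaicc
        ics.append(qaicc if use_q else aicc)
    ics = np.asarray(ics)
    delta = ics - ics.min()
    retained = delta <= delta_max
    w = np.where(retained, np.exp(-delta / 2.0), 0.0)
    w = w / w.sum()

    table = pd.DataFrame({
        "model": [f.spec.name for f in ok],
        "K": [f.K for f in ok],
        "logLik": [f.loglik for f in ok],
        ("QAICc" if use_q else "AICc"): ics,
        "delta": delta,
        "weight": w,
        "retained": retained,
    }).sort_values("delta").reset_index(drop=True)

    # average the real-parameter surface cell by cell
    keys = ["kind", "index", "label", "year", "fixed"]
    stacked = []
    for f, wi in zip(ok, w):
        if wi == 0.0:
            continue
        r = f.real.copy()
        r["w"] = wi
        stacked.append(r)
    allr = pd.concat(stacked, ignore_index=True)
    rows = []
    for key, grp in allr.groupby(keys, sort=False):
        ww = grp["w"].to_numpy()
        ww = ww / ww.sum()
        est = grp["estimate"].to_numpy()
        se = grp["se"].to_numpy()
        avg = float(np.sum(ww * est))
        se_u = float(np.sum(ww * np.sqrt(se ** 2 + (est - avg) ** 2)))
        rec = dict(zip(keys, key))
        rec.update({"estimate": avg, "se_unconditional": se_u,
                    "lcl": max(avg - Z95 * se_u, 0.0),
                    "ucl": min(avg + Z95 * se_u, 1.0)})
        rows.append(rec)
    averaged = pd.DataFrame(rows).sort_values(["kind", "index", "year"]) \
                                 .reset_index(drop=True)
    return ModelSetResult(group=ok[0].group, table=table, chat=chat,
                          averaged=averaged, fits=ok,
                          criterion="QAICc" if use_q else "AICc")


def fit_model_set(
    histories: pd.DataFrame,
    group: PathwayGroup,
    n_boot: int = 0,
    delta_max: float = DELTA_MAX_DEFAULT,
    seed: int = 0,
    median_points: int = 10,
    median_reps: int = 100,
) -> ModelSetResult:
    """Fit the candidate set, estimate c-hat on the global model, and average.

    ``n_boot = 0`` skips the c-hat bootstrap (c-hat treated as 1, AICc
    ranking), mirroring pathways with insufficient data for goodness-of-fit
    testing.
    """
    years = sorted(histories["year"].unique().astype(int))
    specs = candidate_set(group, years)
    fits = [fit_cjs(histories, group, s, seed=seed + i)
            for i, s in enumerate(specs)]
    chat = None
    if n_boot > 0:
        global_fit = max((f for f in fits if f.converged), key=lambda f: f.K)
        chat = estimate_chat(global_fit, histories, n_boot=n_boot,
                             median_points=median_points,
                             median_reps=median_reps, seed=seed)
    return model_average(fits, chat=chat, delta_max=delta_max)
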