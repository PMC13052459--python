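import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.optimize import minimize_scalar
from scipy.special import expit

from postsmolt import passage


# ---------------------------------------------------------------------------
# rank scaling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("y,want", [(1, 0.005), (64, 0.5), (127, 0.995)])
def test_scale_rank_reference_points(y, want):
    assert passage.scale_rank(y, 1, 127, 100) == pytest.approx(want)


def test_scale_rank_validation():
    with pytest.raises(ValueError):
        passage.scale_rank(0, 1, 127, 100)
    with pytest.raises(ValueError):
        passage.scale_rank(5, 10, 5, 100)


def test_scale_unscale_roundtrip_all_ranks():
    for n in (2, 10, 100, 1000):
        ranks = np.arange(1, 128)
        ypp = passage.scale_rank(ranks, 1, 127, n)
        assert np.all((ypp > 0) & (ypp < 1))
        assert np.all(np.diff(ypp) > 0)  # strictly monotone
        back = passage.unscale(ypp, 1, 127, n)
        assert np.array_equal(back, ranks)


def test_unscale_midpoint_and_clamp():
    assert passage.unscale(0.5, 1, 127, 100) == 64
    assert passage.unscale(1e-9, 1, 127, 100) == 1
    assert passage.unscale(1 - 1e-9, 1, 127, 100) == 127
    with pytest.raises(ValueError):
        passage.unscale(0.0, 1, 127, 100)


# ---------------------------------------------------------------------------
# empirical corridors
# ---------------------------------------------------------------------------

def _points(ranks, river="R", year=2019):
    return pd.DataFrame({"tag_id": [f"t{i}" for i in range(len(ranks))],
                         "array_id": "C", "rank": ranks, "river": river,
                         "year": year, "arrival_day": 120})


def test_empirical_corridor_linear_interpolation():
    c = passage.empirical_corridor(_points([10, 20, 30])).iloc[0]
    assert (c["median"], c["q25"], c["q75"]) == (20, 15, 25)


def test_empirical_corridor_degenerate_and_symmetry():
    c1 = passage.empirical_corridor(_points([42])).iloc[0]
    assert c1["q05"] == c1["median"] == c1["q95"] == 42
    sym = passage.empirical_corridor(_points([10, 20, 30, 40, 50])).iloc[0]
    assert sym["median"] == 30


# ---------------------------------------------------------------------------
# beta log-likelihood
# ---------------------------------------------------------------------------

def test_betareg_loglik_uniform_case():
    # mu=0.5, tau=2 is Beta(1,1): density 1, log-density 0
    assert passage.betareg_loglik(np.array([0.5]), 0.5, 2.0) == pytest.approx(0.0)


def test_betareg_loglik_rejects_boundary():
    with pytest.raises(ValueError):
        passage.betareg_loglik(np.array([0.0, 0.5]), 0.5, 2.0)


def test_beta_density_normalises(rng):
    for _ in range(10):
        mu = rng.uniform(0.1, 0.9)
        tau = rng.uniform(0.5, 50.0)
        val, _ = integrate.quad(
            lambda y: np.exp(passage.betareg_loglik(np.array([y]), mu, tau)),
            0.0, 1.0, limit=200)
        assert abs(val - 1.0) < 1e-6


def test_loglik_matches_independent_density(rng):
    """Dual route: our summed log-density vs direct scipy evaluation."""
    y = rng.uniform(0.01, 0.99, 1000)
    mu = rng.uniform(0.2, 0.8, 1000)
    tau = rng.uniform(1.0, 40.0, 1000)
    ours = passage.betareg_loglik(y, mu, tau)
    want = float(np.sum(stats.beta.logpdf(y, mu * tau, (1 - mu) * tau)))
    assert ours == pytest.approx(want, abs=1e-10)


def test_true_parameters_dominate_perturbed(rng):
    mu, tau = 0.3, 15.0
    wins = 0
    for _ in range(20):
        y = rng.beta(mu * tau, (1 - mu) * tau, 200)
        at_true = passage.betareg_loglik(y, mu, tau)
        at_off = passage.betareg_loglik(y, mu + 0.1, tau)
        wins += at_true > at_off
    assert wins >= 18


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _sim_data(rng, n=500, year_effect=0.4, tau0=10.0):
    riv = rng.choice(["A", "B"], n)
    yr = rng.choice([2019, 2021], n)
    day = rng.uniform(110, 140, n)
    mu = expit(0.0 + year_effect * (yr == 2021))
    y = rng.beta(mu * tau0, (1 - mu) * tau0)
    return pd.DataFrame({"y": y, "river": riv, "year": yr,
                         "arrival_day": day})


def test_betareg_parameter_recovery(rng):
    df = _sim_data(rng, n=500)
    fit = passage.fit_betareg(df, ("C(year)",), ())
    params = fit.result.params
    bse = fit.result.bse
    names = list(fit.result.model.exog_names)
    i = names.index("C(year)[T.2021]")
    assert abs(params[i] - 0.4) < 2 * bse[i]
    # precision intercept on the log scale
    assert abs(params[-1] - np.log(10.0)) < 2 * bse[-1]
    # our independent log-likelihood agrees with the fitted model's
    pred = fit.predict(df)
    ours = passage.betareg_loglik(df["y"].to_numpy(),
                                  pred["mu"].to_numpy(),
                                  pred["tau"].to_numpy())
    assert ours == pytest.approx(fit.loglik, abs=1e-6)


def test_betareg_concentration_limit(rng):
    y = np.clip(rng.normal(0.37, 0.004, 400), 0.3, 0.45)
    df = pd.DataFrame({"y": y, "river": "A", "year": 2019,
                       "arrival_day": 120.0})
    fit = passage.fit_betareg(df, (), ())
    mu_hat = float(expit(fit.result.params[0]))
    assert mu_hat == pytest.approx(y.mean(), abs=0.002)


def test_betareg_intercept_only_matches_1d_oracle(rng):
    y = rng.beta(0.3 * 12, 0.7 * 12, 300)
    df = pd.DataFrame({"y": y, "river": "A", "year": 2019,
                       "arrival_day": 120.0})
    fit = passage.fit_betareg(df, (), ())
    mu_hat = float(expit(fit.result.params[0]))
    tau_hat = float(np.exp(fit.result.params[1]))

    def profile_mu(mu):
        r = minimize_scalar(
            lambda lt: -passage.betareg_loglik(y, mu, np.exp(lt)),
            bounds=(-2, 8), method="bounded")
        return r.fun

    r = minimize_scalar(profile_mu, bounds=(0.05, 0.95), method="bounded")
    assert mu_hat == pytest.approx(r.x, abs=1e-3)
    assert passage.betareg_loglik(y, mu_hat, tau_hat) >= -r.fun - 1e-4


def test_backward_select_keeps_active_interaction(rng):
    n = 600
    riv = rng.choice(["A", "B", "C"], n)
    yr = rng.choice([2019, 2021], n)
    day = rng.uniform(110, 140, n)
    eta = -0.5 + 0.7 * ((yr == 2021) & (riv == "B")) \
        - 0.6 * ((yr == 2021) & (riv == "C"))
    y = rng.beta(expit(eta) * 30, (1 - expit(eta)) * 30)
    df = pd.DataFrame({"y": y, "river": riv, "year": yr, "arrival_day": day})
    fit, trail = passage.backward_select(df)
    assert "C(year):C(river)" in fit.mu_terms
    assert "C(year):arrival_c" not in fit.mu_terms
    assert "C(river):arrival_c" not in fit.mu_terms
    # marginality: main effects of a retained interaction survive
    assert {"C(year)", "C(river)"} <= set(fit.mu_terms)


def test_backward_select_null_reaches_intercept(rng):
    """Pure-noise covariates are eliminated down to the intercept model.

    With four independent null terms tested at alpha = 0.05 the expected
    intercept-only rate is about (1 - alpha)^4 ~ 0.81; assert above 0.75
    to leave binomial room at 200 replicates.
    """
    kept = 0
    reps = 200
    for r in range(reps):
        df = _sim_data(np.random.default_rng(300 + r), n=150, year_effect=0.0)
        fit, _ = passage.backward_select(
            df, mu_terms=("C(year)", "arrival_c"),
            tau_terms=("C(year)", "arrival_c"))
        kept += (len(fit.mu_terms) == 0 and len(fit.tau_terms) == 0)
    assert kept / reps >= 0.75


def test_backward_select_fixed_point(rng):
    df = _sim_data(rng, n=300, year_effect=1.0)
    fit, trail = passage.backward_select(df, ("C(year)",), ())
    assert fit.mu_terms == ("C(year)",)


# ---------------------------------------------------------------------------
# corridors from the fitted distribution
# ---------------------------------------------------------------------------

def test_corridor_bounds_uniform_case():
    # mu=0.5, tau=2 is uniform: the central 90% band is (0.05, 0.95),
    # mapping to ranks 7 and 121 on a 127-receiver array with n=100
    b = passage.corridor_bounds(0.5, 2.0, 1, 127, 100)
    assert b[0.9] == (7, 121)


def test_corridor_bounds_concentration_and_monotonicity():
    b = passage.corridor_bounds(0.5, 1e7, 1, 127, 100)
    assert b[0.9][0] == b[0.9][1] == 64
    widths = []
    for tau in (4.0, 16.0, 64.0):
        lo, hi = passage.corridor_bounds(0.3, tau, 1, 127, 100)[0.9]
        widths.append(hi - lo)
    assert widths[0] > widths[1] > widths[2]
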