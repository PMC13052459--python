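import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from postsmolt import cmr


def _group(T=3, d=(10.0, 30.0), habitats=("marine_inlet", "coastal")):
    occ = tuple(["rel"] + [f"A{j}" for j in range(1, T)])
    return cmr.PathwayGroup("g", ("R",), occ, habitats[:T - 1], d[:T - 1])


def _hist_df(hists, year=2019):
    return pd.DataFrame({"tag_id": [f"t{i}" for i in range(len(hists))],
                         "river": "R", "year": year, "history": hists})


# ---------------------------------------------------------------------------
# encounter histories, minimum success
# ---------------------------------------------------------------------------

def _toy_tables():
    receivers = pd.DataFrame({
        "receiver_id": ["r0", "r1", "r2"],
        "array_id": ["rel", "A1", "A2"],
        "x": [0, 1000, 2000], "y": [0, 0, 0], "rank": [1, 1, 1],
        "habitat": ["freshwater", "marine_inlet", "coastal"]})
    dep = pd.DataFrame({"tag_id": ["a", "b", "c"], "river": "R",
                        "year": 2019})
    return receivers, dep


def test_history_encoding():
    receivers, dep = _toy_tables()
    det = pd.DataFrame({
        "tag_id": ["a", "a", "b", "c", "c", "c"],
        "receiver_id": ["r0", "r1", "r0", "r0", "r1", "r2"],
        "timestamp": pd.to_datetime(["2019-05-01"] * 6)})
    g = _group()
    h = cmr.build_encounter_histories(det, dep, receivers, g)
    got = dict(zip(h["tag_id"], h["history"]))
    assert got == {"a": "110", "b": "100", "c": "111"}


def test_history_requires_deployment_row():
    receivers, dep = _toy_tables()
    det = pd.DataFrame({"tag_id": ["zz"], "receiver_id": ["r0"],
                        "timestamp": [pd.Timestamp("2019-05-01")]})
    with pytest.raises(ValueError, match="deployment"):
        cmr.build_encounter_histories(det, dep, receivers, _group())


def test_histories_match_membership_oracle(rng):
    receivers, _ = _toy_tables()
    tags = [f"t{i}" for i in range(40)]
    dep = pd.DataFrame({"tag_id": tags, "river": "R", "year": 2019})
    rows = []
    for t in tags:
        for r in ["r0", "r1", "r2"]:
            if rng.random() < 0.5:
                rows.append((t, r, pd.Timestamp("2019-05-02")))
    det = pd.DataFrame(rows, columns=["tag_id", "receiver_id", "timestamp"])
    h = cmr.build_encounter_histories(det, dep, receivers, _group())
    seen = det.groupby("tag_id")["receiver_id"].agg(set).to_dict()
    for t in tags:
        s = seen.get(t, set())
        if "r0" not in s:
            assert t not in set(h["tag_id"])
        else:
            want = "1" + ("1" if "r1" in s else "0") + ("1" if "r2" in s else "0")
            assert h.loc[h["tag_id"] == t, "history"].iloc[0] == want


def test_min_migration_success():
    h = _hist_df(["110"] * 50 + ["111"] * 50)
    assert cmr.min_migration_success(h, 0) == pytest.approx(100.0)
    assert cmr.min_migration_success(h, 1) == pytest.approx(50.0)
    h2 = _hist_df(["100"] * 10)
    assert np.isnan(cmr.min_migration_success(h2, 1))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _enumerate_total(phi, p):
    T = len(phi) + 1
    tot = 0.0
    for tail in itertools.product((0, 1), repeat=T - 1):
        tot += np.exp(cmr._history_log_prob((1, *tail), phi, p))
    return tot


def test_history_probabilities_sum_to_one(rng):
    """Enumerated CJS history probabilities are a proper distribution."""
    for T in (2, 3, 4, 5):
        for _ in range(20):
            phi = rng.uniform(0.05, 0.99, T - 1)
            p = rng.uniform(0.05, 0.99, T - 1)
            p[-1] = 1.0
            assert abs(_enumerate_total(phi, p) - 1.0) < 1e-12


def test_neg_loglik_certainty_limit():
    g = _group(T=3, d=(1.0, 1.0))
    h = _hist_df(["111"] * 10)
    design = cmr._Design(g, [2019], cmr.CJSModelSpec())
    counts = cmr._aggregate(h)
    # s = p = 1 on the natural scale is +inf on the logit scale; approach it
    val = cmr.cjs_neg_loglik(np.array([30.0, 30.0]), counts, design)
    assert val == pytest.approx(0.0, abs=1e-8)


def test_neg_loglik_nonfinite_params():
    g = _group(T=3, d=(1.0, 1.0))
    design = cmr._Design(g, [2019], cmr.CJSModelSpec())
    counts = cmr._aggregate(_hist_df(["111", "100"]))
    assert cmr.cjs_neg_loglik(np.array([np.nan, 0.0]), counts, design) == np.inf


def _textbook_cjs_nll(phi_p, counts_list, T):
    """Independent standard-CJS negative log-likelihood (natural scale).

    Conventional formulation: product over the detection part up to the
    last sighting and an explicit sum over death intervals afterwards.
    """
    phi = phi_p[:T - 1]
    p = np.append(phi_p[T - 1:], 1.0)
    nll = 0.0
    for h, n in counts_list:
        last = max(i for i, v in enumerate(h) if v)
        lik_front = 1.0
        for t in range(last):
            lik_front *= phi[t] * (p[t] if h[t + 1] else (1 - p[t]))
        # never seen after `last`: die in some interval or survive undetected
        tail = 0.0
        for death in range(last, T):          # death == T means survived all
            term = 1.0
            for t in range(last, min(death, T - 1)):
                term *= phi[t] * (1 - p[t])
            if death < T - 1:
                term *= (1 - phi[death])
            elif death == T - 1:
                continue
            tail += term
        # survive to the end undetected
        surv = 1.0
        for t in range(last, T - 1):
            surv *= phi[t] * (1 - p[t])
        tail += surv
        nll -= n * np.log(lik_front * tail)
    return nll


def test_unit_distance_reduces_to_textbook_cjs(rng):
    """With every segment 1 km the model is the standard CJS."""
    g = _group(T=4, d=(1.0, 1.0, 1.0),
               habitats=("marine_inlet", "marine_inlet", "coastal"))
    T = 4
    # random parameter points: likelihood values agree
    spec = cmr.CJSModelSpec()
    design = cmr._Design(g, [2019], spec)
    hists = ["1" + "".join(map(str, t))
             for t in itertools.product((0, 1), repeat=3)]
    counts_df = _hist_df([h for h in hists for _ in range(5)])
    counts = cmr._aggregate(counts_df)
    counts_list = [(tuple(map(int, h)), n)
                   for h, n in counts[2019].items()]
    # intercept model: one shared s, one shared p
    for _ in range(10):
        eta = rng.normal(0, 1, 2)
        ours = cmr.cjs_neg_loglik(eta, counts, design)
        s, pp = expit(eta)
        theirs = _textbook_cjs_nll(
            np.array([s, s, s, pp, pp]), counts_list, T)
        assert ours == pytest.approx(theirs, abs=1e-9)

    # and the fitted maximum agrees with a direct natural-scale optimiser
    phi_true = np.array([0.9, 0.8, 0.85])
    p_true = np.array([0.7, 0.6, 1.0])
    h = cmr.simulate_histories(rng, g, {2019: (phi_true, p_true)}, {2019: 400})
    fit = cmr.fit_cjs(h, g, spec, seed=0)
    cl = [(tuple(map(int, k)), n) for k, n in cmr._aggregate(h)[2019].items()]

    def nat_obj(x):
        s, pp = x
        return _textbook_cjs_nll(np.array([s, s, s, pp, pp]), cl, T)

    best = min((minimize(nat_obj, x0, method="Nelder-Mead",
                         options={"xatol": 1e-12, "fatol": 1e-14})
                for x0 in ([0.9, 0.7], [0.5, 0.5], [0.8, 0.3])),
               key=lambda r: r.fun)
    assert -fit.loglik == pytest.approx(best.fun, abs=1e-6)


def test_two_occasion_closed_form_mle():
    # 80 of 100 detected over a 10 km segment: s_hat = 0.8 ** (1/10)
    g = _group(T=2, d=(10.0,), habitats=("coastal",))
    h = _hist_df(["11"] * 80 + ["10"] * 20)
    fit = cmr.fit_cjs(h, g, cmr.CJSModelSpec())
    s = fit.real.query("kind == 's_per_km' and not fixed")["estimate"].iloc[0]
    assert s == pytest.approx(0.8 ** 0.1, abs=1e-7)


def test_parameter_recovery_simulation(rng):
    g = _group(T=3, d=(25.0, 40.0))
    phi = np.array([0.99 ** 25, 0.99 ** 40])
    p = np.array([0.8, 1.0])
    h = cmr.simulate_histories(rng, g, {2019: (phi, p)}, {2019: 1000})
    fit = cmr.fit_cjs(h, g, cmr.CJSModelSpec(phi_terms=("habitat",)), seed=0)
    real = fit.real[~fit.real["fixed"]]
    s_hat = real[real["kind"] == "s_per_km"]["estimate"]
    p_hat = real[real["kind"] == "p"]["estimate"].iloc[0]
    assert np.all(np.abs(s_hat - 0.99) < 0.005)
    assert abs(p_hat - 0.8) < 0.05


def test_all_detected_boundary_flagged():
    g = _group(T=3, d=(1.0, 1.0))
    h = _hist_df(["111"] * 50)
    fit = cmr.fit_cjs(h, g, cmr.CJSModelSpec())
    assert fit.boundary
    est = fit.real[~fit.real["fixed"]]["estimate"]
    assert np.all(est > 0.999)


def test_distance_monotonicity():
    """Longer segments with fixed per-km s mean fewer downstream detections."""
    spec = cmr.CJSModelSpec()
    eta = np.array([logit_s := 2.0, 1.0])
    probs = []
    for d in (5.0, 20.0, 60.0):
        g = _group(T=2, d=(d,), habitats=("coastal",))
        design = cmr._Design(g, [2019], spec)
        nat = design.natural(np.array([2.0]))
        probs.append(nat[2019][0][0])
    assert probs[0] > probs[1] > probs[2]


# ---------------------------------------------------------------------------
# information criteria, candidate sets, averaging
# ---------------------------------------------------------------------------

def test_information_criteria_formula():
    aicc, _ = cmr.information_criteria(-100.0, 3, 50)
    assert aicc == pytest.approx(206 + 24 / 46)
    # chat at 1: QAICc equals the AICc recomputed with K+1 parameters
    aicc2, qaicc2 = cmr.information_criteria(-100.0, 3, 50, chat=1.0)
    want = 200 + 2 * 4 + 2 * 4 * 5 / (50 - 5)
    assert qaicc2 == pytest.approx(want)
    aicc0, _ = cmr.information_criteria(-100.0, 0, 50)
    assert aicc0 == pytest.approx(200.0)
    with pytest.raises(ValueError):
        cmr.information_criteria(-100.0, 10, 11)


def test_candidate_sets():
    g2 = cmr.PathwayGroup("two", ("R",), ("rel", "FW", "In", "C"),
                          ("freshwater", "marine_inlet", "coastal"),
                          (5.0, 20.0, 40.0))
    specs = cmr.candidate_set(g2, [2019, 2021])
    assert len(specs) == 16
    g1 = cmr.PathwayGroup("one", ("R",), ("rel", "FW", "C"),
                          ("freshwater", "coastal"), (5.0, 40.0))
    specs1 = cmr.candidate_set(g1, [2019, 2021])
    assert len(specs1) == 4
    # no varying covariates at all: single intercept model
    specs0 = cmr.candidate_set(g1, [2019])
    assert len(specs0) == 1


def _fake_fit(group, spec, loglik, K, n_eff, est, se):
    design = cmr._Design(group, [2019], spec)
    f = cmr.CJSFit(group, spec, design, np.zeros(design.K),
                   np.eye(design.K), loglik, K, n_eff, True, False)
    f.real = pd.DataFrame([{
        "kind": "s_per_km", "index": 0, "label": "coastal", "year": 2019,
        "estimate": est, "se_link": 0.0, "lcl": est, "ucl": est,
        "fixed": False, "se": se}])
    return f


def test_model_average_symmetry_and_exclusion():
    g = _group(T=2, d=(1.0,), habitats=("coastal",))
    spec = cmr.CJSModelSpec()
    f1 = _fake_fit(g, spec, -100.0, 1, 100, 0.9, 0.01)
    f2 = _fake_fit(g, spec, -100.0, 1, 100, 0.8, 0.01)
    res = cmr.model_average([f1, f2])
    assert np.allclose(res.table["weight"], 0.5)
    assert res.averaged["estimate"].iloc[0] == pytest.approx(0.85)

    # single retained model: average is that model
    res1 = cmr.model_average([f1])
    assert res1.averaged["estimate"].iloc[0] == pytest.approx(0.9)
    assert res1.averaged["se_unconditional"].iloc[0] == pytest.approx(0.01)

    # deltas 0, 2, 20: third excluded; weights proportional to 1, e^-1
    f3 = [_fake_fit(g, spec, ll, 1, 100, e, 0.01)
          for ll, e in [(-100.0, 0.9), (-101.0, 0.8), (-110.0, 0.7)]]
    res3 = cmr.model_average(f3)
    t = res3.table.sort_values("delta")
    assert list(t["retained"]) == [True, True, False]
    w = t["weight"].to_numpy()
    assert w[1] / w[0] == pytest.approx(np.exp(-1.0))
    assert w[2] == 0.0
    # averaged estimate stays inside the hull of the retained estimates
    est = res3.averaged["estimate"].iloc[0]
    assert 0.8 <= est <= 0.9


def test_model_average_requires_converged():
    g = _group(T=2, d=(1.0,), habitats=("coastal",))
    f = _fake_fit(g, cmr.CJSModelSpec(), -100.0, 1, 100, 0.9, 0.01)
    f.converged = False
    with pytest.raises(ValueError):
        cmr.model_average([f])


# ---------------------------------------------------------------------------
# overdispersion
# ---------------------------------------------------------------------------

def test_chat_saturated_model_flagged(rng):
    g = _group(T=3, d=(25.0, 40.0))
    phi = np.array([0.99 ** 25, 0.99 ** 40]); p = np.array([0.8, 1.0])
    h = cmr.simulate_histories(rng, g, {2019: (phi, p)}, {2019: 300})
    fit = cmr.fit_cjs(h, g, cmr.CJSModelSpec(phi_terms=("habitat",)), seed=0)
    ce = cmr.estimate_chat(fit, h, n_boot=5, median_points=2, median_reps=2)
    assert ce.flagged and ce.chat_for_ic == 1.0


def test_chat_detects_duplication_overdispersion(rng):
    g = cmr.PathwayGroup("gg", ("R",), ("rel", "FW", "In", "C"),
                         ("freshwater", "marine_inlet", "coastal"),
                         (5.0, 25.0, 40.0))
    phi = np.array([1.0, 0.99 ** 25, 0.99 ** 40])
    p = np.array([0.9, 0.8, 1.0])
    spec = cmr.CJSModelSpec(phi_terms=("habitat",), p_terms=("array",))
    h = cmr.simulate_histories(rng, g, {2019: (phi, p)}, {2019: 150})
    h3 = pd.concat([h] * 3, ignore_index=True)
    fit3 = cmr.fit_cjs(h3, g, spec, seed=0)
    ce = cmr.estimate_chat(fit3, h3, n_boot=40, median_points=4,
                           median_reps=8, seed=1)
    assert ce.chat > 1.0
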