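"""Reference tables, rejection, model choice, parameter estimation and
confidence evaluation for scenario-based ABC.

The workflow follows the classic rejection + regression recipe: simulate a
reference table from the priors of each competing scenario, normalise the
summary statistics by their median absolute deviation (MAD), retain the
closest fraction of rows by Euclidean distance to the observed vector,
then (i) read scenario posterior probabilities off the retained rows
directly and via multinomial logistic regression, and (ii) estimate the
parameters of the winning scenario by local-linear (logit-transformed)
regression adjustment of the retained draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scenario import ScenarioSpec, draw_parameters
from .simulate import LocusModel, simulate_dataset
from .stats import summary_statistics

logger = logging.getLogger(__name__)

DEFAULT_RETAIN_FRACTION = 0.01
DEFAULT_N_CLOSEST_DIRECT = 500


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Simulated (scenario, parameter vector, statistic vector) records."""

    scenario_ids: np.ndarray          # (n,) str
    params: pd.DataFrame              # (n, P) union of parameter names, NaN-padded
    stats: pd.DataFrame               # (n, S)
    mad: np.ndarray                   # (S,) per-stat normalisation constants
    scenarios: dict[str, ScenarioSpec] = field(default_factory=dict)
    locus_model: LocusModel | None = None
    plan: dict[str, int] | None = None

    @property
    def n_rows(self) -> int:
        return len(self.stats)

    def normalised(self) -> np.ndarray:
        w = np.where(self.mad > 0, self.mad, np.inf)  # zero-MAD stats drop out
        return self.stats.to_numpy() / w

    def normalise_observed(self, observed: np.ndarray) -> np.ndarray:
        w = np.where(self.mad > 0, self.mad, np.inf)
        return np.asarray(observed, dtype=float) / w


def _row_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def build_reference_table(
    scenarios: list[ScenarioSpec],
    n_per_scenario: int,
    plan: dict[str, int],
    locus_model: LocusModel,
    seed: int = 0,
) -> ReferenceTable:
    """Simulate *n_per_scenario* datasets per scenario and tabulate stats.

    Deterministic under *seed*: every row draws from its own counter-keyed
    substream, so any parallel partitioning of rows reproduces the serial
    result.
    """
    ids, param_rows, stat_rows = [], [], []
    names = None
    for si, spec in enumerate(scenarios):
        for row in range(n_per_scenario):
            rng = _row_rng(seed, si, row)
            try:
                params = draw_parameters(spec, rng, locus_model=locus_model)
                ds = simulate_dataset(spec, params, plan, locus_model, rng)
                vec, names = summary_statistics(ds)
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed for scenario {spec.id}, row {row}: {exc}"
                ) from exc
            ids.append(spec.id)
            param_rows.append(params)
            stat_rows.append(vec)
    stats = pd.DataFrame(np.vstack(stat_rows), columns=names)
    med = stats.median(axis=0)
    mad = (stats - med).abs().median(axis=0).to_numpy()
    if np.any(mad == 0):
        zero = [names[i] for i in np.flatnonzero(mad == 0)]
        logger.warning("zero-MAD statistics excluded from distances: %s", zero)
    return ReferenceTable(
        scenario_ids=np.array(ids),
        params=pd.DataFrame(param_rows),
        stats=stats,
        mad=mad,
        scenarios={s.id: s for s in scenarios},
        locus_model=locus_model,
        plan=dict(plan),
    )


# ---------------------------------------------------------------------------
# Rejection
# ---------------------------------------------------------------------------

@dataclass
class RetainedSet:
    indices: np.ndarray   # row indices, ascending distance (ties by row index)
    distances: np.ndarray


def reject_closest(
    table: ReferenceTable,
    observed: np.ndarray,
    fraction: float = DEFAULT_RETAIN_FRACTION,
    subset: np.ndarray | None = None,
) -> RetainedSet:
    """Retain the ceil(fraction x rows) rows closest to *observed*.

    Euclidean distance on MAD-normalised statistics; ties broken by row
    index.  ``subset`` optionally restricts candidate rows.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    z = table.normalised()
    obs = table.normalise_observed(observed)
    if obs.shape[0] != z.shape[1]:
        raise ValueError(
            f"observed vector length {obs.shape[0]} != table stats {z.shape[1]}"
        )
    cand = np.arange(table.n_rows) if subset is None else np.asarray(subset)
    d = np.sqrt(np.sum((z[cand] - obs) ** 2, axis=1))
    n_keep = math.ceil(fraction * cand.size)
    order = np.argsort(d, kind="stable")[:n_keep]
    return RetainedSet(indices=cand[order], distances=d[order])


# ---------------------------------------------------------------------------
# Scenario posterior probability
# ---------------------------------------------------------------------------

@dataclass
class ScenarioPosterior:
    """Per-scenario probabilities with 95% CIs (direct and/or logistic)."""

    probabilities: pd.DataFrame  # index scenario, columns p, lo, hi
    method: str
    flagged: bool = False

    @property
    def best(self) -> str:
        return str(self.probabilities["p"].idxmax())


def posterior_direct(
    table: ReferenceTable,
    retained: RetainedSet,
    n_closest: int = DEFAULT_N_CLOSEST_DIRECT,
) -> ScenarioPosterior:
    """Scenario probabilities as shares among the *n_closest* retained rows,
    with normal-approximation multinomial 95% CIs."""
    if n_closest <= 0:
        raise ValueError("n_closest must be positive")
    take = retained.indices[: min(n_closest, retained.indices.size)]
    n = take.size
    labels = table.scenario_ids[take]
    all_ids = sorted(set(table.scenario_ids.tolist()))
    rows = []
    for sid in all_ids:
        p = float(np.mean(labels == sid))
        half = 1.96 * math.sqrt(p * (1.0 - p) / n)
        rows.append({"scenario": sid, "p": p,
                     "lo": max(0.0, p - half), "hi": min(1.0, p + half)})
    df = pd.DataFrame(rows).set_index("scenario")
    return ScenarioPosterior(probabilities=df, method="direct")


def _softmax_probs_and_ci(intercepts, cov, order):
    """Probabilities at the origin and delta-method 95% CIs.

    ``intercepts``: (K-1,) non-baseline linear predictors at x = 0;
    ``cov``: covariance of those intercepts.
    """
    eta = np.concatenate([[0.0], intercepts])
    eta -= eta.max()
    p = np.exp(eta) / np.exp(eta).sum()
    k = eta.size
    rows = []
    for j in range(k):
        # d p_j / d eta_m  (m = 1..K-1, baseline excluded)
        grad = np.array([
            p[j] * ((1.0 if m == j else 0.0) - p[m]) for m in range(1, k)
        ])
        var = float(grad @ cov @ grad)
        half = 1.96 * math.sqrt(max(var, 0.0))
        rows.append({"scenario": order[j], "p": float(p[j]),
                     "lo": max(0.0, p[j] - half), "hi": min(1.0, p[j] + half)})
    return pd.DataFrame(rows).set_index("scenario")


def _ridge_multinomial(y, X, lam=1e-3):
    """Ridge-penalised multinomial logit fallback for separated data.

    Returns (coef matrix (K-1, 1+S), covariance of intercepts) from the
    penalised Hessian.
    """
    from scipy.optimize import minimize

    k = int(y.max()) + 1
    n, s = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    onehot = np.eye(k)[y]

    def nll(beta_flat):
        beta = beta_flat.reshape(k - 1, s + 1)
        eta = np.hstack([np.zeros((n, 1)), Xd @ beta.T])
        eta -= eta.max(axis=1, keepdims=True)
        logz = np.log(np.exp(eta).sum(axis=1))
        ll = (eta * onehot).sum() - logz.sum()
        grad_p = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
        grad = ((grad_p - onehot)[:, 1:]).T @ Xd + 2 * lam * beta
        return -ll + lam * np.sum(beta**2), grad.ravel()

    res = minimize(nll, np.zeros((k - 1) * (s + 1)), jac=True, method="L-BFGS-B")
    beta = res.x.reshape(k - 1, s + 1)
    # numeric Hessian over the intercept block only
    eps = 1e-5
    m = k - 1
    hess = np.zeros((m, m))
    def grad_intercepts(b):
        g = nll(b.ravel())[1].reshape(k - 1, s + 1)
        return g[:, 0]
    for a in range(m):
        bp = beta.copy(); bp[a, 0] += eps
        bm = beta.copy(); bm[a, 0] -= eps
        hess[:, a] = (grad_intercepts(bp) - grad_intercepts(bm)) / (2 * eps)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((m, m), np.nan)
    return beta, cov


def posterior_logistic(
    table: ReferenceTable,
    observed: np.ndarray,
    fraction: float = DEFAULT_RETAIN_FRACTION,
) -> ScenarioPosterior:
    """Multinomial logistic regression of scenario label on centred stats
    over the retained rows, evaluated at the observed point (the origin).

    95% CIs by the delta method on the fitted intercepts.  On complete
    separation or non-convergence the fit is redone with a small ridge
    penalty and flagged.
    """
    retained = reject_closest(table, observed, fraction)
    idx = retained.indices
    labels = table.scenario_ids[idx]
    present = sorted(set(labels.tolist()))
    all_ids = sorted(set(table.scenario_ids.tolist()))
    if len(present) < 2:
        # all retained rows from one scenario: degenerate but well-defined
        rows = [{"scenario": sid,
                 "p": 1.0 if sid in present else 0.0,
                 "lo": 1.0 if sid in present else 0.0,
                 "hi": 1.0 if sid in present else 0.0} for sid in all_ids]
        return ScenarioPosterior(pd.DataFrame(rows).set_index("scenario"),
                                 method="logistic", flagged=True)
    z = table.normalised()[idx]
    obs = table.normalise_observed(observed)
    keep = np.isfinite(obs)
    X = z[:, keep] - obs[keep]
    code = {sid: i for i, sid in enumerate(present)}
    y = np.array([code[sid] for sid in labels])

    flagged = False
    df = None
    try:
        import statsmodels.api as sm

        with np.errstate(all="ignore"):
            fit = sm.MNLogit(y, sm.add_constant(X, has_constant="add")).fit(
                method="lbfgs", maxiter=500, disp=False
            )
        converged = bool(fit.mle_retvals.get("converged", False))
        params = np.asarray(fit.params)  # (1+S, K-1)
        if converged and np.all(np.isfinite(params)) and np.max(np.abs(params)) < 1e3:
            intercepts = params[0, :]
            cov_full = np.asarray(fit.cov_params())
            # intercept entries sit at stride (1+S) in the flattened order
            stride = params.shape[0]
            pos = [j * stride for j in range(params.shape[1])]
            cov = cov_full[np.ix_(pos, pos)]
            if np.all(np.isfinite(cov)):
                df = _softmax_probs_and_ci(intercepts, cov, present)
    except Exception:
        df = None
    if df is None:
        logger.warning("logistic fit unstable (separation?); ridge refit used")
        flagged = True
        beta, cov = _ridge_multinomial(y, X)
        df = _softmax_probs_and_ci(beta[:, 0], cov, present)
    for sid in all_ids:
        if sid not in df.index:
            df.loc[sid] = [0.0, 0.0, 0.0]
    df = df.loc[all_ids]
    # renormalise tiny numeric drift
    df["p"] = df["p"] / df["p"].sum()
    return ScenarioPosterior(probabilities=df, method="logistic", flagged=flagged)


# ---------------------------------------------------------------------------
# Parameter estimation (local-linear regression adjustment)
# ---------------------------------------------------------------------------

@dataclass
class ParameterPosterior:
    """Posterior summaries and the weighted adjusted sample behind them."""

    summary: pd.DataFrame            # index parameter: mean, median, q05, q95
    sample: pd.DataFrame             # adjusted parameter draws
    weights: np.ndarray              # Epanechnikov weights of the draws
    skipped: list[str] = field(default_factory=list)


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return float(np.interp(q, cw, x))


def _param_bounds(spec: ScenarioSpec, locus_model: LocusModel | None, name: str):
    if name == "mu" and locus_model is not None:
        pr = locus_model.mu_prior
    elif name == "P" and locus_model is not None:
        pr = locus_model.p_prior
    else:
        pr = spec.priors[name]
    if pr.dist == "loguniform":
        return math.log(pr.low), math.log(pr.high), True
    return pr.low, pr.high, False


def estimate_parameters(
    table: ReferenceTable,
    observed: np.ndarray,
    scenario: str,
    fraction: float = DEFAULT_RETAIN_FRACTION,
    min_retained: int = 200,
) -> ParameterPosterior:
    """Beaumont-style local-linear adjusted posterior for one scenario.

    Retained draws are logit-mapped to the real line using their prior
    bounds, regression-adjusted toward the observed statistics under
    Epanechnikov weights, back-transformed, and summarised by weighted
    mean, median and 90% equal-tail interval (Q0.05, Q0.95).
    """
    spec = table.scenarios.get(scenario)
    if spec is None:
        raise KeyError(f"scenario {scenario!r} not in table")
    subset = np.flatnonzero(table.scenario_ids == scenario)
    retained = reject_closest(table, observed, fraction, subset=subset)
    idx = retained.indices
    if idx.size < min_retained:
        raise ValueError(
            f"only {idx.size} retained rows for scenario {scenario} "
            f"(need >= {min_retained}); enlarge the table or the fraction"
        )
    d = retained.distances
    dmax = d.max()
    w = 1.0 - (d / dmax) ** 2 if dmax > 0 else np.ones_like(d)
    w = np.maximum(w, 1e-12)

    z = table.normalised()[idx]
    obs = table.normalise_observed(observed)
    keep = np.isfinite(obs)
    X = z[:, keep] - obs[keep]
    Xd = np.hstack([np.ones((X.shape[0], 1)), X])
    sw = np.sqrt(w)

    names = [c for c in table.params.columns
             if np.isfinite(table.params[c].to_numpy()[idx]).all()]
    adjusted = {}
    skipped = []
    rows = []
    for name in names:
        raw = table.params[name].to_numpy()[idx].astype(float)
        lo, hi, is_log = _param_bounds(spec, table.locus_model, name)
        vals = np.log(raw) if is_log else raw
        u = (vals - lo) / (hi - lo)
        at_bound = np.mean((u < 1e-9) | (u > 1 - 1e-9))
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        t = np.log(u / (1.0 - u))
        if at_bound > 0.5:
            logger.warning(
                "parameter %s pinned at a prior bound in %.0f%% of retained "
                "rows; regression adjustment skipped", name, 100 * at_bound,
            )
            skipped.append(name)
            t_adj = t
        else:
            beta, *_ = np.linalg.lstsq(Xd * sw[:, None], t * sw, rcond=None)
            t_adj = t - X @ beta[1:]
        u_adj = 1.0 / (1.0 + np.exp(-t_adj))
        vals_adj = lo + u_adj * (hi - lo)
        back = np.exp(vals_adj) if is_log else vals_adj
        adjusted[name] = back
        rows.append({
            "parameter": name,
            "mean": float(np.average(back, weights=w)),
            "median": _weighted_quantile(back, w, 0.5),
            "q05": _weighted_quantile(back, w, 0.05),
            "q95": _weighted_quantile(back, w, 0.95),
        })
    summary = pd.DataFrame(rows).set_index("parameter")
    return ParameterPosterior(
        summary=summary,
        sample=pd.DataFrame(adjusted),
        weights=w,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Confidence evaluation on pseudo-observed datasets
# ---------------------------------------------------------------------------

def _pod_winner(table, spec, plan, locus_model, fraction, rng):
    params = draw_parameters(spec, rng, locus_model=locus_model)
    ds = simulate_dataset(spec, params, plan, locus_model, rng)
    vec, _ = summary_statistics(ds)
    return posterior_logistic(table, vec, fraction).best


def type1_error(
    table: ReferenceTable,
    focal: str,
    n_pods: int = 500,
    fraction: float = DEFAULT_RETAIN_FRACTION,
    seed: int = 0,
) -> float:
    """Fraction of pods simulated under *focal* where it does not win."""
    spec = table.scenarios[focal]
    losses = 0
    for p in range(n_pods):
        rng = _row_rng(seed, 10_001, p)
        if _pod_winner(table, spec, table.plan, table.locus_model,
                       fraction, rng) != focal:
            losses += 1
    return losses / n_pods


def type2_error(
    table: ReferenceTable,
    focal: str,
    n_pods: int = 500,
    fraction: float = DEFAULT_RETAIN_FRACTION,
    seed: int = 0,
) -> dict[str, float]:
    """Per competitor: fraction of its pods that *focal* wins (false positive)."""
    out = {}
    for ci, (sid, spec) in enumerate(sorted(table.scenarios.items())):
        if sid == focal:
            continue
        wins = 0
        for p in range(n_pods):
            rng = _row_rng(seed, 20_001 + ci, p)
            if _pod_winner(table, spec, table.plan, table.locus_model,
                           fraction, rng) == focal:
                wins += 1
        out[sid] = wins / n_pods
    return out


# ---------------------------------------------------------------------------
# Posterior-predictive model checking
# ---------------------------------------------------------------------------

def model_check(
    table: ReferenceTable,
    posterior: ParameterPosterior,
    scenario: str,
    observed: np.ndarray,
    n_sims: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Tail probability of each observed statistic under the posterior
    predictive: the fraction of simulated values below the observed one,
    flagged outside (0.005, 0.995) (two-sided at P < 0.01)."""
    spec = table.scenarios[scenario]
    sample = posterior.sample
    w = posterior.weights / posterior.weights.sum()
    sims = []
    for s in range(n_sims):
        rng = _row_rng(seed, 30_001, s)
        row = sample.iloc[int(rng.choice(len(sample), p=w))]
        params = {k: float(v) for k, v in row.items()}
        ds = simulate_dataset(spec, params, table.plan, table.locus_model, rng)
        vec, names = summary_statistics(ds)
        sims.append(vec)
    sims = np.vstack(sims)
    obs = np.asarray(observed, dtype=float)
    tail = np.mean(sims < obs[None, :], axis=0)
    return pd.DataFrame({
        "stat": list(table.stats.columns),
        "tail_prob": tail,
        "flagged": (tail < 0.005) | (tail > 0.995),
    }).set_index("stat")


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

def generations_to_years(
    generations: float,
    gen_time_low: float = 80.0,
    gen_time_high: float = 110.0,
) -> tuple[int, int]:
    """Convert a time in generations to a calendar range in years BP.

    With the walnut generation time of 80-110 years, e.g. 579 generations
    maps to (46320, 63690) years BP.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if not 0 < gen_time_low <= gen_time_high:
        raise ValueError("need 0 < gen_time_low <= gen_time_high")
    return (
        round(generations * gen_time_low),
        round(generations * gen_time_high),
    )


def decline_percent(size_before: float, size_after: float) -> float:
    """Percent loss of effective size, e.g. 8040 -> 6320 gives 21.4%."""
    if size_before <= 0:
        raise ValueError("size_before must be positive")
    return 100.0 * (1.0 - size_after / size_before)
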