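"""Random-intercept logistic regression by adaptive Gauss-Hermite quadrature,
with AICc model comparison, likelihood-ratio tests, and Tukey-type
single-step contrasts.

Model
-----
For individual ``i`` and session ``j``, the binary outcome ``y_ij`` (did the
individual direct aggression at visitors in that session) follows

    y_ij ~ Bernoulli(mu_ij),   logit(mu_ij) = x_ij' beta + b_i,
    b_i ~ Normal(0, sigma_b^2),

with fixed effects drawn from {standardized Elo rating, midpoint-coded crowd
size, three-level crowd activity (reference: calm)}.  The marginal likelihood
integrates each ``b_i`` out numerically: the integrand is re-centered at its
per-group mode and re-scaled by its curvature before applying Gauss-Hermite
quadrature (adaptive GHQ), which keeps the node placement effective even when
a group contributes thousands of Bernoulli terms and its posterior is far
from the prior.  An optional independent random slope on the rating covariate
extends the integral to two dimensions (tensor-grid GHQ).

Estimation maximizes the marginal log-likelihood over (beta, sigma) with
L-BFGS-B from deterministic starts (plain-logistic fixed effects, sigma = 1);
the score is computed exactly at the quadrature approximation via posterior-
weighted residuals.  Wald standard errors come from the inverse observed
information (finite differences of the analytic score).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit
from scipy.stats import qmc

from .errors import ConvergenceError, DomainError, SeparationError

logger = logging.getLogger(__name__)

FIXED_TERM_ORDER = ("elo_z", "crowd_size_value", "crowd_activity")
ACTIVITY_LEVELS = ("calm", "moderate", "frenetic")
TERM_LABELS = {
    "elo_z": "Rank",
    "crowd_size_value": "Crowd Size",
    "crowd_activity": "Crowd Activity",
}


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one candidate model.  The per-individual
    random intercept is always present; ``random_slope`` adds an independent
    random slope on ``elo_z``."""

    fixed_terms: tuple = ()
    random_slope: bool = False

    def __post_init__(self):
        unknown = set(self.fixed_terms) - set(FIXED_TERM_ORDER)
        if unknown:
            raise DomainError(f"unknown fixed terms {sorted(unknown)}")
        ordered = tuple(t for t in FIXED_TERM_ORDER if t in self.fixed_terms)
        object.__setattr__(self, "fixed_terms", ordered)

    @property
    def label(self) -> str:
        if not self.fixed_terms:
            return "Intercept only"
        return " + ".join(TERM_LABELS[t] for t in self.fixed_terms)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.fixed_terms) <= set(other.fixed_terms) and (
            self.random_slope == other.random_slope
        )


def design_matrix(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list]:
    """Fixed-effect design: intercept first, then terms in canonical order;
    crowd activity expands to moderate/frenetic indicators (calm reference)."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for term in spec.fixed_terms:
        if term == "crowd_activity":
            act = table["crowd_activity"].astype(str)
            bad = set(act.unique()) - set(ACTIVITY_LEVELS)
            if bad:
                raise DomainError(f"unknown crowd_activity levels {sorted(bad)}")
            for level in ("moderate", "frenetic"):
                cols.append((act == level).to_numpy(dtype=float))
                names.append(f"crowd_activity[{level}]")
        else:
            cols.append(table[term].to_numpy(dtype=float))
            names.append(term)
    return np.column_stack(cols), names


@dataclass
class GLMMFit:
    spec: ModelSpec
    term_names: list
    coefficients: dict
    sigma_b: float
    sigma_slope: float | None
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    diagnostics: str
    group_ids: list
    random_modes: dict  # individual_id -> posterior-mode intercept b_i
    _vcov_fn: object = field(repr=False, default=None)
    _vcov_cache: object = field(repr=False, default=None)

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in self.term_names])

    @property
    def vcov_fixed(self) -> np.ndarray:
        """Fixed-effect covariance from the inverse observed information;
        computed on first access (model ranking does not need it)."""
        if self._vcov_cache is None:
            self._vcov_cache = self._vcov_fn()
        return self._vcov_cache

    @property
    def wald_se(self) -> dict:
        se = np.sqrt(np.abs(np.diag(self.vcov_fixed)))
        return dict(zip(self.term_names, se))

    @property
    def ci95(self) -> dict:
        se = self.wald_se
        return {
            t: (self.coefficients[t] - 1.96 * se[t], self.coefficients[t] + 1.96 * se[t])
            for t in self.term_names
        }

    def coefficient_frame(self) -> pd.DataFrame:
        rows = [
            (t, self.coefficients[t], self.ci95[t][0], self.ci95[t][1], self.wald_se[t])
            for t in self.term_names
        ]
        return pd.DataFrame(rows, columns=["term", "beta", "lower95", "upper95", "se"])


class _GroupData:
    """Per-group arrays: fixed design X (n,p), outcomes y (n,), random design
    U (n,d) with a leading all-ones column (and elo_z if a random slope)."""

    def __init__(self, X, y, U):
        self.X, self.y, self.U = X, y, U


def _prepare_groups(table: pd.DataFrame, spec: ModelSpec):
    X, names = design_matrix(table, spec)
    y = table["outcome"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DomainError("outcome must be binary 0/1")
    d = 2 if spec.random_slope else 1
    groups = []
    ids = []
    for gid, idx in table.groupby("individual_id", sort=True).indices.items():
        Xg, yg = X[idx], y[idx]
        Ug = np.ones((len(idx), 1))
        if spec.random_slope:
            Ug = np.column_stack([Ug, table["elo_z"].to_numpy(dtype=float)[idx]])
        groups.append(_GroupData(Xg, yg, Ug))
        ids.append(gid)
    return groups, ids, names, X, y


def _bern_loglik(y, eta):
    # y*eta - log(1 + e^eta), numerically stable
    return y * eta - np.logaddexp(0.0, eta)


def _group_mode(g: _GroupData, beta, sigma):
    """Posterior mode of z (standardized random effect) for one group, by
    damped Newton on the strictly concave objective h(z)."""
    d = g.U.shape[1]
    eta0 = g.X @ beta
    Us = g.U * sigma  # (n, d)

    def h(z):
        eta = eta0 + Us @ z
        return _bern_loglik(g.y, eta).sum() - 0.5 * z @ z

    # gradient components scale with the group size, so the stopping rule must
    # be relative: round-off in the score is ~1e-12 per observation
    gtol = 1e-9 * max(1.0, len(g.y))
    z = np.zeros(d)
    hz = h(z)
    for _ in range(50):
        mu = expit(eta0 + Us @ z)
        grad = Us.T @ (g.y - mu) - z
        if np.abs(grad).max() < gtol:
            break
        w = mu * (1.0 - mu)
        H = -(Us.T @ (Us * w[:, None])) - np.eye(d)
        step = np.linalg.solve(H, grad)
        z_new = z - step
        h_new = h(z_new)
        halvings = 0
        while h_new < hz - 1e-9 * max(1.0, abs(hz)) and halvings < 20:
            step *= 0.5
            z_new = z - step
            h_new = h(z_new)
            halvings += 1
        z, hz = z_new, h_new
        if np.abs(step).max() < 1e-10:
            break
    mu = expit(eta0 + Us @ z)
    w = mu * (1.0 - mu)
    neg_hess = Us.T @ (Us * w[:, None]) + np.eye(d)
    return z, neg_hess, eta0, Us


def _make_grid(nodes: int, d: int):
    t, w = hermgauss(nodes)
    if d == 1:
        T = t[:, None]
        logw = np.log(w)
        sq = t**2
    else:
        T = np.array(list(itertools.product(t, repeat=d)))
        logw = np.add.outer(np.log(w), np.log(w)).ravel()
        sq = (T**2).sum(axis=1)
    return T, logw, sq


def _group_ll_and_score(g, beta, sigma, T, logw, sq, want_score):
    d = g.U.shape[1]
    zhat, neg_hess, eta0, Us = _group_mode(g, beta, sigma)
    cov = np.linalg.inv(neg_hess)
    A = np.linalg.cholesky(cov)
    Z = zhat + math.sqrt(2.0) * (T @ A.T)  # (K, d)
    eta = eta0[:, None] + Us @ Z.T  # (n, K)
    hk = _bern_loglik(g.y[:, None], eta).sum(axis=0) - 0.5 * (Z**2).sum(axis=1)
    a = hk + sq + logw
    amax = a.max()
    lse = amax + np.log(np.exp(a - amax).sum())
    ll = (
        lse
        + np.log(np.diag(A)).sum()
        + 0.5 * d * math.log(2.0)
        - 0.5 * d * math.log(2.0 * math.pi)
    )
    if not want_score:
        return ll, None, None, zhat
    omega = np.exp(a - lse)  # posterior quadrature weights, sum to 1
    resid = g.y[:, None] - expit(eta)  # (n, K)
    wr = resid @ omega  # (n,)
    g_beta = g.X.T @ wr
    s = g.U.T @ resid  # (d, K)
    g_sigma = (omega * Z.T * s).sum(axis=1)  # (d,)
    return ll, g_beta, g_sigma, zhat


def marginal_loglik(
    table: pd.DataFrame,
    spec: ModelSpec,
    beta: np.ndarray,
    sigma_b: float,
    sigma_slope: float = 0.0,
    quadrature_nodes: int = 25,
) -> float:
    """Marginal log-likelihood at given parameters (public for cross-checks)."""
    groups, _, names, _, _ = _prepare_groups(table, spec)
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != len(names):
        raise DomainError(f"beta must have {len(names)} entries ({names})")
    d = 2 if spec.random_slope else 1
    sigma = np.array([sigma_b, sigma_slope][:d], dtype=float)
    nodes = quadrature_nodes if d == 1 else min(quadrature_nodes, 11)
    T, logw, sq = _make_grid(nodes, d)
    return float(
        sum(_group_ll_and_score(g, beta, sigma, T, logw, sq, False)[0] for g in groups)
    )


def _separating_term(X, y, names):
    """A single covariate whose outcome-1 and outcome-0 supports do not
    overlap completely separates the data; return its name, else None."""
    for j in range(1, X.shape[1]):
        x1, x0 = X[y == 1.0, j], X[y == 0.0, j]
        if len(x1) and len(x0) and (x1.min() > x0.max() or x1.max() < x0.min()):
            return names[j]
    return None


def _start_values(X, y, names):
    import statsmodels.api as sm

    term = _separating_term(X, y, names)
    if term is not None:
        raise SeparationError(term)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = np.asarray(res.params, dtype=float)
    except Exception:  # statsmodels raises PerfectSeparationError or LinAlgError
        params = np.zeros(X.shape[1])
        params[0] = math.log(max(y.mean(), 1e-6) / max(1 - y.mean(), 1e-6))
        return params
    if np.abs(params).max() > 20.0:
        raise SeparationError(names[int(np.argmax(np.abs(params)))])
    return params


def fit_glmm(
    outcome_table: pd.DataFrame,
    spec: ModelSpec,
    quadrature_nodes: int = 25,
    tol: float = 1e-8,
    fix_sigma: float | None = None,
) -> GLMMFit:
    """Maximize the marginal likelihood of the random-intercept logistic model.

    Parameters
    ----------
    outcome_table
        Modeling table with columns ``outcome``, ``individual_id`` and the
        covariates named by ``spec``.
    quadrature_nodes
        Gauss-Hermite nodes per random-effect dimension (capped at 11 per
        dimension for the two-dimensional random-slope model).
    tol
        Relative log-likelihood change at which the optimizer stops.
    fix_sigma
        If given, the random-intercept SD is held at this value (0 reduces
        the model to ordinary logistic regression) instead of estimated.
    """
    table = outcome_table
    y_all = table["outcome"].to_numpy(dtype=float)
    if y_all.min() == y_all.max():
        raise DomainError("outcome is constant; the model is not identifiable")
    groups, ids, names, X, y = _prepare_groups(table, spec)
    if fix_sigma is None and len(groups) < 2:
        raise DomainError("need >= 2 grouping levels to estimate sigma_b")

    d = 2 if spec.random_slope else 1
    nodes = quadrature_nodes if d == 1 else min(quadrature_nodes, 11)
    T, logw, sq = _make_grid(nodes, d)
    p = len(names)
    estimate_sigma = fix_sigma is None

    def unpack(x):
        beta = x[:p]
        if estimate_sigma:
            sigma = x[p:]
        else:
            sigma = np.array([fix_sigma] * d, dtype=float)
        return beta, sigma

    def nll_and_grad(x):
        beta, sigma = unpack(x)
        total = 0.0
        gb = np.zeros(p)
        gs = np.zeros(d)
        for g in groups:
            ll, g_beta, g_sigma, _ = _group_ll_and_score(g, beta, sigma, T, logw, sq, True)
            total += ll
            gb += g_beta
            gs += g_sigma
        grad = np.concatenate([gb, gs]) if estimate_sigma else gb
        return -total, -grad

    beta0 = _start_values(X, y, names)
    x0 = np.concatenate([beta0, np.ones(d)]) if estimate_sigma else beta0
    bounds = [(None, None)] * p + ([(0.0, None)] * d if estimate_sigma else [])

    res = optimize.minimize(
        nll_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": tol, "gtol": 1e-7, "maxiter": 500},
    )
    beta_hat, sigma_hat = unpack(res.x)
    converged = bool(res.success)
    if not converged:
        logger.warning("fit_glmm did not converge: %s", res.message)

    x_opt = res.x

    def compute_vcov_fixed() -> np.ndarray:
        # observed information from central differences of the analytic score
        m = len(x_opt)
        H = np.zeros((m, m))
        for j in range(m):
            h = 1e-5 * max(1.0, abs(x_opt[j]))
            xp, xm = x_opt.copy(), x_opt.copy()
            xp[j] += h
            xm[j] -= h
            # at the sigma >= 0 boundary fall back to a one-sided step
            if estimate_sigma and j >= p and xm[j] < 0:
                xm = x_opt.copy()
                denom = h
            else:
                denom = 2.0 * h
            _, gp = nll_and_grad(xp)
            _, gm = nll_and_grad(xm)
            H[:, j] = (gp - gm) / denom
        H = 0.5 * (H + H.T)
        try:
            vcov = np.linalg.inv(H)
            if not np.all(np.diag(vcov)[:p] > 0):
                raise np.linalg.LinAlgError("non-positive variance")
            return vcov[:p, :p]
        except np.linalg.LinAlgError:
            try:
                return np.linalg.inv(H[:p, :p])
            except np.linalg.LinAlgError:
                return np.linalg.pinv(H[:p, :p])

    loglik = -res.fun
    # posterior-mode intercepts for diagnostics
    modes = {}
    for gid, g in zip(ids, groups):
        zhat, _, _, _ = _group_mode(g, beta_hat, sigma_hat)
        modes[gid] = float(sigma_hat[0] * zhat[0])

    coefficients = dict(zip(names, beta_hat))
    n_params = p + (d if estimate_sigma else 0)
    return GLMMFit(
        spec=spec,
        term_names=names,
        coefficients=coefficients,
        sigma_b=float(sigma_hat[0]),
        sigma_slope=float(sigma_hat[1]) if d == 2 else None,
        loglik=float(loglik),
        n_obs=len(table),
        n_params=n_params,
        converged=converged,
        diagnostics=str(res.message),
        group_ids=ids,
        random_modes=modes,
        _vcov_fn=compute_vcov_fixed,
    )


# ---------------------------------------------------------------------------
# Model comparison, tests, contrasts, diagnostics
# ---------------------------------------------------------------------------

def aicc(fit: GLMMFit) -> float:
    """Small-sample Akaike criterion: -2l + 2k + 2k(k+1)/(n-k-1)."""
    if not fit.converged:
        raise DomainError("aicc requires a converged fit")
    k, n = fit.n_params, fit.n_obs
    if n <= k + 1:
        raise DomainError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def default_candidates() -> list[ModelSpec]:
    """The seven candidate models: every non-empty subset of
    {rank, crowd size, crowd activity}, each with the random intercept."""
    specs = []
    for r in (1, 2, 3):
        for combo in itertools.combinations(FIXED_TERM_ORDER, r):
            specs.append(ModelSpec(fixed_terms=combo))
    return specs


@dataclass
class AICcTable:
    table: pd.DataFrame  # model, AICc, n_params, converged, rank
    fits: dict  # label -> GLMMFit

    def best(self) -> GLMMFit:
        ranked = self.table.dropna(subset=["rank"]).sort_values("rank")
        if ranked.empty:
            raise ConvergenceError("no candidate model converged")
        return self.fits[ranked.iloc[0]["model"]]


def compare_models(
    outcome_table: pd.DataFrame,
    candidate_specs: list[ModelSpec] | None = None,
    **fit_kwargs,
) -> AICcTable:
    """Fit all candidates on the identical row set and rank them by AICc
    (ties broken toward fewer parameters, then label).  Non-converged
    candidates are listed with a flag and excluded from the ranking."""
    specs = candidate_specs if candidate_specs is not None else default_candidates()
    rows = []
    fits = {}
    for spec in sorted(specs, key=lambda s: (len(s.fixed_terms), s.label)):
        fit = fit_glmm(outcome_table, spec, **fit_kwargs)
        fits[spec.label] = fit
        value = aicc(fit) if fit.converged else float("nan")
        rows.append((spec.label, value, fit.n_params, fit.converged))
    df = pd.DataFrame(rows, columns=["model", "AICc", "n_params", "converged"])
    ok = df[df["converged"]].sort_values(
        ["AICc", "n_params", "model"], kind="stable"
    )
    df["rank"] = pd.Series(dtype=float)
    df.loc[ok.index, "rank"] = np.arange(1, len(ok) + 1, dtype=float)
    df = df.sort_values(["rank"], na_position="last").reset_index(drop=True)
    return AICcTable(table=df, fits=fits)


@dataclass(frozen=True)
class LRTResult:
    dropped: str
    chi2: float
    df: int
    p: float


def lrt(fit_full: GLMMFit, fit_reduced: GLMMFit) -> LRTResult:
    """Likelihood-ratio test of nested fits on the same rows."""
    if not fit_reduced.spec.is_nested_in(fit_full.spec):
        raise DomainError("reduced model is not nested in the full model")
    if fit_full.n_obs != fit_reduced.n_obs:
        raise DomainError("fits use different row sets")
    df = fit_full.n_params - fit_reduced.n_params
    if df < 1:
        raise DomainError("full model has no extra parameters")
    chi2 = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    dropped = ",".join(
        sorted(set(fit_full.spec.fixed_terms) - set(fit_reduced.spec.fixed_terms))
    )
    return LRTResult(dropped=dropped or "(none)", chi2=chi2, df=df, p=p)


@dataclass(frozen=True)
class ContrastResult:
    pair: tuple
    estimate: float
    se: float
    z: float
    p_unadjusted: float
    p_adjusted: float


def single_step_adjust(
    z_obs: np.ndarray,
    corr: np.ndarray,
    seed: int = 202306,
    n_qmc: int = 2**14,
) -> np.ndarray:
    """Single-step (Tukey-type) adjusted p-values for a family of correlated
    z statistics: ``p_j = P(max_k |Z_k| >= |z_j|)`` under ``Z ~ N(0, corr)``,
    evaluated by scrambled-Sobol quasi-Monte-Carlo with a fixed seed.  The
    estimate is clipped to its provable envelope
    ``[p_unadjusted, min(1, m * p_unadjusted)]``."""
    z_obs = np.atleast_1d(np.asarray(z_obs, dtype=float))
    m = len(z_obs)
    p_unadj = 2.0 * stats.norm.sf(np.abs(z_obs))
    if m == 1:
        return p_unadj
    # the contrast family may be linearly dependent (e.g. all pairwise
    # differences of 3 levels), so factor the correlation by eigendecomposition
    vals, vecs = np.linalg.eigh(corr)
    keep = vals > 1e-10
    A = vecs[:, keep] * np.sqrt(vals[keep])
    r = A.shape[1]
    sob = qmc.Sobol(d=r, scramble=True, seed=seed)
    u = sob.random(n_qmc)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    Z = stats.norm.ppf(u) @ A.T  # (n, m)
    maxabs = np.abs(Z).max(axis=1)
    p_adj = np.array([(maxabs >= abs(z)).mean() for z in z_obs])
    return np.clip(p_adj, p_unadj, np.minimum(1.0, m * p_unadj))


def tukey_contrasts(fit: GLMMFit, seed: int = 202306, n_qmc: int = 2**14) -> list[ContrastResult]:
    """All pairwise log-odds differences among the crowd-activity levels,
    with single-step multiplicity adjustment over the 3-contrast family."""
    if "crowd_activity" not in fit.spec.fixed_terms:
        raise DomainError("fit does not include crowd_activity")
    names = fit.term_names
    idx = {t: i for i, t in enumerate(names)}
    p = len(names)

    def cvec(level_hi, level_lo):
        c = np.zeros(p)
        for lv, sgn in ((level_hi, 1.0), (level_lo, -1.0)):
            if lv != "calm":
                c[idx[f"crowd_activity[{lv}]"]] += sgn
        return c

    pairs = [("moderate", "calm"), ("frenetic", "calm"), ("frenetic", "moderate")]
    C = np.array([cvec(a, b) for a, b in pairs])
    beta = fit.beta
    est = C @ beta
    V = C @ fit.vcov_fixed @ C.T
    se = np.sqrt(np.diag(V))
    z = est / se
    corr = V / np.outer(se, se)
    p_unadj = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = single_step_adjust(z, corr, seed=seed, n_qmc=n_qmc)
    return [
        ContrastResult(
            pair=pairs[j],
            estimate=float(est[j]),
            se=float(se[j]),
            z=float(z[j]),
            p_unadjusted=float(p_unadj[j]),
            p_adjusted=float(p_adj[j]),
        )
        for j in range(len(pairs))
    ]


def residual_diagnostics(
    fit: GLMMFit, outcome_table: pd.DataFrame, n_bins: int = 20
) -> pd.DataFrame:
    """Binned Pearson residuals against fitted probabilities (conditional on
    the posterior-mode random intercepts): per-bin mean residual with a
    +/-2SE reference band.  A machine-readable stand-in for a residual plot."""
    X, _ = design_matrix(outcome_table, fit.spec)
    eta = X @ fit.beta
    b = outcome_table["individual_id"].map(fit.random_modes).to_numpy(dtype=float)
    mu = expit(eta + b)
    y = outcome_table["outcome"].to_numpy(dtype=float)
    r = (y - mu) / np.sqrt(mu * (1.0 - mu))
    df = pd.DataFrame({"fitted": mu, "resid": r})
    n_bins = max(1, min(n_bins, len(df)))
    try:
        df["bin"] = pd.qcut(df["fitted"], q=n_bins, labels=False, duplicates="drop")
        df["bin"] = df["bin"].fillna(0).astype(int)  # constant fits collapse to one bin
    except ValueError:
        df["bin"] = 0
    out = (
        df.groupby("bin")
        .agg(n=("resid", "size"), mean_fitted=("fitted", "mean"), mean_resid=("resid", "mean"))
        .reset_index()
    )
    out["band_halfwidth"] = 2.0 / np.sqrt(out["n"])
    out["inside_band"] = out["mean_resid"].abs() <= out["band_halfwidth"]
    return out
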