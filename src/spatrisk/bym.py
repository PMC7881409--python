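"""Bayesian convolution (BYM) spatial model for area-level relative risks.

The model for area i = 1..n:

    O_i ~ Poisson(E_i * theta_i)
    log theta_i = alpha + beta' x_i + u_i + delta_i

with an exchangeable Normal(0, sigma^2) unstructured effect u, an intrinsic
CAR (ICAR) spatially structured effect delta over the neighbour graph, and
priors alpha ~ N(0, 100), beta_j ~ N(0, 1), sigma ~ half-Normal(0, 1000)
(second arguments are variances), tau_delta ~ Gamma(0.5, 0.0005). The ICAR
prior is improper (flat along the constant direction); it is identified by
recentring delta to sum to zero after every sweep, the subtracted mean being
absorbed into the intercept, and its normalizer uses the rank-aware
(n - k)/2 exponent with k the number of graph components.

Inference is a Metropolis-within-Gibbs sampler written for vectorized
single-site updates: u is updated element-wise in one shot (its sites are
conditionally independent), delta is updated colour class by colour class
of a greedy graph colouring (sites within a class share no edge, so their
full conditionals are mutually independent), alpha and each beta_j by
scalar random walks, log sigma by a random walk, and tau_delta by its
conjugate Gamma full conditional. Proposal step sizes adapt toward a target
acceptance rate during burn-in only and are frozen afterwards, preserving
detailed balance for the retained draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import AdjacencyStructure, StudyDataset, ValidationError

_Z975 = 1.959963984540054


class ConfigurationError(ValueError):
    pass


@dataclass
class BymConfig:
    """Chain settings and prior hyperparameters.

    Second moments follow the variance convention: ``prior_alpha_sd=10``
    means alpha ~ Normal(0, 100). ``winbugs_precision=True`` flips the
    convention and reads the same numbers as precisions. ``sigma_fixed`` /
    ``tau_fixed`` clamp the hyperparameters (used for oracle checks against
    fixed-hyperparameter grid posteriors); ``use_u`` / ``use_delta`` drop a
    random-effect block entirely.
    """

    n_iterations: int = 50_000
    burn_in: int = 2_000
    thin: int = 1
    seed: int = 20080101
    prior_alpha_sd: float = 10.0
    prior_beta_sd: float = 1.0
    prior_sigma_scale: float = np.sqrt(1000.0)
    car_precision_prior: tuple[float, float] = (0.5, 0.0005)
    winbugs_precision: bool = False
    init_step: float = 0.3
    target_accept: float = 0.44
    adapt_interval: int = 50
    sigma_fixed: Optional[float] = None
    tau_fixed: Optional[float] = None
    use_u: bool = True
    use_delta: bool = True

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ConfigurationError("burn_in must be < n_iterations")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        for name in ("prior_alpha_sd", "prior_beta_sd", "prior_sigma_scale"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.winbugs_precision:
            # second arguments were precisions: variance = 1/precision
            self.prior_alpha_sd = 1.0 / np.sqrt(self.prior_alpha_sd**2)
            self.prior_beta_sd = 1.0 / np.sqrt(self.prior_beta_sd**2)
            self.prior_sigma_scale = 1.0 / np.sqrt(self.prior_sigma_scale**2)
            self.winbugs_precision = False


@dataclass
class PosteriorSample:
    """Raw draws from the sampler (every ``thin``-th post-warm-up sweep kept
    by :func:`summarize_posterior`; the arrays here include warm-up so the
    caller chooses the discard)."""

    areas: list[str]
    covariate_names: list[str]
    alpha: np.ndarray  # (S,)
    beta: np.ndarray  # (S, p)
    u: np.ndarray  # (S, n)
    delta: np.ndarray  # (S, n)
    sigma: np.ndarray  # (S,)
    tau: np.ndarray  # (S,)
    theta: np.ndarray  # (S, n) relative risks
    deviance_raw: np.ndarray  # (S,) -2 log L
    deviance_sat: np.ndarray  # (S,) saturated-deviance convention
    observed: np.ndarray  # (n,)
    expected: np.ndarray  # (n,)
    config: BymConfig
    acceptance: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.alpha)

    def retained(self, burn_in: Optional[int] = None, thin: Optional[int] = None):
        b = self.config.burn_in if burn_in is None else burn_in
        t = self.config.thin if thin is None else thin
        sl = slice(b, None, t)
        return sl


@dataclass
class RiskSurface:
    """Per-area posterior relative-risk summaries, ready for mapping."""

    table: pd.DataFrame  # area, rr_mean, rr_median, rr_ci_low, rr_ci_high,
    #                      exceedance_prob


# ---------------------------------------------------------------------------
# ICAR log density


def icar_logdensity(
    delta: np.ndarray, tau: float, adjacency: AdjacencyStructure
) -> float:
    """Unnormalized ICAR log density ((n-k)/2) log tau - (tau/2) sum (di-dj)^2.

    k is the number of connected components (the rank deficiency of the
    graph Laplacian); constant shifts of delta within a component leave the
    density unchanged.
    """
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    delta = np.asarray(delta, dtype=float)
    if delta.size != adjacency.n_areas:
        raise ValidationError("delta length must equal number of areas")
    ii, jj = adjacency.edge_index_arrays()
    ss = float(np.sum((delta[ii] - delta[jj]) ** 2))
    n, k = adjacency.n_areas, adjacency.n_components
    return 0.5 * (n - k) * np.log(tau) - 0.5 * tau * ss


# ---------------------------------------------------------------------------
# Sampler


def _colour_classes(adj: AdjacencyStructure) -> list[np.ndarray]:
    g = adj.graph()
    colouring = nx.greedy_color(g, strategy="largest_first")
    idx = {a: k for k, a in enumerate(adj.areas)}
    classes: dict[int, list[int]] = {}
    for area, c in colouring.items():
        classes.setdefault(c, []).append(idx[area])
    return [np.array(sorted(v), dtype=int) for _, v in sorted(classes.items())]


def fit_bym(
    dataset: StudyDataset,
    covariates: Sequence[str] = (),
    config: Optional[BymConfig] = None,
    sex: str = "both",
) -> PosteriorSample:
    """Run the Metropolis-within-Gibbs sampler; returns every sweep's draws.

    Deterministic under a fixed ``config.seed``: a single generator is
    consumed in a fixed documented order (alpha, beta_1..p, u block, delta
    colour classes in index order, sigma, tau) each sweep.
    """
    config = config or BymConfig()
    if dataset.adjacency is None:
        raise ConfigurationError("dataset has no adjacency structure")
    adj = dataset.adjacency
    if not adj.connected:
        raise ConfigurationError(
            "adjacency graph is disconnected; per-component centring is not "
            "implemented — supply a connected graph"
        )
    recs = dataset.for_sex(sex)
    order = {a: k for k, a in enumerate(adj.areas)}
    recs = sorted(recs, key=lambda r: order[r.area_id])
    y = np.array([r.observed for r in recs], dtype=float)
    E = np.array([r.expected for r in recs], dtype=float)
    if np.any(E <= 0):
        raise ValidationError("expected counts must be > 0")
    n = len(y)
    p = len(covariates)
    X = np.empty((n, p))
    for j, c in enumerate(covariates):
        vals = [getattr(r, c) for r in recs]
        if any(v is None for v in vals):
            raise ValidationError(f"covariate {c!r} missing for some areas")
        X[:, j] = vals

    rng = np.random.default_rng(config.seed)
    logE = np.log(E)
    log_yfact = gammaln(y + 1.0)
    ii, jj = adj.edge_index_arrays()
    W = np.zeros((n, n))
    W[ii, jj] = 1.0
    W[jj, ii] = 1.0
    m = W.sum(axis=1)  # neighbour counts
    colours = _colour_classes(adj)
    rank = n - adj.n_components

    va = config.prior_alpha_sd**2
    vb = config.prior_beta_sd**2
    vs = config.prior_sigma_scale**2
    a0, b0 = config.car_precision_prior

    # state
    alpha = float(np.log(y.sum() / E.sum())) if y.sum() > 0 else 0.0
    beta = np.zeros(p)
    u = np.zeros(n)
    delta = np.zeros(n)
    sigma = config.sigma_fixed if config.sigma_fixed is not None else 0.1
    tau = config.tau_fixed if config.tau_fixed is not None else 10.0
    eta = alpha + X @ beta + u + delta  # log theta
    mu = E * np.exp(eta)

    # adaptive step sizes
    s_alpha = config.init_step
    s_beta = np.full(p, config.init_step)
    s_u = np.full(n, config.init_step)
    s_d = np.full(n, config.init_step)
    s_sig = config.init_step
    acc = {"alpha": 0, "beta": np.zeros(p), "u": np.zeros(n),
           "delta": np.zeros(n), "sigma": 0}
    win = {"alpha": 0, "beta": np.zeros(p), "u": np.zeros(n),
           "delta": np.zeros(n), "sigma": 0}

    S = config.n_iterations
    out_alpha = np.empty(S)
    out_beta = np.empty((S, p))
    out_u = np.empty((S, n))
    out_delta = np.empty((S, n))
    out_sigma = np.empty(S)
    out_tau = np.empty(S)
    out_theta = np.empty((S, n))
    out_draw = np.empty(S)
    out_dsat = np.empty(S)

    sum_y = y.sum()
    y_safe = np.where(y > 0, y, 1.0)  # avoids log(0) in the saturated deviance
    adapt_gain = 1.0

    for it in range(S):
        adapting = it < config.burn_in
        # --- alpha: scalar random walk
        da = s_alpha * rng.standard_normal()
        new_mu = mu * np.exp(da)
        logr = (
            sum_y * da
            - (new_mu.sum() - mu.sum())
            - ((alpha + da) ** 2 - alpha**2) / (2 * va)
        )
        win["alpha"] += 1
        if np.log(rng.random()) < logr:
            alpha += da
            mu = new_mu
            acc["alpha"] += 1

        # --- beta_j: scalar random walks
        for j in range(p):
            db = s_beta[j] * rng.standard_normal()
            new_mu = mu * np.exp(X[:, j] * db)
            logr = (
                (y * X[:, j]).sum() * db
                - (new_mu.sum() - mu.sum())
                - ((beta[j] + db) ** 2 - beta[j] ** 2) / (2 * vb)
            )
            win["beta"][j] += 1
            if np.log(rng.random()) < logr:
                beta[j] += db
                mu = new_mu
                acc["beta"][j] += 1

        # --- u: element-wise MH (conditionally independent sites)
        if config.use_u:
            du = s_u * rng.standard_normal(n)
            unif = rng.random(n)
            new_mu = mu * np.exp(du)
            logr = (
                y * du
                - (new_mu - mu)
                - ((u + du) ** 2 - u**2) / (2 * sigma**2)
            )
            accept = np.log(unif) < logr
            u = np.where(accept, u + du, u)
            mu = np.where(accept, new_mu, mu)
            acc["u"] += accept
            win["u"] += 1

        # --- delta: colour class by colour class
        if config.use_delta:
            nbr_sum = W @ delta
            for cls in colours:
                dd = s_d[cls] * rng.standard_normal(cls.size)
                unif = rng.random(cls.size)
                new_mu_c = mu[cls] * np.exp(dd)
                d_old = delta[cls]
                d_new = d_old + dd
                prior_diff = -0.5 * tau * (
                    m[cls] * (d_new**2 - d_old**2)
                    - 2.0 * nbr_sum[cls] * (d_new - d_old)
                )
                logr = y[cls] * dd - (new_mu_c - mu[cls]) + prior_diff
                accept = np.log(unif) < logr
                sel = cls[accept]
                delta[sel] = d_new[accept]
                mu[sel] = new_mu_c[accept]
                acc["delta"][cls] += accept
                win["delta"][cls] += 1
                if sel.size:
                    nbr_sum = W @ delta
            # recentre: move the flat direction into the intercept
            shift = delta.mean()
            delta -= shift
            alpha += shift

        # --- translation moves along likelihood-flat directions:
        # (beta_j, u) and (alpha, u) trade off without changing the linear
        # predictor, so their conditional along the flat direction is
        # Gaussian and can be Gibbs-sampled exactly. Without these moves
        # the weakly identified beta mixes an order of magnitude slower.
        if config.use_u:
            for j in range(p):
                xj = X[:, j]
                prec = 1.0 / vb + (xj @ xj) / sigma**2
                mean = (-beta[j] / vb + (u @ xj) / sigma**2) / prec
                eps = mean + rng.standard_normal() / np.sqrt(prec)
                beta[j] += eps
                u -= eps * xj
            prec = 1.0 / va + n / sigma**2
            mean = (-alpha / va + u.sum() / sigma**2) / prec
            eps = mean + rng.standard_normal() / np.sqrt(prec)
            alpha += eps
            u -= eps

        # --- sigma: random walk on log sigma (half-Normal prior)
        if config.use_u and config.sigma_fixed is None:
            dl = s_sig * rng.standard_normal()
            new_sigma = sigma * np.exp(dl)
            ssu = float(u @ u)
            logr = (
                -n * dl
                - 0.5 * ssu * (1 / new_sigma**2 - 1 / sigma**2)
                - (new_sigma**2 - sigma**2) / (2 * vs)
                + dl  # Jacobian of the log transform
            )
            win["sigma"] += 1
            if np.log(rng.random()) < logr:
                sigma = new_sigma
                acc["sigma"] += 1

        # --- tau: conjugate Gamma full conditional
        if config.use_delta and config.tau_fixed is None:
            ss = float(np.sum((delta[ii] - delta[jj]) ** 2))
            tau = rng.gamma(a0 + 0.5 * rank, 1.0 / (b0 + 0.5 * ss))

        # --- adaptation (burn-in only)
        if adapting and (it + 1) % config.adapt_interval == 0:
            tgt = config.target_accept
            s_alpha *= np.exp(adapt_gain * (acc["alpha"] / win["alpha"] - tgt))
            if p:
                s_beta *= np.exp(adapt_gain * (acc["beta"] / win["beta"] - tgt))
            if config.use_u:
                s_u *= np.exp(adapt_gain * (acc["u"] / win["u"] - tgt))
            if config.use_delta:
                s_d *= np.exp(adapt_gain * (acc["delta"] / win["delta"] - tgt))
            if config.use_u and config.sigma_fixed is None:
                s_sig *= np.exp(adapt_gain * (acc["sigma"] / win["sigma"] - tgt))
            for k in acc:
                acc[k] = np.zeros_like(win[k]) if np.ndim(win[k]) else 0
                win[k] = np.zeros_like(win[k]) if np.ndim(win[k]) else 0
            adapt_gain = max(0.1, adapt_gain * 0.98)

        eta = alpha + X @ beta + u + delta
        out_alpha[it] = alpha
        out_beta[it] = beta
        out_u[it] = u
        out_delta[it] = delta
        out_sigma[it] = sigma
        out_tau[it] = tau
        out_theta[it] = np.exp(eta)
        ll = np.where(y > 0, y * np.log(mu), 0.0) - mu - log_yfact
        out_draw[it] = -2.0 * ll.sum()
        sat = np.where(y > 0, y * np.log(y_safe / mu), 0.0) - (y - mu)
        out_dsat[it] = 2.0 * sat.sum()

    post = S - config.burn_in
    sample = PosteriorSample(
        areas=list(adj.areas),
        covariate_names=list(covariates),
        alpha=out_alpha,
        beta=out_beta,
        u=out_u,
        delta=out_delta,
        sigma=out_sigma,
        tau=out_tau,
        theta=out_theta,
        deviance_raw=out_draw,
        deviance_sat=out_dsat,
        observed=y,
        expected=E,
        config=config,
        acceptance={
            "alpha": acc["alpha"] / max(win["alpha"], 1),
            "post_burnin_draws": post,
        },
    )
    _warn_acceptance(sample)
    return sample


def _warn_acceptance(sample: PosteriorSample) -> None:
    import logging

    r = sample.acceptance.get("alpha", 0.4)
    if not (0.05 < r < 0.95):
        logging.getLogger(__name__).warning(
            "alpha acceptance rate %.3f outside (0.05, 0.95) after adaptation", r
        )


# ---------------------------------------------------------------------------
# Posterior summaries


def summarize_posterior(
    sample: PosteriorSample,
    burn_in: Optional[int] = None,
    thin: Optional[int] = None,
) -> tuple[RiskSurface, pd.DataFrame]:
    """Risk surface and parameter table from retained draws.

    Parameter rows report the posterior mean and equal-tailed 95% credible
    interval; each covariate carries a ``significant`` flag that is False
    when its exp(beta) interval spans 1.
    """
    sl = sample.retained(burn_in, thin)
    theta = sample.theta[sl]
    if theta.shape[0] < 100:
        raise ValidationError(
            f"only {theta.shape[0]} retained draws; need >= 100 to summarize"
        )
    lo, med, hi = np.percentile(theta, [2.5, 50.0, 97.5], axis=0)
    surface = RiskSurface(
        table=pd.DataFrame(
            {
                "area": sample.areas,
                "rr_mean": theta.mean(axis=0),
                "rr_median": med,
                "rr_ci_low": lo,
                "rr_ci_high": hi,
                "exceedance_prob": (theta > 1.0).mean(axis=0),
            }
        )
    )
    rows = [_param_row("alpha", sample.alpha[sl], exp_scale=False)]
    for j, name in enumerate(sample.covariate_names):
        rows.append(_param_row(f"beta_{name}", sample.beta[sl, j], exp_scale=True))
    rows.append(_param_row("sigma_u", sample.sigma[sl], exp_scale=False))
    rows.append(_param_row("tau_delta", sample.tau[sl], exp_scale=False))
    params = pd.DataFrame(rows)
    return surface, params


def _param_row(name: str, draws: np.ndarray, exp_scale: bool) -> dict:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    row = {
        "parameter": name,
        "mean": float(draws.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
    }
    if exp_scale:
        elo, ehi = np.exp(lo), np.exp(hi)
        row.update(
            exp_mean=float(np.exp(draws).mean()),
            exp_ci_low=float(elo),
            exp_ci_high=float(ehi),
            significant=bool(elo > 1.0 or ehi < 1.0),
        )
    return row


# ---------------------------------------------------------------------------
# Convergence diagnostics


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    nlen = x.size
    if nlen < 10 or np.var(x) == 0:
        return float(nlen)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[nlen - 1 :] / nlen
    rho = acov / acov[0]
    s = 0.0
    for t in range(1, nlen - 2, 2):  # Geyer initial positive sequence
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        s += pair
    return float(nlen / (1.0 + 2.0 * s))


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments."""
    x = np.asarray(x, dtype=float)
    a = x[: int(first * x.size)]
    b = x[-int(last * x.size) :]
    if a.size < 10 or b.size < 10:
        raise ValidationError("chain too short for a Geweke diagnostic")
    va = np.var(a, ddof=1) / effective_sample_size(a)
    vb = np.var(b, ddof=1) / effective_sample_size(b)
    if va + vb == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor R-hat over >= 2 chains."""
    chains = [np.asarray(c, dtype=float) for c in chains]
    if len(chains) < 2:
        raise ValidationError("R-hat needs >= 2 chains")
    L = min(c.size for c in chains)
    arr = np.stack([c[-L:] for c in chains])
    mchain = arr.mean(axis=1)
    B = L * np.var(mchain, ddof=1)
    Wv = np.mean(np.var(arr, axis=1, ddof=1))
    if Wv == 0:
        return np.inf if B > 0 else 1.0
    var_hat = (L - 1) / L * Wv + B / L
    return float(np.sqrt(var_hat / Wv))


def convergence_diagnostics(
    sample: PosteriorSample,
    extra_chains: Sequence[PosteriorSample] = (),
    burn_in: Optional[int] = None,
) -> pd.DataFrame:
    """Per-parameter Geweke z, ESS, and R-hat when extra chains are given."""
    sl = sample.retained(burn_in)
    names = ["alpha", "sigma_u", "tau_delta"] + [
        f"beta_{c}" for c in sample.covariate_names
    ]
    series = {
        "alpha": sample.alpha[sl],
        "sigma_u": sample.sigma[sl],
        "tau_delta": sample.tau[sl],
    }
    for j, c in enumerate(sample.covariate_names):
        series[f"beta_{c}"] = sample.beta[sl, j]
    if series["alpha"].size < 200 and not extra_chains:
        raise ValidationError("need >= 200 retained draws for diagnostics")
    rows = []
    for name in names:
        x = series[name]
        degenerate = bool(np.var(x) == 0)
        row = {
            "parameter": name,
            "geweke_z": 0.0 if degenerate else geweke_z(x),
            "ess": effective_sample_size(x),
            "degenerate": degenerate,
        }
        if extra_chains:
            others = [_series_for(c, name, burn_in) for c in extra_chains]
            row["rhat"] = gelman_rubin([x] + others)
        rows.append(row)
    return pd.DataFrame(rows)


def _series_for(sample: PosteriorSample, name: str, burn_in) -> np.ndarray:
    sl = sample.retained(burn_in)
    if name == "alpha":
        return sample.alpha[sl]
    if name == "sigma_u":
        return sample.sigma[sl]
    if name == "tau_delta":
        return sample.tau[sl]
    j = sample.covariate_names.index(name.removeprefix("beta_"))
    return sample.beta[sl, j]
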