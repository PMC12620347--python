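"""Hierarchical Bayesian estimation of the SCR tree across participants.

Latent-trait formulation: each participant i has probability-scale
parameters theta_ip = Phi(mu_p + gamma_p * educ_i + delta_ip), where Phi is
the standard normal CDF, mu_p is the group-level probit mean, gamma_p the
slope of the (mean-centered) education covariate and delta_i ~ MVN(0, Sigma)
a participant random effect with full covariance.  The data enter through
the multinomial tree likelihood of :mod:`scrmpt.tree`.

Priors: mu_p ~ N(0, prior_mu_sd^2) (default 1), gamma_p ~
N(0, prior_slope_sd^2), Sigma ~ inverse-Wishart(P+1, I).
The inverse-Wishart degrees of freedom P+1 imply a uniform marginal prior on
each random-effect correlation and admit an exact conjugate Gibbs update of
Sigma given the offsets, which dominates the sampler's mixing budget.

Sampling: Metropolis-within-Gibbs with adaptive random-walk proposals on
all probit-scale quantities, an exact Gibbs step for Sigma, and a
translation move that shifts (mu_p, delta_.p) jointly along the likelihood-
invariant direction to decorrelate the group mean from the offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart
from sklearn.base import BaseEstimator

from .io import counts_frame_to_arrays
from .mle import MPTMaximumLikelihood, free_parameter_names
from .tree import CountTable, ModelVariant, _probs_from_columns

__all__ = [
    "HierarchicalMPT",
    "fit_hierarchical",
    "rhat",
    "split_rhat",
    "posterior_predictive_p",
    "condition_difference",
]


def _expand_theta(theta: np.ndarray, names: list[str]) -> np.ndarray:
    """Map latent columns (per free parameter) to (n, 3, 3) probabilities."""
    col = {n: theta[:, i] for i, n in enumerate(names)}
    gi = col.get("G", col.get("Gi"))
    gr = col.get("G", col.get("Gr"))
    ab = col.get("ab", col["a"])
    return _probs_from_columns(col["Vi"], col["Vr"], gi, gr, col["a"], ab, col["b"])


def _loglik_vec(counts: np.ndarray, theta: np.ndarray, names: list[str]) -> np.ndarray:
    """Per-participant multinomial log-likelihood for theta (n, P) in (0,1)."""
    probs = _expand_theta(theta, names)
    return np.einsum("nij,nij->n", counts, np.log(np.clip(probs, 1e-300, None)))


def split_rhat(x: np.ndarray) -> float:
    """Classic split-chain Gelman-Rubin statistic for one scalar quantity.

    ``x`` has shape (n_chains, n_draws).  Each chain is split in half, the
    potential-scale-reduction factor is computed over the 2*m half-chains.
    Returns NaN (undefined, not 1) when the within-chain variance is zero.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = splits.shape
    within = splits.var(axis=1, ddof=1)
    w = within.mean()
    if w == 0.0:
        return float("nan")
    means = splits.mean(axis=1)
    b_over_n = means.var(ddof=1)
    var_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_hat / w))


def rhat(chains: np.ndarray | dict[str, np.ndarray]) -> float | dict[str, float]:
    """Split R-hat per quantity; ~1 for well-mixed chains."""
    if isinstance(chains, dict):
        return {k: split_rhat(v) for k, v in chains.items()}
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 2:
        return split_rhat(arr)
    if arr.ndim == 3:  # (n_chains, n_draws, n_quantities)
        return {i: split_rhat(arr[:, :, i]) for i in range(arr.shape[2])}
    raise ValueError("chains must be (n_chains, n_draws[, n_quantities])")


@dataclass
class _ChainResult:
    mu: np.ndarray        # (n_draws, P)
    gamma: np.ndarray     # (n_draws, P)
    sd: np.ndarray        # (n_draws, P) random-effect SDs
    theta: np.ndarray     # (n_thinned, n, P) probability-scale participant draws
    accept: dict[str, float]


class HierarchicalMPT(BaseEstimator):
    """Hierarchical Bayesian SCR-tree estimator for one group x condition cell.

    Parameters
    ----------
    variant : {"greene", "original"}
    constraint_gi_eq_gr : bool
        Share G across probe types (default True, the reported configuration).
    covariate : str or None
        Column of the metadata table used as a mean-centered covariate
        (default ``education_years``); disabled with a warning when missing.
    n_chains, n_warmup, n_draws : int
        MCMC geometry; defaults 4 chains x (3000 warmup + 3000 kept), which
        keeps the split R-hat of every group-level quantity below 1.05 on
        study-sized data.
    ppc_thin : int
        Keep every ``ppc_thin``-th participant-level draw for posterior
        predictive checks.
    random_state : int
        Root seed (mandatory; chains derive independent streams from it).

    Attributes
    ----------
    param_names_ : list of free parameter names (canonical order)
    mu_draws_, gamma_draws_, sd_draws_ : arrays (n_chains, n_draws, P)
    group_prob_draws_ : Phi(mu) draws, same shape (probability scale,
        evaluated at the covariate mean)
    theta_draws_ : (total_thinned, n, P) participant-level draws
    rhat_ : dict of split R-hat per group-level quantity
    summary_ : DataFrame with posterior mean and 95% credible interval per
        parameter on the probability scale
    """

    def __init__(
        self,
        variant: str = "greene",
        constraint_gi_eq_gr: bool = True,
        covariate: str | None = "education_years",
        n_chains: int = 4,
        n_warmup: int = 3000,
        n_draws: int = 3000,
        ppc_thin: int = 10,
        prior_mu_sd: float = 1.0,
        prior_slope_sd: float = 1.0,
        random_state: int | None = None,
        max_init_retries: int = 10,
    ) -> None:
        self.variant = variant
        self.constraint_gi_eq_gr = constraint_gi_eq_gr
        self.covariate = covariate
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_draws = n_draws
        self.ppc_thin = ppc_thin
        self.prior_mu_sd = prior_mu_sd
        self.prior_slope_sd = prior_slope_sd
        self.random_state = random_state
        self.max_init_retries = max_init_retries

    # ------------------------------------------------------------------
    def fit(
        self,
        X: pd.DataFrame | np.ndarray,
        metadata: pd.DataFrame | None = None,
    ) -> "HierarchicalMPT":
        """Fit to per-participant count data of a single group x condition.

        ``X`` is either an aggregated count frame (see
        :func:`scrmpt.io.aggregate_trials`) or an (n, 3, 3) array.
        """
        if self.random_state is None:
            raise ValueError("random_state (seed) is mandatory for MCMC fits")
        if isinstance(X, pd.DataFrame):
            if "condition" in X.columns and X["condition"].nunique() > 1:
                raise ValueError(
                    "fit one group x condition cell at a time; "
                    f"got conditions {sorted(X['condition'].unique())}"
                )
            counts, ids = counts_frame_to_arrays(X)
        else:
            counts = np.asarray(X, dtype=np.int64)
            ids = list(range(len(counts)))
        if counts.ndim != 3 or counts.shape[1:] != (3, 3):
            raise ValueError("counts must have shape (n, 3, 3)")
        n = counts.shape[0]
        if n < 5:
            raise ValueError(f"need >= 5 participants; got {n}")

        educ = self._covariate_values(ids, metadata, n)
        names = free_parameter_names(
            ModelVariant(self.variant), self.constraint_gi_eq_gr
        )
        P = len(names)

        seed_seq = np.random.SeedSequence(self.random_state)
        chain_seeds = seed_seq.spawn(self.n_chains)
        mu0 = self._initial_mu(counts)

        results = [
            self._run_chain(counts, educ, names, mu0, np.random.default_rng(s))
            for s in chain_seeds
        ]

        self.participant_ids_ = ids
        self.param_names_ = names
        self.n_participants_ = n
        self.counts_ = counts
        self.education_centered_ = educ
        self.mu_draws_ = np.stack([r.mu for r in results])
        self.gamma_draws_ = np.stack([r.gamma for r in results])
        self.sd_draws_ = np.stack([r.sd for r in results])
        self.theta_draws_ = np.concatenate([r.theta for r in results], axis=0)
        self.group_prob_draws_ = ndtr(self.mu_draws_)
        self.accept_rates_ = [r.accept for r in results]

        diag = {}
        for i, name in enumerate(names):
            diag[f"mu[{name}]"] = split_rhat(self.mu_draws_[:, :, i])
            diag[f"sd[{name}]"] = split_rhat(self.sd_draws_[:, :, i])
            if educ is not None:
                diag[f"gamma[{name}]"] = split_rhat(self.gamma_draws_[:, :, i])
        self.rhat_ = diag
        finite = [v for v in diag.values() if np.isfinite(v)]
        self.max_rhat_ = max(finite) if finite else float("nan")

        probs = self.group_prob_draws_.reshape(-1, P)
        self.summary_ = pd.DataFrame(
            {
                "parameter": names,
                "mean": probs.mean(axis=0),
                "lower": np.quantile(probs, 0.025, axis=0),
                "upper": np.quantile(probs, 0.975, axis=0),
            }
        )
        return self

    # ------------------------------------------------------------------
    def _covariate_values(
        self, ids: list, metadata: pd.DataFrame | None, n: int
    ) -> np.ndarray | None:
        if self.covariate is None:
            return None
        if metadata is None or self.covariate not in getattr(
            metadata, "columns", []
        ):
            warnings.warn(
                f"covariate {self.covariate!r} unavailable; fitting without it",
                stacklevel=3,
            )
            return None
        meta = metadata.set_index("participant_id")[self.covariate]
        try:
            vals = meta.loc[ids].to_numpy(dtype=float)
        except KeyError:
            warnings.warn(
                "covariate missing for some participants; fitting without it",
                stacklevel=3,
            )
            return None
        if np.any(~np.isfinite(vals)):
            warnings.warn(
                "non-finite covariate values; fitting without the covariate",
                stacklevel=3,
            )
            return None
        return vals - vals.mean()  # centered at the within-fit sample mean

    def _initial_mu(self, counts: np.ndarray) -> np.ndarray:
        """Probit of the pooled aggregate ML estimate (shared across chains)."""
        pooled = CountTable(counts.sum(axis=0))
        try:
            est = MPTMaximumLikelihood(
                variant=self.variant,
                constraint_gi_eq_gr=self.constraint_gi_eq_gr,
                n_starts=3,
                random_state=0,
            ).fit(pooled)
            d = est.params_.as_dict()
            d["G"] = d["Gi"]
            probs = np.array([d[nm] for nm in est.free_names_])
        except ValueError:
            probs = np.full(len(free_parameter_names(
                ModelVariant(self.variant), self.constraint_gi_eq_gr)), 0.5)
        return ndtri(np.clip(probs, 0.02, 0.98))

    # ------------------------------------------------------------------
    def _run_chain(
        self,
        counts: np.ndarray,
        educ: np.ndarray | None,
        names: list[str],
        mu0: np.ndarray,
        rng: np.random.Generator,
    ) -> _ChainResult:
        n, P = counts.shape[0], len(names)
        use_cov = educ is not None
        x = educ if use_cov else np.zeros(n)
        prior_df = P + 1
        prior_scale = np.eye(P)
        mu_var = float(self.prior_mu_sd) ** 2
        slope_var = float(self.prior_slope_sd) ** 2

        for _ in range(self.max_init_retries):
            mu = mu0 + rng.normal(0.0, 0.3, size=P)
            gamma = np.zeros(P)
            delta = rng.normal(0.0, 0.1, size=(n, P))
            sigma = 0.16 * np.eye(P)
            theta = ndtr(mu + x[:, None] * gamma + delta)
            ll = _loglik_vec(counts, theta, names)
            if np.all(np.isfinite(ll)):
                break
        else:
            raise RuntimeError("could not find a finite-likelihood initialization")

        sigma_inv = np.linalg.inv(sigma)
        s_mu = np.full(P, 0.2)
        s_gamma = np.full(P, 0.05)
        s_delta = np.full(P, 0.4)
        s_trans = np.full(P, 0.2)
        target = 0.44
        mu_joint_chol: np.ndarray | None = None
        s_joint = 2.38 / np.sqrt(P)
        acc_counts = {"mu": 0.0, "gamma": 0.0, "delta": 0.0, "trans": 0.0, "mu_joint": 0.0}
        n_total = self.n_warmup + self.n_draws

        mu_out = np.empty((self.n_draws, P))
        gamma_out = np.empty((self.n_draws, P))
        sd_out = np.empty((self.n_draws, P))
        theta_out = []
        # warmup history for empirical-variance proposal rescaling
        mu_hist = np.empty((self.n_warmup, P))
        gamma_hist = np.empty((self.n_warmup, P))

        def qf(d: np.ndarray) -> np.ndarray:
            return np.einsum("ij,jk,ik->i", d, sigma_inv, d)

        for t in range(n_total):
            warm = t < self.n_warmup
            gain = min(0.25, 2.0 / np.sqrt(t + 10.0)) if warm else 0.0
            if warm and t > 0 and t % 100 == 0 and t >= self.n_warmup // 4:
                # adaptive-Metropolis rescaling: empirical posterior spread of
                # recent warmup draws sets the proposal geometry (then fine-
                # tuned by the acceptance-rate recursion)
                recent = mu_hist[max(t - 400, 0) : t]
                s_mu = np.maximum(2.4 * recent.std(axis=0), 0.02)
                emp_cov = np.cov(recent.T) + 1e-6 * np.eye(P)
                try:
                    mu_joint_chol = np.linalg.cholesky(emp_cov)
                except np.linalg.LinAlgError:
                    pass
                if use_cov:
                    recent_g = gamma_hist[max(t - 400, 0) : t]
                    s_gamma = np.maximum(2.4 * recent_g.std(axis=0), 0.005)

            # --- group-level probit means -----------------------------
            for p in range(P):
                prop = mu.copy()
                prop[p] += s_mu[p] * rng.normal()
                theta_new = theta.copy()
                theta_new[:, p] = ndtr(prop[p] + x * gamma[p] + delta[:, p])
                ll_new = _loglik_vec(counts, theta_new, names)
                logr = (ll_new - ll).sum() - 0.5 * (prop[p] ** 2 - mu[p] ** 2) / mu_var
                acc = np.log(rng.uniform()) < logr
                if acc:
                    mu, theta, ll = prop, theta_new, ll_new
                    if not warm:
                        acc_counts["mu"] += 1.0 / P
                if warm:
                    s_mu[p] *= np.exp(gain * ((1.0 if acc else 0.0) - target))

            # --- joint group-mean move along the empirical covariance --
            if mu_joint_chol is not None:
                prop = mu + s_joint * (mu_joint_chol @ rng.normal(size=P))
                theta_new = ndtr(prop + x[:, None] * gamma + delta)
                ll_new = _loglik_vec(counts, theta_new, names)
                logr = (ll_new - ll).sum() - 0.5 * (prop @ prop - mu @ mu) / mu_var
                acc = np.log(rng.uniform()) < logr
                if acc:
                    mu, theta, ll = prop, theta_new, ll_new
                    if not warm:
                        acc_counts["mu_joint"] += 1.0
                if warm:
                    s_joint *= np.exp(gain * ((1.0 if acc else 0.0) - 0.25))

            # --- covariate slopes -------------------------------------
            if use_cov:
                for p in range(P):
                    prop_g = gamma.copy()
                    prop_g[p] += s_gamma[p] * rng.normal()
                    theta_new = theta.copy()
                    theta_new[:, p] = ndtr(mu[p] + x * prop_g[p] + delta[:, p])
                    ll_new = _loglik_vec(counts, theta_new, names)
                    logr = (ll_new - ll).sum() - 0.5 * (
                        prop_g[p] ** 2 - gamma[p] ** 2
                    ) / slope_var
                    acc = np.log(rng.uniform()) < logr
                    if acc:
                        gamma, theta, ll = prop_g, theta_new, ll_new
                        if not warm:
                            acc_counts["gamma"] += 1.0 / P
                    if warm:
                        s_gamma[p] *= np.exp(
                            gain * ((1.0 if acc else 0.0) - target)
                        )

            # --- participant offsets (vectorised across participants) --
            for p in range(P):
                step = s_delta[p] * rng.normal(size=n)
                delta_new = delta.copy()
                delta_new[:, p] += step
                theta_new = theta.copy()
                theta_new[:, p] = ndtr(mu[p] + x * gamma[p] + delta_new[:, p])
                ll_new = _loglik_vec(counts, theta_new, names)
                logr = ll_new - ll - 0.5 * (qf(delta_new) - qf(delta))
                mask = np.log(rng.uniform(size=n)) < logr
                delta[mask, p] = delta_new[mask, p]
                theta[mask, p] = theta_new[mask, p]
                ll = np.where(mask, ll_new, ll)
                rate = mask.mean()
                if warm:
                    s_delta[p] *= np.exp(gain * (rate - target))
                elif not warm:
                    acc_counts["delta"] += rate / P

            # --- translation move (likelihood-invariant) ---------------
            for p in range(P):
                eps = s_trans[p] * rng.normal()
                mu_new = mu[p] + eps
                delta_new = delta.copy()
                delta_new[:, p] -= eps
                logr = (
                    -0.5 * (mu_new**2 - mu[p] ** 2) / mu_var
                    - 0.5 * (qf(delta_new) - qf(delta)).sum()
                )
                acc = np.log(rng.uniform()) < logr
                if acc:
                    mu[p] = mu_new
                    delta = delta_new
                    if not warm:
                        acc_counts["trans"] += 1.0 / P
                if warm:
                    s_trans[p] *= np.exp(gain * ((1.0 if acc else 0.0) - target))
            # theta unchanged by construction of the translation move

            # --- conjugate covariance update ---------------------------
            sigma = invwishart.rvs(
                df=prior_df + n, scale=prior_scale + delta.T @ delta,
                random_state=rng,
            )
            sigma = np.atleast_2d(sigma)
            sigma_inv = np.linalg.inv(sigma)

            if warm:
                mu_hist[t] = mu
                gamma_hist[t] = gamma
            else:
                k = t - self.n_warmup
                mu_out[k] = mu
                gamma_out[k] = gamma
                sd_out[k] = np.sqrt(np.diag(sigma))
                if k % self.ppc_thin == 0:
                    theta_out.append(theta.copy())

        accept = {k: v / self.n_draws for k, v in acc_counts.items()}
        return _ChainResult(
            mu=mu_out, gamma=gamma_out, sd=sd_out,
            theta=np.stack(theta_out), accept=accept,
        )


def fit_hierarchical(
    counts: pd.DataFrame | np.ndarray,
    metadata: pd.DataFrame | None = None,
    variant: str = "greene",
    **config,
) -> HierarchicalMPT:
    """Functional wrapper over :class:`HierarchicalMPT`."""
    return HierarchicalMPT(variant=variant, **config).fit(counts, metadata)


def posterior_predictive_p(
    fit: HierarchicalMPT,
    counts: np.ndarray | pd.DataFrame | None = None,
    seed: int | None = None,
) -> float:
    """Posterior predictive p-value of a chi-square-style discrepancy.

    For each retained participant-level posterior draw, the observed and a
    replicated dataset are scored by T = sum over probe x response cells of
    (mean observed frequency - mean expected frequency)^2 / expected, and
    p is the fraction of draws with T(rep) >= T(obs).
    """
    if counts is None:
        arr = fit.counts_
    elif isinstance(counts, pd.DataFrame):
        arr, _ = counts_frame_to_arrays(counts)
    else:
        arr = np.asarray(counts, dtype=np.int64)
    if arr.shape != fit.counts_.shape:
        raise ValueError("data shape does not match the fitted participants")
    totals = arr.sum(axis=2)  # (n, 3)
    n = arr.shape[0]
    rng = np.random.default_rng(
        fit.random_state + 1 if seed is None else seed
    )
    obs_mean = arr.mean(axis=0)  # (3, 3)
    n_ge = 0
    draws = fit.theta_draws_
    for theta in draws:
        probs = _expand_theta(theta, fit.param_names_)  # (n, 3, 3)
        expected = (totals[:, :, None] * probs).mean(axis=0)
        expected = np.clip(expected, 1e-9, None)
        t_obs = float(np.sum((obs_mean - expected) ** 2 / expected))
        rep = np.stack(
            [
                np.stack(
                    [rng.multinomial(totals[i, j], probs[i, j]) for j in range(3)]
                )
                for i in range(n)
            ]
        )
        rep_mean = rep.mean(axis=0)
        t_rep = float(np.sum((rep_mean - expected) ** 2 / expected))
        if t_rep >= t_obs:
            n_ge += 1
    return n_ge / len(draws)


def condition_difference(
    fitA: HierarchicalMPT,
    fitB: HierarchicalMPT,
    pairing: str = "A-B",
) -> pd.DataFrame:
    """Posterior difference (A - B) of probability-scale group parameters.

    Returns one row per parameter (canonical order) with the posterior mean
    difference, 95% equal-tailed credible interval, and a ``credible`` flag
    that is True iff the interval excludes 0.
    """
    if fitA.param_names_ != fitB.param_names_:
        raise ValueError(
            "fits have mismatched parameter sets: "
            f"{fitA.param_names_} vs {fitB.param_names_}"
        )
    P = len(fitA.param_names_)
    a = fitA.group_prob_draws_.reshape(-1, P)
    b = fitB.group_prob_draws_.reshape(-1, P)
    m = min(len(a), len(b))
    diff = a[:m] - b[:m]
    lower = np.quantile(diff, 0.025, axis=0)
    upper = np.quantile(diff, 0.975, axis=0)
    return pd.DataFrame(
        {
            "parameter": fitA.param_names_,
            "pairing": pairing,
            "mean": diff.mean(axis=0),
            "lower": lower,
            "upper": upper,
            "credible": (lower > 0) | (upper < 0),
        }
    )
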