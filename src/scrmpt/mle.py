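"""Maximum-likelihood fitting of the SCR tree to aggregate count data.

This is the aggregate-data baseline complementing the hierarchical Bayesian
fit: a single parameter vector is estimated per :class:`~scrmpt.tree.CountTable`
by maximizing the multinomial likelihood over the unit hypercube.  The
optimization runs on the logit scale (so box constraints vanish) from
multiple random starts; standard errors come from the observed information
at interior optima and are flagged absent at boundaries.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .tree import CountTable, ModelVariant, MPTParameters, log_likelihood

__all__ = ["MPTMaximumLikelihood", "mle_fit", "free_parameter_names"]

_LOGIT_BOUNDARY = 6.0  # |logit| beyond this is treated as a boundary estimate


def free_parameter_names(
    variant: ModelVariant, constraint_gi_eq_gr: bool
) -> list[str]:
    """Names of the free parameters for a variant/constraint combination.

    greene + constraint (the reported configuration) has six free
    parameters: Vi, Vr, G, a, ab, b.
    """
    variant = ModelVariant(variant)
    names = ["Vi", "Vr"]
    names += ["G"] if constraint_gi_eq_gr else ["Gi", "Gr"]
    names += ["a"]
    if variant is ModelVariant.GREENE:
        names += ["ab"]
    names += ["b"]
    return names


def _vector_to_params(
    vec: np.ndarray, variant: ModelVariant, constraint: bool
) -> MPTParameters:
    """Map a probability-scale free-parameter vector to MPTParameters."""
    it = iter(vec)
    vi, vr = next(it), next(it)
    if constraint:
        gi = gr = next(it)
    else:
        gi, gr = next(it), next(it)
    a = next(it)
    ab = next(it) if ModelVariant(variant) is ModelVariant.GREENE else a
    b = next(it)
    return MPTParameters(
        vi=vi, vr=vr, gi=gi, gr=gr, a=a, ab=ab, b=b,
        constraint_gi_eq_gr=constraint,
    )


class MPTMaximumLikelihood(BaseEstimator):
    """Multi-start ML estimator for the SCR tree.

    Parameters
    ----------
    variant : {"greene", "original"}
        Bias structure of the tree.
    constraint_gi_eq_gr : bool
        Share a single gist parameter G across probe types (default True;
        without it the model is over-parameterized for a single table).
    n_starts : int
        Number of random logit-scale starting points.
    random_state : int or None
        Seed for the starting points (deterministic re-fit under same seed).

    Attributes
    ----------
    params_ : MPTParameters
        Estimates at the best optimum.
    se_ : dict
        Probability-scale standard errors per free parameter (NaN at
        boundaries).
    loglik_ : float
    converged_ : bool
        True if at least one start converged.
    boundary_ : dict
        Per free parameter, whether the estimate sits on the boundary.
    """

    def __init__(
        self,
        variant: str = "greene",
        constraint_gi_eq_gr: bool = True,
        n_starts: int = 10,
        random_state: int | None = None,
    ) -> None:
        self.variant = variant
        self.constraint_gi_eq_gr = constraint_gi_eq_gr
        self.n_starts = n_starts
        self.random_state = random_state

    def _neg_loglik(self, z: np.ndarray, data: CountTable) -> float:
        params = _vector_to_params(
            expit(z), ModelVariant(self.variant), self.constraint_gi_eq_gr
        )
        ll = log_likelihood(params, data, ModelVariant(self.variant))
        return np.inf if not np.isfinite(ll) else -ll

    def fit(self, X: CountTable | np.ndarray, y=None) -> "MPTMaximumLikelihood":
        data = X if isinstance(X, CountTable) else CountTable(np.asarray(X))
        if np.any(data.totals < 1):
            raise ValueError(
                "every probe type needs at least one trial; "
                f"totals={data.totals.tolist()}"
            )
        if data.counts.sum() == 0:
            raise ValueError("all-zero count table: nothing to fit")
        names = free_parameter_names(
            ModelVariant(self.variant), self.constraint_gi_eq_gr
        )
        k = len(names)
        rng = np.random.default_rng(self.random_state)
        starts = [np.zeros(k)] + [
            rng.uniform(-2.0, 2.0, size=k) for _ in range(max(0, self.n_starts - 1))
        ]
        best: tuple[float, np.ndarray] | None = None
        any_converged = False
        for z0 in starts:
            res = optimize.minimize(
                self._neg_loglik,
                z0,
                args=(data,),
                method="L-BFGS-B",
                options={"maxiter": 500},
            )
            any_converged = any_converged or bool(res.success)
            cand = (float(res.fun), np.asarray(res.x))
            if best is None or cand[0] < best[0] - 1e-10:
                best = cand
            elif abs(cand[0] - best[0]) <= 1e-10:
                # tie-break: lowest parameter-vector lexicographic order
                if tuple(expit(cand[1])) < tuple(expit(best[1])):
                    best = cand
        assert best is not None
        z_hat = best[1]
        p_hat = expit(z_hat)
        self.free_names_ = names
        self.params_ = _vector_to_params(
            p_hat, ModelVariant(self.variant), self.constraint_gi_eq_gr
        )
        self.loglik_ = -best[0]
        self.converged_ = any_converged
        self.boundary_ = {
            n: bool(abs(z) > _LOGIT_BOUNDARY) for n, z in zip(names, z_hat)
        }
        self.se_ = self._standard_errors(z_hat, p_hat, data)
        return self

    def _standard_errors(
        self, z_hat: np.ndarray, p_hat: np.ndarray, data: CountTable
    ) -> dict[str, float]:
        """Observed-information SEs via a central-difference Hessian.

        Computed on the logit scale and mapped to the probability scale by
        the delta method, se_p = se_z * p * (1 - p).  Boundary estimates get
        NaN (the information matrix is not informative there).
        """
        names = self.free_names_
        k = len(z_hat)
        se = {n: float("nan") for n in names}
        if any(self.boundary_.values()):
            return se
        h = 1e-4
        hess = np.empty((k, k))
        f0 = self._neg_loglik(z_hat, data)

        def f(z):
            return self._neg_loglik(z, data)

        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h
                ej[j] = h
                if i == j:
                    val = (f(z_hat + ei) - 2 * f0 + f(z_hat - ei)) / h**2
                else:
                    val = (
                        f(z_hat + ei + ej)
                        - f(z_hat + ei - ej)
                        - f(z_hat - ei + ej)
                        + f(z_hat - ei - ej)
                    ) / (4 * h**2)
                hess[i, j] = hess[j, i] = val
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return se
        diag = np.diag(cov)
        if np.any(diag <= 0):
            return se
        se_z = np.sqrt(diag)
        for n, s, p in zip(names, se_z, p_hat):
            se[n] = float(s * p * (1.0 - p))
        return se


def mle_fit(
    data: CountTable,
    variant: str = "greene",
    constraint_gi_eq_gr: bool = True,
    n_starts: int = 10,
    seed: int | None = None,
) -> MPTMaximumLikelihood:
    """Functional wrapper: fit the tree by multi-start ML and return the estimator."""
    return MPTMaximumLikelihood(
        variant=variant,
        constraint_gi_eq_gr=constraint_gi_eq_gr,
        n_starts=n_starts,
        random_state=seed,
    ).fit(data)
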