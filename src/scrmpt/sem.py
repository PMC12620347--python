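"""Covariance-structure SEM by maximum likelihood, with standard fit indices.

The model is held in RAM form: for the full variable vector v (observed
then latent), v = A v + e with cov(e) = S, so the implied covariance is
Sigma = (I - A)^-1 S (I - A)^-T restricted to the observed block.  Free
entries of A are factor loadings and structural regressions; S holds
(residual) variances and exogenous covariances.  The ML discrepancy

    F(theta) = log|Sigma| + tr(S_sample Sigma^-1) - log|S_sample| - p

is minimized over the free parameters; chi^2 = (n - 1) F_min, and CFI, TLI,
RMSEA and SRMR are derived against the independence baseline.

Identification: by default each latent's (residual) variance is fixed to 1
so all loadings are free ("std_lv"); a marker-variable option fixes the
first loading to 1 instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

__all__ = ["SEMSpec", "StructuralEquationModel", "sem_fit"]


@dataclass(frozen=True)
class SEMSpec:
    """Model specification: measurement model plus structural regressions.

    ``measurement`` maps each latent factor name to its indicator columns;
    ``regressions`` are strings like ``"outcome ~ pred1 + pred2"`` among
    latents and observed variables.
    """

    measurement: dict[str, list[str]] = field(default_factory=dict)
    regressions: list[str] = field(default_factory=list)

    def parsed_regressions(self) -> list[tuple[str, list[str]]]:
        out = []
        for line in self.regressions:
            if "~" not in line:
                raise ValueError(f"regression {line!r} must contain '~'")
            lhs, rhs = line.split("~", 1)
            preds = [t.strip() for t in rhs.split("+") if t.strip()]
            out.append((lhs.strip(), preds))
        return out

    def observed_variables(self) -> list[str]:
        seen: list[str] = []
        latents = set(self.measurement)
        for inds in self.measurement.values():
            for v in inds:
                if v not in seen:
                    seen.append(v)
        for lhs, preds in self.parsed_regressions():
            for v in [lhs, *preds]:
                if v not in latents and v not in seen:
                    seen.append(v)
        return seen


class StructuralEquationModel(BaseEstimator):
    """ML estimator for a latent-variable path model.

    Parameters
    ----------
    spec : SEMSpec
    identification : {"std_lv", "marker"}
        ``std_lv`` fixes each latent (residual) variance to 1 so every
        loading is free; ``marker`` fixes the first loading to 1.
    standardize : bool
        z-score observed variables before fitting.
    n_starts : int
        Extra jittered restarts if the first optimization stalls.
    random_state : int or None

    Attributes
    ----------
    loadings_, regressions_ : DataFrames with unstandardized and
        standardized estimates
    variances_ : DataFrame of (residual) variances
    fit_indices_ : dict with chi2, df, chi2_df, cfi, tli, tli_raw, rmsea,
        srmr, f_min
    converged_ : bool; grad_norm_ : float
    """

    def __init__(
        self,
        spec: SEMSpec,
        identification: str = "std_lv",
        standardize: bool = False,
        n_starts: int = 3,
        random_state: int | None = None,
    ) -> None:
        self.spec = spec
        self.identification = identification
        self.standardize = standardize
        self.n_starts = n_starts
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _build(self, observed: list[str], sample_var: np.ndarray) -> None:
        spec = self.spec
        latents = list(spec.measurement)
        self._observed = observed
        self._latents = latents
        all_vars = observed + latents
        self._vars = all_vars
        idx = {v: i for i, v in enumerate(all_vars)}
        m = len(all_vars)

        a_entries: list[tuple[int, int, str]] = []  # (row, col, label)
        fixed_a: list[tuple[int, int, float]] = []
        for lat, inds in spec.measurement.items():
            if not inds:
                raise ValueError(f"latent {lat!r} has no indicators")
            for k, ind in enumerate(inds):
                if ind not in idx:
                    raise ValueError(f"indicator {ind!r} not among variables")
                if self.identification == "marker" and k == 0:
                    fixed_a.append((idx[ind], idx[lat], 1.0))
                else:
                    a_entries.append((idx[ind], idx[lat], f"{lat}=~{ind}"))
        for lhs, preds in spec.parsed_regressions():
            for p in preds:
                a_entries.append((idx[lhs], idx[p], f"{lhs}~{p}"))

        endo = {r for r, _, _ in a_entries} | {r for r, _, _ in fixed_a}
        exo_obs = [v for v in observed if idx[v] not in endo]

        var_entries: list[tuple[int, str]] = [
            (idx[v], f"var:{v}") for v in observed
        ]
        for lat in latents:
            if self.identification == "marker":
                var_entries.append((idx[lat], f"var:{lat}"))
        fixed_s: list[tuple[int, int, float]] = []
        if self.identification == "std_lv":
            for lat in latents:
                fixed_s.append((idx[lat], idx[lat], 1.0))
        cov_entries: list[tuple[int, int, str]] = []
        for i, v in enumerate(exo_obs):
            for w in exo_obs[i + 1 :]:
                cov_entries.append((idx[v], idx[w], f"cov:{v},{w}"))

        self._a_entries = a_entries
        self._fixed_a = fixed_a
        self._var_entries = var_entries
        self._fixed_s = fixed_s
        self._cov_entries = cov_entries
        self._m = m
        self._obs_idx = np.arange(len(observed))
        self.param_names_ = (
            [lab for _, _, lab in a_entries]
            + [lab for _, lab in var_entries]
            + [lab for _, _, lab in cov_entries]
        )
        self._n_a = len(a_entries)
        self._n_v = len(var_entries)

    def _matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = self._m
        A = np.zeros((m, m))
        S = np.zeros((m, m))
        k = 0
        for r, c, _ in self._a_entries:
            A[r, c] = theta[k]
            k += 1
        for r, c, val in self._fixed_a:
            A[r, c] = val
        for i, _ in self._var_entries:
            S[i, i] = np.exp(theta[k])  # log-parametrized, keeps S diagonal > 0
            k += 1
        for r, c, val in self._fixed_s:
            S[r, c] = val
        for r, c, _ in self._cov_entries:
            S[r, c] = S[c, r] = theta[k]
            k += 1
        return A, S

    def _implied(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A, S = self._matrices(theta)
        binv = np.linalg.solve(np.eye(self._m) - A, np.eye(self._m))
        full = binv @ S @ binv.T
        obs = full[np.ix_(self._obs_idx, self._obs_idx)]
        return full, obs

    def _discrepancy(self, theta: np.ndarray) -> float:
        try:
            _, sigma = self._implied(theta)
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            # non-PD implied covariance: smooth penalty pushing back into
            # the admissible region (counted, never silent)
            self._n_nonpd += 1
            return 1e8 + float(np.sum(theta**2))
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        inv = np.linalg.inv(sigma)
        p = len(self._obs_idx)
        f = logdet + float(np.trace(self._S_sample @ inv)) - self._logdet_S - p
        return f

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "StructuralEquationModel":
        observed = self.spec.observed_variables()
        missing = [v for v in observed if v not in X.columns]
        if missing:
            raise ValueError(f"data is missing observed variables: {missing}")
        data = X[observed].dropna().astype(float)
        n = len(data)
        if n <= len(observed):
            raise ValueError("need more observations than observed variables")
        if self.standardize:
            data = (data - data.mean()) / data.std(ddof=1)
        S = np.cov(data.to_numpy(), rowvar=False, ddof=1)
        return self.fit_covariance(S, n, observed)

    def fit_covariance(
        self, S: np.ndarray, n_obs: int, var_names: list[str]
    ) -> "StructuralEquationModel":
        """Fit from a sample covariance matrix (n-1 denominator)."""
        S = np.asarray(S, dtype=float)
        observed = self.spec.observed_variables()
        order = [var_names.index(v) for v in observed]
        S = S[np.ix_(order, order)]
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError("sample covariance must be positive definite")
        self._S_sample = S
        self._logdet_S = float(logdet)
        self._n_nonpd = 0
        self.n_obs_ = int(n_obs)
        self._build(observed, np.diag(S))

        idx = {v: i for i, v in enumerate(self._vars)}
        sd_obs = np.sqrt(np.diag(S))
        theta0 = np.concatenate(
            [
                [
                    0.7 * sd_obs[idx[lab.split("=~")[1]]]
                    if "=~" in lab
                    else 0.0
                    for _, _, lab in self._a_entries
                ],
                [
                    np.log(0.5 * max(S[i, i], 1e-3))
                    if i < len(observed)
                    else np.log(1.0)
                    for i, _ in self._var_entries
                ],
                np.zeros(len(self._cov_entries)),
            ]
        )

        rng = np.random.default_rng(self.random_state)
        best = None
        for s in range(max(1, self.n_starts)):
            start = theta0 if s == 0 else theta0 + rng.normal(0, 0.3, theta0.shape)
            res = optimize.minimize(
                self._discrepancy,
                start,
                method="L-BFGS-B",
                options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            if best.fun < 1e-8:
                break
        assert best is not None
        self.theta_ = np.asarray(best.x)
        self.converged_ = bool(best.success) and best.fun < 1e7
        grad = getattr(best, "jac", None)
        self.grad_norm_ = float(np.max(np.abs(grad))) if grad is not None else float("nan")
        self.f_min_ = float(best.fun)
        self._finalize()
        return self

    # ------------------------------------------------------------------
    def _finalize(self) -> None:
        full, sigma = self._implied(self.theta_)
        A, S = self._matrices(self.theta_)
        sds = np.sqrt(np.clip(np.diag(full), 1e-300, None))
        idx = {v: i for i, v in enumerate(self._vars)}

        def std_coef(r: int, c: int) -> float:
            return A[r, c] * sds[c] / sds[r]

        loads, regs = [], []
        for r, c, lab in self._a_entries + [
            (r, c, None) for r, c, _ in self._fixed_a
        ]:
            var_r, var_c = self._vars[r], self._vars[c]
            rec = {
                "estimate": float(A[r, c]),
                "std_estimate": float(std_coef(r, c)),
            }
            if var_c in self._latents and var_r in self._observed:
                loads.append({"latent": var_c, "indicator": var_r, **rec})
            else:
                regs.append({"outcome": var_r, "predictor": var_c, **rec})
        self.loadings_ = pd.DataFrame(loads)
        self.regressions_ = pd.DataFrame(regs)
        self.variances_ = pd.DataFrame(
            [
                {
                    "variable": self._vars[i],
                    "estimate": float(S[i, i]),
                    "std_estimate": float(S[i, i] / full[i, i]),
                }
                for i, _ in self._var_entries
            ]
            + [
                {
                    "variable": self._vars[r],
                    "estimate": float(val),
                    "std_estimate": float(val / full[r, r]),
                }
                for r, c, val in self._fixed_s
                if r == c
            ]
        )
        self.implied_cov_ = sigma
        self.implied_cov_full_ = full

        p = len(self._obs_idx)
        n = self.n_obs_
        n_free = len(self.theta_)
        df = p * (p + 1) // 2 - n_free
        chi2 = max((n - 1) * self.f_min_, 0.0)
        s_sample = self._S_sample
        f_base = float(np.sum(np.log(np.diag(s_sample)))) - self._logdet_S
        chi2_b = max((n - 1) * f_base, 0.0)
        df_b = p * (p - 1) // 2
        num = max(chi2 - df, 0.0)
        denom = max(chi2_b - df_b, chi2 - df, 1e-300)
        cfi = 1.0 - num / denom
        if df > 0 and df_b > 0 and chi2_b / df_b > 1.0:
            tli_raw = (chi2_b / df_b - chi2 / df) / (chi2_b / df_b - 1.0)
        else:
            tli_raw = float("nan")
        rmsea = (
            float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))) if df > 0 else 0.0
        )
        d = np.sqrt(np.diag(s_sample))
        r_sample = s_sample / np.outer(d, d)
        r_model = sigma / np.outer(d, d)
        tri = np.tril_indices(p)
        srmr = float(np.sqrt(np.mean((r_sample[tri] - r_model[tri]) ** 2)))
        self.fit_indices_ = {
            "chi2": chi2,
            "df": df,
            "chi2_df": chi2 / df if df > 0 else float("nan"),
            "cfi": cfi,
            "tli": min(tli_raw, 1.0) if np.isfinite(tli_raw) else tli_raw,
            "tli_raw": tli_raw,
            "rmsea": rmsea,
            "srmr": srmr,
            "f_min": self.f_min_,
            "n_free": n_free,
            "n_nonpd": self._n_nonpd,
        }

    # ------------------------------------------------------------------
    def path_coefficient(
        self, outcome: str, predictor: str, standardized: bool = True
    ) -> float:
        A, _ = self._matrices(self.theta_)
        full = self.implied_cov_full_
        idx = {v: i for i, v in enumerate(self._vars)}
        r, c = idx[outcome], idx[predictor]
        if standardized:
            return float(A[r, c] * np.sqrt(full[c, c] / full[r, r]))
        return float(A[r, c])

    def indirect_effect(
        self, chain: list[str], standardized: bool = True
    ) -> float:
        """Product of path coefficients along ``chain`` (source ... sink)."""
        est = 1.0
        for src, dst in zip(chain[:-1], chain[1:]):
            est *= self.path_coefficient(dst, src, standardized=standardized)
        return est

    def indirect_effect_delta(
        self, chain: list[str], standardized: bool = True
    ) -> tuple[float, float]:
        """Delta-method estimate and SE of an indirect effect.

        Uses the observed-information covariance 2/(n-1) H^-1 with a
        numerical Hessian of the ML discrepancy.
        """
        theta = self.theta_
        k = len(theta)
        h = 1e-5
        hess = np.empty((k, k))
        f0 = self._discrepancy(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h
                ej = np.zeros(k); ej[j] = h
                if i == j:
                    val = (
                        self._discrepancy(theta + ei)
                        - 2 * f0
                        + self._discrepancy(theta - ei)
                    ) / h**2
                else:
                    val = (
                        self._discrepancy(theta + ei + ej)
                        - self._discrepancy(theta + ei - ej)
                        - self._discrepancy(theta - ei + ej)
                        + self._discrepancy(theta - ei - ej)
                    ) / (4 * h**2)
                hess[i, j] = hess[j, i] = val
        cov = 2.0 / (self.n_obs_ - 1) * np.linalg.pinv(hess)

        def eff(t: np.ndarray) -> float:
            saved = self.theta_
            self.theta_ = t
            try:
                self._finalize_light()
                return self.indirect_effect(chain, standardized=standardized)
            finally:
                self.theta_ = saved
                self._finalize_light()

        grad = np.empty(k)
        for i in range(k):
            ei = np.zeros(k); ei[i] = 1e-6
            grad[i] = (eff(theta + ei) - eff(theta - ei)) / 2e-6
        se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        return self.indirect_effect(chain, standardized=standardized), se

    def _finalize_light(self) -> None:
        full, sigma = self._implied(self.theta_)
        self.implied_cov_full_ = full
        self.implied_cov_ = sigma

    def bootstrap_indirect(
        self,
        data: pd.DataFrame,
        chain: list[str],
        n_boot: int = 1000,
        seed: int | None = None,
        standardized: bool = True,
    ) -> tuple[float, tuple[float, float]]:
        """Nonparametric percentile-bootstrap CI for an indirect effect."""
        rng = np.random.default_rng(seed)
        observed = self.spec.observed_variables()
        raw = data[observed].dropna().reset_index(drop=True)
        n = len(raw)
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            est = StructuralEquationModel(
                spec=self.spec,
                identification=self.identification,
                standardize=self.standardize,
                n_starts=1,
                random_state=0,
            )
            try:
                est.fit(raw.iloc[idx])
                vals.append(est.indirect_effect(chain, standardized=standardized))
            except (ValueError, np.linalg.LinAlgError):
                continue
        arr = np.asarray(vals)
        lo, hi = np.percentile(arr, [2.5, 97.5])
        point = self.indirect_effect(chain, standardized=standardized)
        return point, (float(lo), float(hi))


def sem_fit(
    data: pd.DataFrame,
    spec: SEMSpec,
    identification: str = "std_lv",
    standardize: bool = False,
    seed: int | None = None,
) -> StructuralEquationModel:
    """Functional wrapper over :class:`StructuralEquationModel`."""
    return StructuralEquationModel(
        spec=spec,
        identification=identification,
        standardize=standardize,
        random_state=seed,
    ).fit(data)
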