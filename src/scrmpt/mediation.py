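"""Serial (chain) mediation with percentile-bootstrap indirect effects.

The two-mediator chain model X -> M1 -> M2 -> Y fits three OLS equations

    M1 = a1*X            (+ covariates)
    M2 = a2*X + d21*M1   (+ covariates)
    Y  = c'*X + b1*M1 + b2*M2  (+ covariates)

and reports the indirect effects a1*b1, a2*b2 and a1*d21*b2 with seeded
percentile bootstrap confidence intervals.  With ``m2=None`` the model
reduces to the single-mediator form (indirect effect a1*b1).  In the fitted
OLS system the total effect decomposes exactly:
c = c' + a1*b1 + a2*b2 + a1*d21*b2.

Standardization: continuous variables are z-scored when
``standardized=True``; a binary predictor (two distinct values, e.g. a 1/2
group code) is left as coded, so its paths are partially standardized.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["SerialMediation", "serial_mediation"]

_COND_LIMIT = 1e8


def _ols(Xmat: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """OLS coefficients (incl. intercept first), R^2 and F."""
    n, k1 = Xmat.shape
    beta, *_ = np.linalg.lstsq(Xmat, y, rcond=None)
    resid = y - Xmat @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    k = k1 - 1  # predictors excluding intercept
    df_res = n - k1
    f = (
        (r2 / k) / ((1.0 - r2) / df_res)
        if k > 0 and df_res > 0 and r2 < 1.0
        else float("inf") if r2 >= 1.0 else float("nan")
    )
    return beta, r2, f


class SerialMediation(BaseEstimator):
    """Serial two-mediator (or single-mediator) OLS mediation estimator.

    Parameters
    ----------
    x, y : str
        Predictor and outcome column names.
    m1, m2 : str or None
        Mediator columns; ``m2=None`` gives the single-mediator model.
    covariates : sequence of str
        Covariate columns entered in every equation.
    n_boot : int
        Bootstrap resamples for percentile CIs (0 disables the bootstrap).
    random_state : int or None
        Bootstrap seed; identical seeds give identical CIs.
    standardized : bool
        z-score continuous variables before fitting.

    Attributes
    ----------
    paths_ : dict with a1, a2, d21, b1, b2, c_prime and total effect c
    indirect_ : dict of indirect-effect point estimates
    indirect_ci_ : dict of (lower, upper) percentile bootstrap intervals
    significant_ : dict of CI-excludes-zero flags
    r_squared_, f_stats_ : per-equation R^2 and F
    """

    def __init__(
        self,
        x: str,
        y: str,
        m1: str,
        m2: str | None = None,
        covariates: tuple[str, ...] = (),
        n_boot: int = 5000,
        random_state: int | None = None,
        standardized: bool = True,
    ) -> None:
        self.x = x
        self.y = y
        self.m1 = m1
        self.m2 = m2
        self.covariates = covariates
        self.n_boot = n_boot
        self.random_state = random_state
        self.standardized = standardized

    def _variables(self) -> list[str]:
        names = [self.x, self.m1] + ([self.m2] if self.m2 else []) + [self.y]
        names += list(self.covariates)
        if len(set(names)) != len(names):
            raise ValueError(f"variable names must be distinct; got {names}")
        return names

    def _prepare(self, data: pd.DataFrame) -> pd.DataFrame:
        names = self._variables()
        missing = [c for c in names if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing columns: {missing}")
        sub = data[names].dropna().astype(float)
        k_pred = 2 + (1 if self.m2 else 0) + len(self.covariates)
        if len(sub) < k_pred + 2:
            raise ValueError(
                f"need at least {k_pred + 2} complete cases; got {len(sub)}"
            )
        if self.standardized:
            sub = sub.copy()
            for c in names:
                vals = sub[c]
                if vals.nunique() > 2:  # binary codes left as coded
                    sd = vals.std(ddof=1)
                    if sd == 0:
                        raise ValueError(f"variable {c!r} is constant")
                    sub[c] = (vals - vals.mean()) / sd
        return sub

    def _fit_paths(self, sub: pd.DataFrame) -> dict[str, float]:
        n = len(sub)
        ones = np.ones((n, 1))
        cov = sub[list(self.covariates)].to_numpy() if self.covariates else np.empty((n, 0))
        x = sub[self.x].to_numpy()
        m1 = sub[self.m1].to_numpy()
        y = sub[self.y].to_numpy()

        def design(*cols):
            mat = np.column_stack([np.ones(n), *cols, cov]) if cols else ones
            if np.linalg.cond(mat) > _COND_LIMIT:
                raise ValueError(
                    "collinear predictors in design with columns "
                    f"{[self.x, self.m1, self.m2]}"
                )
            return mat

        paths: dict[str, float] = {}
        b_m1, r2_1, f_1 = _ols(design(x), m1)
        paths["a1"] = float(b_m1[1])
        if self.m2:
            m2 = sub[self.m2].to_numpy()
            b_m2, r2_2, f_2 = _ols(design(x, m1), m2)
            paths["a2"] = float(b_m2[1])
            paths["d21"] = float(b_m2[2])
            b_y, r2_3, f_3 = _ols(design(x, m1, m2), y)
            paths["c_prime"] = float(b_y[1])
            paths["b1"] = float(b_y[2])
            paths["b2"] = float(b_y[3])
            r2 = {"m1": r2_1, "m2": r2_2, "y": r2_3}
            f = {"m1": f_1, "m2": f_2, "y": f_3}
        else:
            b_y, r2_3, f_3 = _ols(design(x, m1), y)
            paths["c_prime"] = float(b_y[1])
            paths["b1"] = float(b_y[2])
            r2 = {"m1": r2_1, "y": r2_3}
            f = {"m1": f_1, "y": f_3}
        b_tot, _, _ = _ols(design(x), y)
        paths["c"] = float(b_tot[1])
        self._last_r2, self._last_f = r2, f
        return paths

    @staticmethod
    def _indirects(paths: dict[str, float], has_m2: bool) -> dict[str, float]:
        out = {"a1*b1": paths["a1"] * paths["b1"]}
        if has_m2:
            out["a2*b2"] = paths["a2"] * paths["b2"]
            out["a1*d21*b2"] = paths["a1"] * paths["d21"] * paths["b2"]
        return out

    def fit(self, X: pd.DataFrame, y=None) -> "SerialMediation":
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0")
        raw = X[self._variables()].dropna().reset_index(drop=True)
        sub = self._prepare(raw)
        self.n_obs_ = len(sub)
        self.paths_ = self._fit_paths(sub)
        self.r_squared_ = self._last_r2
        self.f_stats_ = self._last_f
        self.indirect_ = self._indirects(self.paths_, self.m2 is not None)

        self.indirect_ci_ = {}
        self.significant_ = {}
        if self.n_boot > 0:
            rng = np.random.default_rng(self.random_state)
            boots = {k: np.empty(self.n_boot) for k in self.indirect_}
            n = len(raw)
            for i in range(self.n_boot):
                idx = rng.integers(0, n, size=n)
                bsub = self._prepare(raw.iloc[idx])
                try:
                    bpaths = self._fit_paths(bsub)
                except (ValueError, np.linalg.LinAlgError):
                    for k in boots:
                        boots[k][i] = np.nan
                    continue
                for k, v in self._indirects(bpaths, self.m2 is not None).items():
                    boots[k][i] = v
            for k, arr in boots.items():
                arr = arr[np.isfinite(arr)]
                lo, hi = np.percentile(arr, [2.5, 97.5])
                self.indirect_ci_[k] = (float(lo), float(hi))
                self.significant_[k] = bool(lo > 0 or hi < 0)
        return self


def serial_mediation(
    data: pd.DataFrame,
    x: str,
    y: str,
    m1: str,
    m2: str | None = None,
    covariates: tuple[str, ...] = (),
    n_boot: int = 5000,
    seed: int | None = None,
    standardized: bool = True,
) -> SerialMediation:
    """Functional wrapper over :class:`SerialMediation`."""
    return SerialMediation(
        x=x, y=y, m1=m1, m2=m2, covariates=covariates,
        n_boot=n_boot, random_state=seed, standardized=standardized,
    ).fit(data)
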