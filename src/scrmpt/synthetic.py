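"""Synthetic data generators with attached ground truth.

Every generator emits the exact table schemas the analysis modules consume
plus a :class:`SyntheticTruth` carrying the generating parameters, so each
pipeline stage has seed-reproducible, recovery-testable input without any
external download.

Default truth presets are named after the study cells they emulate
(age group x interference condition for the memory task; acute-training vs
control for the eye-movement experiment) and use the published group-level
estimates as generating values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
import json

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .hierarchical import _expand_theta
from .mle import free_parameter_names
from .tree import PROBE_ORDER, RESPONSE_ORDER, ModelVariant

__all__ = [
    "SyntheticTruth",
    "MPT_PRESETS",
    "PATH_TRUTH_AGE_CHAIN",
    "EYE_TRUTH",
    "generate_mpt_dataset",
    "generate_stroop_trials",
    "generate_eye_indicators",
    "generate_path_dataset",
    "DEFAULT_AOIS",
]

#: group-level probability-scale truths per age group x interference condition
#: (memory experiment) and training group x condition (training experiment)
MPT_PRESETS: dict[str, dict[str, float]] = {
    "younger_gist": {"Vi": 0.87, "Vr": 0.33, "G": 0.85, "a": 0.23, "ab": 0.04, "b": 0.05},
    "younger_nongist": {"Vi": 0.86, "Vr": 0.52, "G": 0.76, "a": 0.31, "ab": 0.09, "b": 0.05},
    "older_gist": {"Vi": 0.51, "Vr": 0.03, "G": 0.78, "a": 0.51, "ab": 0.13, "b": 0.08},
    "older_nongist": {"Vi": 0.61, "Vr": 0.11, "G": 0.66, "a": 0.53, "ab": 0.16, "b": 0.10},
    "training_gist": {"Vi": 0.60, "Vr": 0.10, "G": 0.86, "a": 0.32, "ab": 0.11, "b": 0.05},
    "control_gist": {"Vi": 0.51, "Vr": 0.04, "G": 0.88, "a": 0.34, "ab": 0.06, "b": 0.08},
    "training_nongist": {"Vi": 0.75, "Vr": 0.07, "G": 0.77, "a": 0.38, "ab": 0.11, "b": 0.04},
    "control_nongist": {"Vi": 0.68, "Vr": 0.12, "G": 0.81, "a": 0.26, "ab": 0.10, "b": 0.08},
}

#: education-years distributions per age group
EDUCATION_DEFAULTS = {"older": (10.15, 2.29), "younger": (15.68, 2.14)}

#: standardized chain-mediation truth: age group -> inhibition -> R-I -> accuracy
PATH_TRUTH_AGE_CHAIN: dict[str, float] = {
    "a1": -0.38,   # x -> m1 (inhibitory function)
    "a2": 0.51,    # x -> m2 (R-I)
    "d21": -0.21,  # m1 -> m2
    "b1": -0.10,   # m1 -> y (accuracy)
    "b2": -0.53,   # m2 -> y
    "c_prime": -0.33,
}

#: one-factor eye-movement measurement + structural truth (standardized);
#: the R-I -> ACC path is a free default, not a published value
EYE_TRUTH: dict[str, object] = {
    "loadings": (0.96, 0.98, 0.99, 0.99),  # FD, FD_P, FF, FF_P
    "group_to_latent": -0.32,
    "group_to_ri": 0.18,
    "group_to_acc": -0.06,
    "latent_to_ri": 0.50,
    "latent_to_acc": -0.50,
    "ri_to_acc": -0.40,
}

#: screen AOI rectangles (pixels, 1920x1080, origin top-left)
DEFAULT_AOIS: dict[str, tuple[float, float, float, float]] = {
    "figure": (200, 200, 1000, 900),
    "target_word": (1100, 300, 1700, 400),
    "interfering_word": (1100, 600, 1700, 700),
}


@dataclass
class SyntheticTruth:
    """Generating parameters attached to every synthetic dataset."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        text = json.dumps(asdict(self), indent=2, default=default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _resolve_preset(truth: str | dict[str, float]) -> dict[str, float]:
    if isinstance(truth, str):
        if truth not in MPT_PRESETS:
            raise ValueError(
                f"unknown preset {truth!r}; available: {sorted(MPT_PRESETS)}"
            )
        return dict(MPT_PRESETS[truth])
    return dict(truth)


def generate_mpt_dataset(
    truth: str | dict[str, float],
    n_participants: int = 40,
    trials_per_probe: tuple[int, int, int] = (15, 18, 15),
    seed: int | None = None,
    re_sd: float = 0.4,
    re_corr: float = 0.2,
    education_slope: float = 0.0,
    group: str = "older",
    condition: str = "gist",
    education: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Trial-level SCR responses from the hierarchical tree model.

    Participant probabilities arise through the probit link
    theta_ip = Phi(Phi^-1(truth_p) + slope * educ_i + delta_ip) with
    delta ~ MVN(0, Sigma), Sigma = re_sd^2 [(1 - re_corr) I + re_corr J].
    Defaults emulate one interference condition of the memory task: 40
    participants x (15, 18, 15) intact/related/unrelated trials.

    Returns (trials, metadata, truth); trials has the canonical columns
    participant_id, group, condition, probe, response.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    probs = _resolve_preset(truth)
    names = free_parameter_names(ModelVariant.GREENE, True)
    missing = [n for n in names if n not in probs]
    if missing:
        raise ValueError(f"truth is missing parameters: {missing}")
    mu = ndtri(np.array([probs[n] for n in names]))
    P = len(names)
    sigma = re_sd**2 * ((1 - re_corr) * np.eye(P) + re_corr * np.ones((P, P)))
    rng = np.random.default_rng(seed)

    edu_mean, edu_sd = education or EDUCATION_DEFAULTS.get(group, (12.0, 2.5))
    educ = rng.normal(edu_mean, edu_sd, size=n_participants)
    educ_c = educ - educ.mean()
    delta = rng.multivariate_normal(np.zeros(P), sigma, size=n_participants)
    theta = ndtr(mu + education_slope * educ_c[:, None] + delta)
    tree_probs = _expand_theta(theta, names)  # (n, 3, 3)

    totals = np.asarray(trials_per_probe, dtype=int)
    rows = []
    for i in range(n_participants):
        pid = f"{group[0]}{i + 1:03d}"
        for j, probe in enumerate(PROBE_ORDER):
            counts = rng.multinomial(totals[j], tree_probs[i, j])
            for k, resp in enumerate(RESPONSE_ORDER):
                rows.extend(
                    [
                        {
                            "participant_id": pid,
                            "group": group,
                            "condition": condition,
                            "probe": probe.value,
                            "response": resp.value,
                        }
                    ]
                    * int(counts[k])
                )
    trials = pd.DataFrame(rows)
    metadata = pd.DataFrame(
        {
            "participant_id": [f"{group[0]}{i + 1:03d}" for i in range(n_participants)],
            "group": group,
            "education_years": educ,
        }
    )
    truth_obj = SyntheticTruth(
        kind="mpt",
        params={
            "group_probabilities": probs,
            "probit_means": mu,
            "re_sd": re_sd,
            "re_corr": re_corr,
            "education_slope": education_slope,
            "trials_per_probe": list(map(int, totals)),
            "group": group,
            "condition": condition,
            "participant_theta": theta,
        },
        seed=seed,
    )
    return trials, metadata, truth_obj


def generate_stroop_trials(
    n_participants: int = 40,
    n_consistent: int = 40,
    n_inconsistent: int = 40,
    accuracy: float = 0.94,
    cost_frac: float = 0.16,
    rt_median_ms: float = 800.0,
    rt_cv: float = 0.25,
    accuracy_sd: float = 0.03,
    cost_sd: float = 0.05,
    group: str = "older",
    seed: int | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Stroop trials with a relative RT cost in the inconsistent condition.

    RTs are lognormal around ``rt_median_ms`` (coefficient of variation
    ``rt_cv``); inconsistent-trial medians are inflated by the participant's
    cost fraction; correctness is Bernoulli.  Defaults: 40 + 40 trials per
    participant, and accuracy/cost implying IF = acc * (2 - cost) = 1.73
    (the older-adult level; use accuracy=0.97, cost_frac=0.07 for the
    younger level, IF = 1.87).
    """
    rng = np.random.default_rng(seed)
    log_sd = np.sqrt(np.log1p(rt_cv**2))
    rows = []
    for i in range(n_participants):
        pid = f"{group[0]}{i + 1:03d}"
        acc_i = float(np.clip(rng.normal(accuracy, accuracy_sd), 0.0, 1.0))
        cost_i = max(rng.normal(cost_frac, cost_sd), -0.5)
        for cond, n_tr, median in (
            ("consistent", n_consistent, rt_median_ms),
            ("inconsistent", n_inconsistent, rt_median_ms * (1 + cost_i)),
        ):
            rts = median * np.exp(rng.normal(0.0, log_sd, size=n_tr))
            correct = rng.uniform(size=n_tr) < acc_i
            for rt, c in zip(rts, correct):
                rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "condition": cond,
                        "rt_ms": float(rt),
                        "correct": int(c),
                    }
                )
    truth = SyntheticTruth(
        kind="stroop",
        params={
            "accuracy": accuracy,
            "cost_frac": cost_frac,
            "implied_IF": accuracy * (2.0 - cost_frac),
            "rt_median_ms": rt_median_ms,
            "rt_cv": rt_cv,
            "group": group,
        },
        seed=seed,
    )
    return pd.DataFrame(rows), truth


def _sequential_structural(
    rng: np.random.Generator,
    n: int,
    exog: dict[str, np.ndarray],
    equations: list[tuple[str, dict[str, float]]],
) -> dict[str, np.ndarray]:
    """Build unit-variance variables from standardized linear equations.

    Each equation (name, {predictor: coefficient}) draws a residual whose
    variance tops the implied variance up to 1; a residual variance below 0
    (coefficients imply variance > 1) raises an error.
    """
    values = dict(exog)
    # track the full covariance of built variables for residual calculation
    order = list(exog)
    cov = np.eye(len(order))

    def cov_of(names_w: dict[str, float]) -> float:
        idx = {v: i for i, v in enumerate(order)}
        w = np.zeros(len(order))
        for nm, c in names_w.items():
            w[idx[nm]] = c
        return float(w @ cov @ w)

    for name, coeffs in equations:
        implied = cov_of(coeffs)
        resid_var = 1.0 - implied
        if resid_var < -1e-12:
            raise ValueError(
                f"coefficients of {name!r} imply variance {implied:.3f} > 1; "
                "residual variance would be negative"
            )
        resid_var = max(resid_var, 0.0)
        lin = sum(c * values[v] for v, c in coeffs.items())
        values[name] = lin + rng.normal(0.0, np.sqrt(resid_var), size=n)
        # extend covariance bookkeeping
        idx = {v: i for i, v in enumerate(order)}
        w = np.zeros(len(order))
        for nm, c in coeffs.items():
            w[idx[nm]] = c
        new_col = cov @ w
        cov = np.block(
            [[cov, new_col[:, None]], [new_col[None, :], np.array([[1.0]])]]
        )
        order.append(name)
    return values


def generate_eye_indicators(
    n_per_group: tuple[int, int] = (29, 30),
    loadings: tuple[float, float, float, float] = (0.96, 0.98, 0.99, 0.99),
    group_to_latent: float = -0.32,
    structural: bool = False,
    truth: dict | None = None,
    units: str = "standardized",
    fixation_streams: bool = False,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth] | tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Per-participant eye-movement indicators driven by one latent factor.

    The latent "interference" factor (attention captured by the interfering
    word) is shifted by group — control coded 1, acute-training coded 2, a
    negative standardized path meaning less interference processing after
    training — and the four indicators FD, FD_P, FF, FF_P load on it with
    the given standardized loadings (noise variance 1 - loading^2).

    ``structural=True`` additionally emits R_I and ACC columns from the
    full structural truth.  ``units="natural"`` rescales indicators to
    familiar units (ms, counts, proportions); ``fixation_streams=True``
    (requires natural units) additionally returns a fixation-event table
    whose :func:`scrmpt.indices.aoi_metrics` output reproduces the
    integerized indicators.
    """
    loadings = tuple(float(l) for l in loadings)
    if any(l <= 0 or l > 1 for l in loadings):
        raise ValueError("standardized loadings must lie in (0, 1]")
    t = dict(EYE_TRUTH)
    if truth:
        t.update(truth)
    t["loadings"] = loadings
    t["group_to_latent"] = group_to_latent
    rng = np.random.default_rng(seed)
    n_control, n_training = n_per_group
    n = n_control + n_training
    group = np.array([1] * n_control + [2] * n_training)
    x_std = (group - 1.5) / 0.5

    eqs = [("latent", {"x": group_to_latent})]
    if structural:
        eqs += [
            ("R_I", {"x": float(t["group_to_ri"]), "latent": float(t["latent_to_ri"])}),
            (
                "ACC",
                {
                    "x": float(t["group_to_acc"]),
                    "latent": float(t["latent_to_acc"]),
                    "R_I": float(t["ri_to_acc"]),
                },
            ),
        ]
    values = _sequential_structural(rng, n, {"x": x_std}, eqs)
    latent = values["latent"]

    names = ["FD", "FD_P", "FF", "FF_P"]
    data = {"participant_id": [f"p{i + 1:03d}" for i in range(n)], "group": group}
    z = {}
    for nm, lam in zip(names, loadings):
        z[nm] = lam * latent + rng.normal(0.0, np.sqrt(1 - lam**2), size=n)
    if units == "natural":
        # anchors near the pooled interfering-word AOI statistics
        anchors = {"FD": (385.0, 370.0), "FD_P": (0.115, 0.11), "FF": (1.8, 1.6), "FF_P": (0.12, 0.11)}
        for nm in names:
            m, s = anchors[nm]
            data[nm] = np.maximum(m + s * z[nm], 0.02 if nm.endswith("_P") else (105.0 if nm == "FD" else 1.0))
    elif units == "standardized":
        for nm in names:
            data[nm] = z[nm]
    else:
        raise ValueError("units must be 'standardized' or 'natural'")
    if structural:
        data["R_I"] = values["R_I"]
        data["ACC"] = values["ACC"]
    df = pd.DataFrame(data)
    truth_obj = SyntheticTruth(
        kind="eye", params={**t, "structural": structural, "units": units,
                            "n_per_group": list(n_per_group)}, seed=seed,
    )
    if not fixation_streams:
        return df, truth_obj
    if units != "natural":
        raise ValueError("fixation_streams requires units='natural'")
    streams = _emit_fixation_streams(df, rng)
    return df, streams, truth_obj


def _emit_fixation_streams(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Fixation events whose AOI metrics reproduce the indicator table.

    For each participant: FF equal-duration fixations inside the
    interfering-word AOI (total FD) and enough fixations outside all AOIs to
    make the FD_P / FF_P denominators come out right.  Counts are
    integerized, so the emitted stream defines slightly adjusted FF / FF_P
    values; FD and the duration proportion follow exactly.
    """
    x0, y0, x1, y1 = DEFAULT_AOIS["interfering_word"]
    rows = []
    for _, r in df.iterrows():
        ff = max(int(round(r["FF"])), 1)
        fd = max(float(r["FD"]), 100.0 * ff)
        total_dur = fd / max(float(r["FD_P"]), 1e-6)
        n_total = max(int(round(ff / max(float(r["FF_P"]), 1e-6))), ff + 1)
        out_n = n_total - ff
        out_dur_each = max((total_dur - fd) / out_n, 100.0)
        onset = 0.0
        for k in range(ff):
            rows.append(
                {
                    "participant_id": r["participant_id"],
                    "trial": 1,
                    "x": float(rng.uniform(x0, x1)),
                    "y": float(rng.uniform(y0, y1)),
                    "onset_ms": onset,
                    "duration_ms": fd / ff,
                }
            )
            onset += fd / ff
        for k in range(out_n):
            rows.append(
                {
                    "participant_id": r["participant_id"],
                    "trial": 1,
                    "x": 50.0,
                    "y": 50.0,
                    "onset_ms": onset,
                    "duration_ms": out_dur_each,
                }
            )
            onset += out_dur_each
    return pd.DataFrame(rows)


def generate_path_dataset(
    truth: dict[str, float] | None = None,
    n: int = 79,
    seed: int | None = None,
    binary_x: bool = False,
    columns: tuple[str, str, str, str] = ("group", "IF", "R_I", "ACC"),
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Observation table following the standardized chain X -> M1 -> M2 -> Y.

    Defaults to the age-group chain truth (x = age score, m1 = inhibitory
    function, m2 = R-I, y = accuracy).  With ``binary_x`` the emitted x
    column is a balanced 1/2 group code (equations use its standardized
    form); otherwise x is a standard-normal score.  All variables have unit
    population variance, so OLS on z-scored data recovers the coefficients.
    """
    t = dict(PATH_TRUTH_AGE_CHAIN)
    if truth:
        t.update(truth)
    rng = np.random.default_rng(seed)
    x_col, m1_col, m2_col, y_col = columns
    if binary_x:
        half = n // 2
        raw = np.array([1] * half + [2] * (n - half))
        raw = rng.permutation(raw)
        x = (raw - raw.mean()) / raw.std(ddof=0)
    else:
        raw = x = rng.normal(size=n)
    values = _sequential_structural(
        rng,
        n,
        {"x": x},
        [
            ("m1", {"x": t["a1"]}),
            ("m2", {"x": t["a2"], "m1": t["d21"]}),
            ("y", {"x": t["c_prime"], "m1": t["b1"], "m2": t["b2"]}),
        ],
    )
    df = pd.DataFrame(
        {
            x_col: raw,
            m1_col: values["m1"],
            m2_col: values["m2"],
            y_col: values["y"],
        }
    )
    indirect = {
        "a1*b1": t["a1"] * t["b1"],
        "a2*b2": t["a2"] * t["b2"],
        "a1*d21*b2": t["a1"] * t["d21"] * t["b2"],
    }
    truth_obj = SyntheticTruth(
        kind="path",
        params={**t, "indirect": indirect, "binary_x": binary_x, "n": n},
        seed=seed,
    )
    return df, truth_obj
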