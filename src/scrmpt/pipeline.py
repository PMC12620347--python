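"""End-to-end orchestration of the two experiment analyses.

``run_experiment1`` reproduces the memory-experiment workflow: response
proportions (with R-I / R-U), hierarchical tree fits per group x condition,
interference-condition difference tables, Stroop inhibition indices,
FDR-adjusted exploratory correlations, and the chain mediation model.

``run_experiment2`` reproduces the training-experiment workflow: AOI
metric group comparisons (t, Cohen's d), tree fits per training group, and
the one-factor SEM with its chain indirect effect.

Both run on synthetic presets (default) or on user-supplied delimited
tables, write plain-text outputs to a directory, and record a manifest
with the seed provenance and a hash of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from .hierarchical import HierarchicalMPT, condition_difference
from .indices import bh_adjust, group_effect_size, inhibition_index_table, response_proportions
from .io import aggregate_trials, read_table, write_table
from .mediation import SerialMediation
from .sem import SEMSpec, StructuralEquationModel
from .synthetic import (
    DEFAULT_AOIS,
    generate_eye_indicators,
    generate_mpt_dataset,
    generate_path_dataset,
    generate_stroop_trials,
)

__all__ = ["SamplerConfig", "RunConfig", "run_experiment1", "run_experiment2"]

log = logging.getLogger("scrmpt")


class SamplerConfig(BaseModel):
    n_chains: int = Field(4, ge=2)
    n_warmup: int = Field(3000, ge=10)
    n_draws: int = Field(3000, ge=10)


class RunConfig(BaseModel):
    """Validated run configuration; all randomness derives from ``seed``."""

    mode: Literal["synthetic", "files"] = "synthetic"
    seed: int = 0
    out_dir: str = "results"
    variant: Literal["greene", "original"] = "greene"
    n_participants: int = Field(40, ge=5)
    trials_per_probe: tuple[int, int, int] = (15, 18, 15)
    sampler: SamplerConfig = SamplerConfig()
    n_boot: int = Field(2000, ge=0)
    aois: dict[str, tuple[float, float, float, float]] | None = None
    # file-mode inputs
    trials_path: str | None = None
    metadata_path: str | None = None
    stroop_path: str | None = None
    observations_path: str | None = None


def _seed_for(root: int, stage: str) -> int:
    """Stable stage seed derived from the root seed (kept below 2^31)."""
    digest = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


class _Manifest:
    def __init__(self, config: RunConfig, experiment: str) -> None:
        self.data = {
            "experiment": experiment,
            "config": json.loads(config.model_dump_json()),
            "outputs": [],
        }
        self.out_dir = Path(config.out_dir)

    def add(self, path: Path, stage: str, seed: int | None = None) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.data["outputs"].append(
            {"file": path.name, "stage": stage, "seed": seed, "sha256": digest}
        )

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")
        return path


def _stage(name: str):
    """Decorator: stage-granular logging and stage-named failures."""

    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out

        return inner

    return wrap


def _hierarchical_cell(
    counts: pd.DataFrame, meta: pd.DataFrame, config: RunConfig, seed: int
) -> HierarchicalMPT:
    return HierarchicalMPT(
        variant=config.variant,
        n_chains=config.sampler.n_chains,
        n_warmup=config.sampler.n_warmup,
        n_draws=config.sampler.n_draws,
        random_state=seed,
    ).fit(counts, meta)


def _summary_table(fits: dict[str, HierarchicalMPT]) -> pd.DataFrame:
    frames = []
    for cell, fit in fits.items():
        s = fit.summary_.copy()
        s.insert(0, "cell", cell)
        s["max_rhat"] = fit.max_rhat_
        frames.append(s)
    return pd.concat(frames, ignore_index=True)


def run_experiment1(config: RunConfig) -> dict:
    """Memory-experiment analysis bundle; returns paths and key frames."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, "experiment1")

    @_stage("load-data")
    def load() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        if config.mode == "files":
            if not (config.trials_path and config.stroop_path):
                raise ValueError("file mode needs trials_path and stroop_path")
            trials = read_table(config.trials_path)
            meta = (
                read_table(config.metadata_path)
                if config.metadata_path
                else pd.DataFrame(columns=["participant_id", "education_years"])
            )
            stroop = read_table(config.stroop_path)
            return trials, meta, stroop
        frames, metas, stroops = [], [], []
        stroop_truth = {
            "younger": {"accuracy": 0.97, "cost_frac": 0.07},
            "older": {"accuracy": 0.94, "cost_frac": 0.16},
        }
        for group in ("younger", "older"):
            for cond in ("gist", "nongist"):
                tri, meta, _ = generate_mpt_dataset(
                    f"{group}_{cond}",
                    n_participants=config.n_participants,
                    trials_per_probe=config.trials_per_probe,
                    seed=_seed_for(config.seed, f"mpt:{group}:{cond}"),
                    group=group,
                    condition=cond,
                )
                frames.append(tri)
                if cond == "gist":
                    metas.append(meta)
            st, _ = generate_stroop_trials(
                n_participants=config.n_participants,
                group=group,
                seed=_seed_for(config.seed, f"stroop:{group}"),
                **stroop_truth[group],
            )
            stroops.append(st)
        return (
            pd.concat(frames, ignore_index=True),
            pd.concat(metas, ignore_index=True),
            pd.concat(stroops, ignore_index=True),
        )

    trials, meta, stroop = load()

    @_stage("response-proportions")
    def props() -> pd.DataFrame:
        table = response_proportions(trials, by=("group", "condition"))
        manifest.add(write_table(table, out / "response_proportions.tsv"), "response-proportions")
        return table

    prop_table = props()

    @_stage("inhibition-index")
    def inhibition() -> pd.DataFrame:
        table = inhibition_index_table(stroop)
        table = table.merge(
            stroop[["participant_id", "group"]].drop_duplicates(), on="participant_id"
        )
        manifest.add(write_table(table, out / "inhibition_index.tsv"), "inhibition-index")
        return table

    if_table = inhibition()

    @_stage("hierarchical-fits")
    def mpt_fits() -> tuple[dict, pd.DataFrame]:
        counts = aggregate_trials(trials)
        fits = {}
        for group in sorted(counts["group"].unique()):
            for cond in sorted(counts["condition"].unique()):
                cell = f"{group}:{cond}"
                sub = counts[(counts["group"] == group) & (counts["condition"] == cond)]
                fits[cell] = _hierarchical_cell(
                    sub, meta, config, _seed_for(config.seed, f"fit:{cell}")
                )
        table = _summary_table(fits)
        manifest.add(write_table(table, out / "mpt_estimates.tsv"), "hierarchical-fits")
        return fits, table

    fits, mpt_table = mpt_fits()

    @_stage("condition-differences")
    def differences() -> pd.DataFrame:
        frames = []
        for group in sorted({c.split(":")[0] for c in fits}):
            diff = condition_difference(
                fits[f"{group}:gist"], fits[f"{group}:nongist"], pairing=f"{group}: gist-nongist"
            )
            frames.append(diff)
        table = pd.concat(frames, ignore_index=True)
        manifest.add(write_table(table, out / "condition_differences.tsv"), "condition-differences")
        return table

    diff_table = differences()

    @_stage("correlations-fdr")
    def correlations() -> pd.DataFrame:
        perf = (
            response_proportions(trials, by=("participant_id",))
            .drop_duplicates("participant_id")[["participant_id", "R_I", "accuracy"]]
        )
        merged = if_table.merge(perf, on="participant_id")
        rows = []
        for var in ("accuracy", "R_I"):
            r, p = stats.pearsonr(merged["IF"], merged[var])
            rows.append({"pair": f"IF~{var}", "r": r, "p": p})
        table = pd.DataFrame(rows)
        table["p_fdr"] = bh_adjust(table["p"].to_numpy())
        manifest.add(write_table(table, out / "correlations_fdr.tsv"), "correlations-fdr")
        return table

    corr_table = correlations()

    @_stage("chain-mediation")
    def mediation() -> pd.DataFrame:
        perf = (
            response_proportions(trials, by=("participant_id", "group"))
            .drop_duplicates("participant_id")[["participant_id", "group", "R_I", "accuracy"]]
        )
        merged = if_table.drop(columns=["group"]).merge(perf, on="participant_id")
        merged = merged.merge(meta[["participant_id", "education_years"]], on="participant_id")
        merged["age_code"] = merged["group"].map({"younger": 1, "older": 2})
        est = SerialMediation(
            x="age_code", m1="IF", m2="R_I", y="accuracy",
            covariates=("education_years",),
            n_boot=config.n_boot,
            random_state=_seed_for(config.seed, "mediation"),
        ).fit(merged)
        rows = [
            {"quantity": k, "estimate": v, "lower": est.indirect_ci_.get(k, (np.nan, np.nan))[0],
             "upper": est.indirect_ci_.get(k, (np.nan, np.nan))[1]}
            for k, v in {**est.paths_, **est.indirect_}.items()
        ]
        table = pd.DataFrame(rows)
        manifest.add(write_table(table, out / "mediation.tsv"), "chain-mediation")
        return table

    med_table = mediation()
    manifest_path = manifest.write()
    return {
        "out_dir": out,
        "manifest": manifest_path,
        "response_proportions": prop_table,
        "inhibition": if_table,
        "mpt_estimates": mpt_table,
        "condition_differences": diff_table,
        "correlations": corr_table,
        "mediation": med_table,
        "fits": fits,
    }


def run_experiment2(config: RunConfig) -> dict:
    """Training-experiment analysis bundle (AOI metrics, tree fits, SEM)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, "experiment2")
    aois = config.aois or DEFAULT_AOIS

    @_stage("load-data")
    def load() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        if config.mode == "files":
            if not config.observations_path:
                raise ValueError("file mode needs observations_path")
            obs = read_table(config.observations_path)
            trials = read_table(config.trials_path) if config.trials_path else pd.DataFrame()
            meta = read_table(config.metadata_path) if config.metadata_path else pd.DataFrame()
            return obs, trials, meta
        obs, _ = generate_eye_indicators(
            n_per_group=(29, 30),
            structural=True,
            units="natural",
            seed=_seed_for(config.seed, "eye"),
        )
        frames, metas = [], []
        for code, name in ((1, "control"), (2, "training")):
            for cond in ("gist", "nongist"):
                tri, meta, _ = generate_mpt_dataset(
                    f"{name}_{cond}",
                    n_participants=(obs["group"] == code).sum(),
                    trials_per_probe=config.trials_per_probe,
                    seed=_seed_for(config.seed, f"mpt2:{name}:{cond}"),
                    group=name,
                    condition=cond,
                    education=(10.7, 2.6),
                )
                frames.append(tri)
                if cond == "gist":
                    metas.append(meta)
        return obs, pd.concat(frames, ignore_index=True), pd.concat(metas, ignore_index=True)

    obs, trials, meta = load()

    @_stage("aoi-group-comparisons")
    def aoi_compare() -> pd.DataFrame:
        rows = []
        for metric in ("FD", "FD_P", "FF", "FF_P"):
            g1 = obs.loc[obs["group"] == 2, metric]  # training
            g2 = obs.loc[obs["group"] == 1, metric]  # control
            d, t = group_effect_size(
                g1.mean(), g1.std(ddof=1), len(g1), g2.mean(), g2.std(ddof=1), len(g2)
            )
            rows.append(
                {
                    "aoi": "interfering_word",
                    "metric": metric,
                    "training_mean": g1.mean(),
                    "training_sd": g1.std(ddof=1),
                    "control_mean": g2.mean(),
                    "control_sd": g2.std(ddof=1),
                    "t": t,
                    "cohens_d": d,
                }
            )
        table = pd.DataFrame(rows)
        manifest.add(write_table(table, out / "aoi_group_comparisons.tsv"), "aoi-group-comparisons")
        return table

    aoi_table = aoi_compare()

    mpt_table = None
    if len(trials):

        @_stage("hierarchical-fits")
        def mpt_fits() -> pd.DataFrame:
            counts = aggregate_trials(trials)
            fits = {}
            for group in sorted(counts["group"].unique()):
                for cond in sorted(counts["condition"].unique()):
                    cell = f"{group}:{cond}"
                    sub = counts[(counts["group"] == group) & (counts["condition"] == cond)]
                    fits[cell] = _hierarchical_cell(
                        sub, meta, config, _seed_for(config.seed, f"fit2:{cell}")
                    )
            table = _summary_table(fits)
            manifest.add(write_table(table, out / "mpt_estimates.tsv"), "hierarchical-fits")
            return table

        mpt_table = mpt_fits()

    @_stage("sem")
    def sem() -> tuple[pd.DataFrame, dict]:
        spec = SEMSpec(
            measurement={"interference": ["FD", "FD_P", "FF", "FF_P"]},
            regressions=[
                "interference ~ group",
                "R_I ~ group + interference",
                "ACC ~ group + interference + R_I",
            ],
        )
        est = StructuralEquationModel(
            spec, standardize=True, random_state=_seed_for(config.seed, "sem")
        ).fit(obs)
        chain = est.indirect_effect(["group", "interference", "R_I", "ACC"])
        frames = [
            est.loadings_.assign(kind="loading").rename(
                columns={"latent": "lhs", "indicator": "rhs"}
            ),
            est.regressions_.assign(kind="regression").rename(
                columns={"outcome": "lhs", "predictor": "rhs"}
            ),
        ]
        table = pd.concat(frames, ignore_index=True)
        indices = dict(est.fit_indices_)
        indices["chain_indirect_std"] = chain
        manifest.add(write_table(table, out / "sem_estimates.tsv"), "sem")
        (out / "sem_fit_indices.json").write_text(json.dumps(indices, indent=2) + "\n")
        manifest.add(out / "sem_fit_indices.json", "sem")
        return table, indices

    sem_table, sem_indices = sem()
    manifest_path = manifest.write()
    result = {
        "out_dir": out,
        "manifest": manifest_path,
        "aoi_comparisons": aoi_table,
        "sem_estimates": sem_table,
        "sem_fit_indices": sem_indices,
    }
    if mpt_table is not None:
        result["mpt_estimates"] = mpt_table
    return result
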