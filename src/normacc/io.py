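"""Trial-table I/O, run configuration, and the simulate->fit->analyze pipeline.

CSV is the interchange format for trial tables (inspectable, diffable);
fit results are serialized as JSON.  Every run records its seed and a
hash of its configuration so identical configs reproduce identical
outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, fitting, tasks

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SCHEMAS",
    "read_trial_table",
    "write_trial_table",
    "read_config",
    "run_pipeline",
]

SCHEMAS = {
    "triangles": ["block", "trial", "H_true", "source", "x", "llr", "feedback"],
    "triangles_choices": ["block", "trial", "H_true", "source", "x", "llr", "feedback", "choice"],
    "dots_trials": tasks.DOTS_TRIAL_COLUMNS,
    "dots_trials_choices": tasks.DOTS_TRIAL_COLUMNS + ["choice"],
    "dots_frames": tasks.DOTS_FRAME_COLUMNS,
}


def read_trial_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a trial table CSV against a named schema.

    Raises ValueError naming any missing columns; non-numeric values in
    numeric columns are reported with their row numbers.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; options: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    non_numeric = {"coh_level"}
    for col in SCHEMAS[schema]:
        if col in non_numeric:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"{path.name}: column {col!r} malformed at rows {list(bad[:10])}")
        df[col] = coerced
    if "llr" in df.columns and not np.isfinite(df["llr"].to_numpy(dtype=float)).all():
        raise ValueError(f"{path.name}: non-finite llr values")
    if "duration_s" in df.columns:
        d = df["duration_s"].to_numpy(dtype=float)
        if ((d < 5.0 - 1e-9) | (d > 10.0 + 1e-9)).any():
            raise ValueError(f"{path.name}: durations outside [5, 10] s")
    logger.info("read %d rows from %s (schema %s)", len(df), path, schema)
    return df


def write_trial_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Reproducible end-to-end run: generator, observer, fits, analyses."""

    task: str = "triangles"
    seed: int = 0
    out_dir: str = "normacc_run"
    generator: dict = field(default_factory=dict)
    observer: dict = field(default_factory=dict)
    fit_models: list = field(default_factory=lambda: ["normative"])
    fit: dict = field(default_factory=dict)
    analyses: list = field(default_factory=list)

    VALID_MODELS = ("normative", "leaky", "bounded", "block_independent")
    VALID_ANALYSES = ("psychometric", "psi", "tradeoff", "duration", "leakdiff")

    def validate(self) -> None:
        if self.task not in ("triangles", "dots"):
            raise ValueError(f"unknown task {self.task!r}")
        for m in self.fit_models:
            if m not in self.VALID_MODELS:
                raise ValueError(f"unknown model tag {m!r}")
        for a in self.analyses:
            if a not in self.VALID_ANALYSES:
                raise ValueError(f"unknown analysis {a!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _fit_result_payload(res) -> dict:
    if isinstance(res, list):
        return {"shuffles": [_fit_result_payload(r) for r in res]}
    return {
        "model": res.model,
        "task": res.task,
        "params": res.params,
        "n_params": res.n_params,
        "n_trials": res.n_trials,
        "log_likelihood": res.log_likelihood,
        "neg_log_posterior": res.neg_log_posterior,
        "bic": res.bic,
        "converged": res.converged,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate -> observe -> fit -> analyze and write artifacts.

    Writes the config copy (with hash and seed), generated tables,
    fit-result JSON, the model-comparison table, and analysis CSVs to the
    output directory.  Failures in a stage are logged; artifacts from
    completed stages are retained alongside a failure manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)
    try:
        if config.task == "triangles":
            gen_cfg = tasks.TrianglesConfig(seed=config.seed, **config.generator)
            trials = tasks.gen_triangles(gen_cfg)
            obs_kwargs = dict(config.observer)
            obs_kwargs.setdefault("subjective_hazard", {b: h for b, h in enumerate(gen_cfg.hazard_set)})
            obs_kwargs.setdefault("gain", 1.0 / gen_cfg.sigma_over_d**2)
            obs = tasks.ObserverParams(seed=config.seed + 1, **obs_kwargs)
            observed = tasks.observe(trials, obs)
            write_trial_table(observed, out / "trials.csv")
            manifest["stages"]["simulate"] = "ok"

            spec_kwargs = dict(config.fit)
            spec_kwargs.setdefault("seed", config.seed + 2)
            results = {}
            for m in config.fit_models:
                spec = fitting.FitSpec(task="triangles", model="normative" if m == "block_independent" else m, **spec_kwargs)
                if m == "block_independent":
                    results[m] = fitting.fit_block_independent(observed, spec)
                else:
                    results[m] = fitting.fit_triangles(observed, fitting.FitSpec(task="triangles", model=m, **spec_kwargs))
            with open(out / "fits.json", "w") as fh:
                json.dump({m: _fit_result_payload(r) for m, r in results.items()}, fh, indent=1)
            manifest["stages"]["fit"] = "ok"
            if results:
                fitting.compare_models(results).to_csv(out / "model_comparison.csv", index=False)

            for a in config.analyses:
                if a == "psychometric":
                    st = behavior.switch_table(observed)
                    fit = behavior.fit_psychometric(
                        st["switch"], st["llr_change"], min_abs_prev_llr=4.0,
                        prev_abs_llr=st["prev_abs_llr"],
                    )
                    pd.DataFrame([{"phi": fit.phi, "beta_slope": fit.beta_slope}]).to_csv(
                        out / "psychometric.csv", index=False
                    )
                elif a == "psi":
                    frames = []
                    for b, g in observed.groupby("block"):
                        est = behavior.estimate_psi_nonparametric(g)
                        est.insert(0, "block", b)
                        frames.append(est)
                    pd.concat(frames).to_csv(out / "psi_nonparametric.csv", index=False)
                elif a == "tradeoff":
                    behavior.tradeoff_table(observed).to_csv(out / "tradeoff.csv", index=False)
            manifest["stages"]["analyze"] = "ok"
        else:
            sessions = []
            lams = config.generator.get("lams", [0.1, 2.0])
            gen_extra = {k: v for k, v in config.generator.items() if k != "lams"}
            for i, lam in enumerate(lams):
                gcfg = tasks.DotsConfig(lam=lam, seed=config.seed + i, **gen_extra)
                data = tasks.gen_dots(gcfg)
                obs_kwargs = dict(config.observer)
                obs_kwargs.setdefault("subjective_hazard", lam)
                obs = tasks.ObserverParams(seed=config.seed + 100 + i, **obs_kwargs)
                observed = tasks.observe(data, obs)
                write_trial_table(observed, out / f"dots_trials_{i}.csv")
                write_trial_table(data.frames, out / f"dots_frames_{i}.csv")
                sessions.append((observed, data.frames, gcfg.frame_rate))
            manifest["stages"]["simulate"] = "ok"
            spec_kwargs = dict(config.fit)
            spec_kwargs.setdefault("seed", config.seed + 2)
            results = {}
            for m in config.fit_models:
                if m == "block_independent":
                    results[m] = fitting.fit_block_independent(
                        sessions, fitting.FitSpec(task="dots", **spec_kwargs)
                    )
                else:
                    results[m] = fitting.fit_dots(
                        sessions, fitting.FitSpec(task="dots", model=m, **spec_kwargs)
                    )
            with open(out / "fits.json", "w") as fh:
                json.dump({m: _fit_result_payload(r) for m, r in results.items()}, fh, indent=1)
            if results:
                fitting.compare_models(results).to_csv(out / "model_comparison.csv", index=False)
            manifest["stages"]["fit"] = "ok"
            for a in config.analyses:
                if a == "duration":
                    allt = pd.concat([s[0] for s in sessions], ignore_index=True)
                    behavior.accuracy_by_duration(allt, seed=config.seed + 3).to_csv(
                        out / "accuracy_by_duration.csv", index=False
                    )
            manifest["stages"]["analyze"] = "ok"
    except Exception as exc:  # retain partial outputs with a failure manifest
        manifest["failure"] = repr(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
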