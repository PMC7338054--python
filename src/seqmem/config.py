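"""Pipeline configuration, validation and run orchestration.

A `PipelineConfig` bundles every sub-configuration (stimuli, decay kernel,
detector, harness, cohort) with a mandatory global seed.  All randomness
flows from that seed through named substreams (stimuli / retrieval noise /
detector calibration / cohort), so each stage is independently
reproducible.  Configs round-trip through JSON (YAML accepted on input).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from seqmem.changepoint import (DEFAULT_ARL0, DEFAULT_BURN_IN,
                                DEFAULT_MAX_LENGTH, DetectorConfig,
                                calibrate_thresholds, load_thresholds,
                                save_thresholds)
from seqmem.cohort import CohortSpec
from seqmem.decay import DecayParams
from seqmem.harness import HarnessConfig
from seqmem.stimuli import _EXPERIMENTS

_SUBSTREAMS = ("stimuli", "noise", "calibration", "cohort")


class ConfigError(ValueError):
    """Invalid or unknown configuration content, naming the field."""


@dataclass
class PipelineConfig:
    experiment_id: str = "1A"
    n_blocks: int | None = None
    model_mode: str = "constrained"
    decay: DecayParams = field(default_factory=DecayParams)
    arl0: float = DEFAULT_ARL0
    burn_in: int = DEFAULT_BURN_IN
    max_length: int = DEFAULT_MAX_LENGTH
    calibration_sims: int = 100_000
    n_replicates: int = 1
    cohort: CohortSpec = field(default_factory=CohortSpec)
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def substream(self, name: str) -> np.random.Generator:
        if name not in _SUBSTREAMS:
            raise ConfigError(f"unknown substream {name!r}")
        root = np.random.SeedSequence(self.seed)
        return np.random.default_rng(root.spawn(len(_SUBSTREAMS))[
            _SUBSTREAMS.index(name)])

    def substream_seed(self, name: str) -> int:
        return int(self.substream(name).integers(2 ** 31))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        try:
            if "decay" in d and isinstance(d["decay"], dict):
                d["decay"] = DecayParams(**d["decay"])
            if "cohort" in d and isinstance(d["cohort"], dict):
                d["cohort"] = CohortSpec(**d["cohort"])
        except TypeError as e:
            raise ConfigError(str(e)) from None
        except ValueError as e:
            raise ConfigError(str(e)) from None
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.experiment_id not in _EXPERIMENTS:
            raise ConfigError(
                f"experiment_id: {self.experiment_id!r} is not one of "
                f"{sorted(_EXPERIMENTS)}")
        if self.model_mode not in ("constrained", "unconstrained"):
            raise ConfigError(f"model_mode: {self.model_mode!r} invalid")
        if self.arl0 <= 0:
            raise ConfigError("arl0: must be positive")
        if self.seed is None:
            raise ConfigError("seed: mandatory for stochastic commands")


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Load a JSON or YAML config file; missing fields take defaults."""
    d: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml
            d = yaml.safe_load(text) or {}
        else:
            d = json.loads(text) if text.strip() else {}
    if overrides:
        d.update(overrides)
    return PipelineConfig.from_dict(d)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {obj!r}")


def ensure_calibration(cfg: PipelineConfig, cache_dir: str | Path | None = None,
                       null: str = "matched") -> DetectorConfig:
    """Load cached detector thresholds or calibrate (and cache) them.

    ``null='matched'`` (the default Type-I configuration) calibrates on
    the model's own regularity-free IC streams for the configured model
    mode; ``null='gaussian'`` gives the IID reference calibration.
    """
    if null not in ("matched", "gaussian"):
        raise ConfigError(f"null: {null!r} must be 'matched' or 'gaussian'")
    cache_dir = Path(cfg.out_dir if cache_dir is None else cache_dir)
    seed = cfg.substream_seed("calibration")
    mode = cfg.model_mode if null == "matched" else "iid"
    name = (f"thresholds_arl{int(cfg.arl0)}_len{cfg.max_length}"
            f"_n{cfg.calibration_sims}_{null}-{mode}_seed{seed}.csv")
    path = cache_dir / name
    if path.exists():
        return load_thresholds(path)
    if null == "matched":
        from seqmem.harness import calibrate_matched
        decay = cfg.decay if cfg.model_mode == "constrained" else None
        det = calibrate_matched(cfg.arl0, cfg.max_length,
                                cfg.calibration_sims, decay=decay, seed=seed,
                                burn_in=cfg.burn_in)
    else:
        det = calibrate_thresholds(cfg.arl0, cfg.max_length,
                                   cfg.calibration_sims,
                                   np.random.default_rng(seed), cfg.burn_in)
    save_thresholds(det, path, n_sims=cfg.calibration_sims, seed=seed)
    return det


def harness_config(cfg: PipelineConfig, detector: DetectorConfig,
                   mode: str | None = None) -> HarnessConfig:
    return HarnessConfig(model_mode=cfg.model_mode if mode is None else mode,
                         decay=cfg.decay, detector=detector,
                         seed=cfg.substream_seed("noise"))


PIPELINE_COMMANDS = ("generate", "calibrate", "synth", "simulate",
                     "analyze", "reproduce-fig5")


class DependencyError(RuntimeError):
    """A required upstream artifact is missing."""


def run_pipeline(cfg: PipelineConfig, command: str,
                 out_dir: str | Path | None = None) -> Path:
    """Run one pipeline stage, writing its artifacts and a run manifest.

    Outputs are deterministic under ``cfg.seed``.  ``simulate`` and
    ``reproduce-fig5`` calibrate the detector first if no cached
    thresholds exist; ``analyze`` requires the ``synth`` artifacts and
    raises :class:`DependencyError` without them.  Returns the manifest
    path.
    """
    import pandas as pd

    from seqmem import behaviour, cohort, harness, stimuli

    if command not in PIPELINE_COMMANDS:
        raise ConfigError(f"unknown pipeline command {command!r}")
    out = Path(cfg.out_dir if out_dir is None else out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    if command == "generate":
        session = stimuli.schedule_session(cfg.experiment_id,
                                           cfg.substream("stimuli"),
                                           n_blocks=cfg.n_blocks)
        df = stimuli.session_to_dataframe(session)
        df["seed"] = cfg.seed
        path = out / f"trials_exp{cfg.experiment_id}.csv"
        df.to_csv(path, index=False)
        outputs.append(path)
    elif command == "calibrate":
        ensure_calibration(cfg, out)
    elif command == "synth":
        trials, fam = cohort.simulate_cohort(cfg.experiment_id, cfg.cohort,
                                             cfg.substream("cohort"))
        for name, df in (("responses.csv", trials),
                         ("familiarity.csv", fam)):
            path = out / name
            df.to_csv(path, index=False)
            outputs.append(path)
    elif command == "analyze":
        path = out / "responses.csv"
        if not path.exists():
            raise DependencyError(
                f"analyze needs {path}; run the 'synth' stage (or supply "
                "a trial-response CSV) first")
        classified = behaviour.classify_responses(pd.read_csv(path))
        dp = behaviour.dprime_by_block(classified)
        adv = behaviour.rt_advantage(behaviour.baseline_and_trim(classified))
        for name, df in (("dprime.csv", dp), ("rt_advantage.csv", adv)):
            p = out / name
            df.to_csv(p, index=False)
            outputs.append(p)
        fam_path = out / "familiarity.csv"
        if fam_path.exists():
            m = behaviour.mcc_from_responses(pd.read_csv(fam_path))
            p = out / "mcc.csv"
            m.to_csv(p, index=False)
            outputs.append(p)
    elif command == "simulate":
        det = ensure_calibration(cfg, out)
        hcfg = harness_config(cfg, det)
        df = harness.run_replicates(cfg.experiment_id, hcfg,
                                    cfg.n_replicates,
                                    cfg.substream_seed("stimuli"),
                                    n_blocks=cfg.n_blocks)
        path = out / f"model_rts_exp{cfg.experiment_id}_{cfg.model_mode}.csv"
        df.to_csv(path, index=False)
        outputs.append(path)
        adv = harness.summarize_rt_advantage(df)
        spath = out / (path.stem + "_advantage.csv")
        adv.to_csv(spath, index=False)
        outputs.append(spath)
    else:  # reproduce-fig5
        for exp in ("1A", "2"):
            for mode in ("unconstrained", "constrained"):
                sub = dataclasses.replace(cfg, experiment_id=exp,
                                          model_mode=mode)
                det = ensure_calibration(sub, out)
                hcfg = harness_config(sub, det)
                df = harness.run_replicates(exp, hcfg, sub.n_replicates,
                                            sub.substream_seed("stimuli"))
                path = out / f"model_rts_exp{exp}_{mode}.csv"
                df.to_csv(path, index=False)
                outputs.append(path)
                if exp == "1A":
                    adv = harness.summarize_rt_advantage(df, "per_block")
                else:
                    adv = pd.concat([
                        harness.summarize_rt_advantage(
                            df, "per_intra_block_presentation",
                            reoccurring=c).assign(condition=c)
                        for c in ("RANREGr", "RANREGr*")])
                spath = out / f"rt_advantage_exp{exp}_{mode}.csv"
                adv.to_csv(spath, index=False)
                outputs.append(spath)

    return write_manifest(cfg, command, outputs, out)


def write_manifest(cfg: PipelineConfig, command: str, outputs: list[Path],
                   out_dir: str | Path) -> Path:
    """Run manifest: command, config, seeds, output hashes, versions."""
    import seqmem

    man = {
        "command": command,
        "seqmem_version": seqmem.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg.seed,
        "substream_seeds": {s: cfg.substream_seed(s) for s in _SUBSTREAMS},
        "config": json.loads(json.dumps(cfg.to_dict(),
                                        default=_json_default)),
        "outputs": {},
    }
    for p in outputs:
        p = Path(p)
        if p.exists():
            man["outputs"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    out = Path(out_dir) / f"manifest_{command}.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(man, indent=2) + "\n")
    return out
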