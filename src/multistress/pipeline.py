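"""End-to-end orchestration: simulate/load -> standardize -> fit -> report.

A run is described by a :class:`RunConfig` (typically loaded from YAML),
executes deterministically given its seeds, and writes every stage output
plus a ``manifest.json`` with SHA-256 checksums and a ``run.log``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, dataio, interactions, mechanisms, models, synthdata, tradeoffs

logger = logging.getLogger(__name__)

TRAIT_DESIGNS = ("pop_algae", "pop_insecticide", "threeway")


@dataclass
class RunConfig:
    """Configuration for one pipeline run (exactly one input source)."""

    input_csv: str | None = None
    synthetic: synthdata.SyntheticConfig | None = None
    standardize_mode: str = "paper_literal"
    test_type: str = "wald2"
    survival_family: str = "weibull_aft"
    bootstrap_reps: int = 2000
    interaction_seed: int = 0
    interaction_rule: str = "magnitude"
    outdir: str = "multistress_out"

    def __post_init__(self):
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("set exactly one of input_csv / synthetic")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = synthdata.SyntheticConfig.from_dict(raw["synthetic"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; return the manifest (also written to disk).

    Stage failures are re-raised annotated with the stage name. Stages that
    can degrade gracefully (missing arms in the interaction survey or a
    transition) log and continue.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("multistress")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    outputs: list[Path] = []
    stage = "load"
    try:
        if config.synthetic is not None:
            records, truth = synthdata.generate_experiment(config.synthetic)
            raw_path = outdir / "raw.csv"
            dataio.write_observations(records, raw_path)
            truth.to_json(outdir / "ground_truth.json")
            outputs += [raw_path, outdir / "ground_truth.json"]
        else:
            records = dataio.read_observations(config.input_csv)

        stage = "standardize"
        std = dataio.standardize_batches(records, mode=config.standardize_mode)
        std_path = outdir / "standardized.csv"
        dataio.write_observations(std, std_path)
        outputs.append(std_path)

        stage = "models"
        anova_frames = []
        for design in TRAIT_DESIGNS:
            for trait in dataio.TRAITS:
                try:
                    tab = models.fit_trait_model(
                        std, trait, design=design, test_type=config.test_type
                    )
                except dataio.ValidationError as exc:
                    logger.warning("trait model %s/%s skipped: %s", design, trait, exc)
                    continue
                frame = tab.to_frame()
                frame.insert(0, "design", design)
                frame["method"] = tab.method
                anova_frames.append(frame)
        table1 = pd.concat(anova_frames, ignore_index=True) if anova_frames else pd.DataFrame()
        table1.to_csv(outdir / "table1_style.csv", index=False)
        outputs.append(outdir / "table1_style.csv")

        surv_frames = []
        for design in TRAIT_DESIGNS:
            try:
                fit = models.fit_survival(std, design=design, family=config.survival_family)
            except dataio.ValidationError as exc:
                logger.warning("survival %s skipped: %s", design, exc)
                continue
            frame = fit.terms.copy()
            frame.insert(0, "design", design)
            frame["n_events"] = fit.n_events
            frame["flag"] = fit.flag
            surv_frames.append(frame)
        surv = pd.concat(surv_frames, ignore_index=True) if surv_frames else pd.DataFrame()
        surv.to_csv(outdir / "survival.csv", index=False)
        outputs.append(outdir / "survival.csv")

        stage = "mechanisms"
        mech = mechanisms.run_historical_transitions(std)
        mech.to_csv(outdir / "mechanisms.csv", index=False)
        outputs.append(outdir / "mechanisms.csv")

        stage = "interactions"
        calls, summary = interactions.interaction_survey(
            std,
            n_boot=config.bootstrap_reps,
            seed=config.interaction_seed,
            rule=config.interaction_rule,
        )
        calls.to_csv(outdir / "interaction_calls.csv", index=False)
        summary.to_csv(outdir / "interaction_summary.csv", index=False)
        outputs += [outdir / "interaction_calls.csv", outdir / "interaction_summary.csv"]

        stage = "tradeoffs"
        tern = tradeoffs.ternary_coordinates(std)
        tern.to_csv(outdir / "ternary.csv", index=False)
        outputs.append(outdir / "ternary.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "standardize_mode": config.standardize_mode,
        "test_type": config.test_type,
        "survival_family": config.survival_family,
        "bootstrap_reps": config.bootstrap_reps,
        "interaction_seed": config.interaction_seed,
        "synthetic_seed": config.synthetic.seed if config.synthetic else None,
        "outputs": {p.name: _sha256(p) for p in outputs},
        "log": log_path.name,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
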