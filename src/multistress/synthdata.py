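"""Synthetic common-garden experiment generator with a ground-truth ledger.

Every downstream stage of the pipeline (standardization, mixed-model
ANOVAs, survival fits, decomposition, interaction classification) assumes a
particular statistical structure in the data. This module generates datasets
with exactly that structure from an explicit parameterization, and returns
alongside each dataset the noiseless quantities the parameterization
implies, so recovery tests can compare estimates against known truth.

Trait model for animal ``i`` in population ``p``, genotype ``g``, arm ``a``,
batch ``b``::

    y_i = intercept + pop_effect[p] + arm_effect[a] + pop_arm_effect[p, a]
          + stressor_interaction[a]            (pair arms only)
          + genotype_intercept[g] + batch_offset[b] + residual_i

Mortality is a Weibull event-time process (shape 1 = exponential) with
proportional-hazards shifts per arm and population, right-censored at the
end of the experiment. Animals that die before the maturity day contribute
only to survival: their trait cells are missing.

Randomness: one integer seed feeds a ``numpy.random.SeedSequence`` that is
split into named streams (genotype intercepts, batch offsets, then one
stream per population x genotype for residuals and event times), so any
subset of the design is reproducible independently of the rest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .dataio import (
    ARMS,
    CSV_COLUMNS,
    PAIR_ARMS,
    PAIR_COMPONENTS,
    POPULATIONS,
    TRAITS,
)

DEFAULT_INTERCEPTS = {"fecundity": 10.0, "size_mm": 3.0, "age_days": 10.0}


def _per_trait(value, traits=TRAITS) -> dict[str, float]:
    """Broadcast a scalar to a per-trait dict; pass dicts through (0-filled)."""
    if isinstance(value, Mapping):
        return {t: float(value.get(t, 0.0)) for t in traits}
    return {t: float(value) for t in traits}


@dataclass
class WeibullHazard:
    """Weibull event-time model with log proportional-hazards shifts.

    ``scale`` is the Weibull scale in days at log-hazard 0; ``shape`` 1
    reduces to an exponential. A positive shift multiplies the hazard by
    ``exp(shift)`` (shorter lives).
    """

    scale: float = 120.0
    shape: float = 1.0
    log_hazard_arm: dict[str, float] = field(default_factory=dict)
    log_hazard_pop: dict[str, float] = field(default_factory=dict)

    def survival_at(self, t: float, population: str = None, arm: str = None) -> float:
        """Closed-form S(t) for one population x arm cell."""
        mult = np.exp(
            self.log_hazard_arm.get(arm, 0.0) + self.log_hazard_pop.get(population, 0.0)
        )
        return float(np.exp(-mult * (t / self.scale) ** self.shape))

    def draw_times(self, rng: np.random.Generator, log_hazard: float, size: int) -> np.ndarray:
        # inverse-transform: T = scale * (E / m)^(1/shape), E ~ Exp(1)
        e = rng.exponential(1.0, size=size)
        return self.scale * (e / np.exp(log_hazard)) ** (1.0 / self.shape)


@dataclass
class SyntheticConfig:
    """Full generative parameterization; its values are the ground truth."""

    populations: tuple[str, ...] = POPULATIONS
    n_genotypes_per_pop: int = 10
    n_replicates: int = 3
    n_batches: int = 3
    arms: tuple[str, ...] = tuple(ARMS)

    trait_intercepts: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    #: population -> trait -> additive shift (genetic-evolution truth)
    population_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    #: arm code -> trait -> additive shift (plasticity truth); CTRL must be 0
    treatment_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    #: (population, arm) -> trait -> shift (evolution-of-plasticity truth)
    pop_arm_effects: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    #: pair arm code -> trait -> shift (stressor-interaction truth;
    #: 0 = additive, same sign as the summed single effects = synergistic,
    #: opposite sign = antagonistic)
    stressor_interaction: dict[str, dict[str, float]] = field(default_factory=dict)

    sd_genotype: dict[str, float] | float = 0.5
    sd_batch: dict[str, float] | float = 0.2
    sd_residual: dict[str, float] | float = 1.0

    hazard: WeibullHazard = field(default_factory=WeibullHazard)
    censor_day: float = 40.0
    maturity_day: float = 8.0
    #: animals dying before maturity_day get missing trait cells
    maturity_missingness: bool = True
    fecundity_mode: str = "rounded_gaussian"  # or "count" (Poisson)

    seed: int = 0

    def __post_init__(self):
        self.sd_genotype = _per_trait(self.sd_genotype)
        self.sd_batch = _per_trait(self.sd_batch)
        self.sd_residual = _per_trait(self.sd_residual)
        self.validate()

    def validate(self) -> None:
        if self.n_genotypes_per_pop < 1 or self.n_replicates < 1 or self.n_batches < 1:
            raise ValueError("all counts must be >= 1")
        if len(self.populations) < 1:
            raise ValueError("at least one population required")
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown treatment arms: {sorted(unknown)}")
        for sd in (*self.sd_genotype.values(), *self.sd_batch.values(),
                   *self.sd_residual.values()):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.censor_day <= 0:
            raise ValueError("censor_day must be > 0")
        ctrl = self.treatment_effects.get("CTRL", {})
        if any(v != 0 for v in ctrl.values()):
            raise ValueError("the control arm must have zero treatment effect")
        if self.fecundity_mode not in ("rounded_gaussian", "count"):
            raise ValueError(f"unknown fecundity_mode {self.fecundity_mode!r}")
        for pair in self.stressor_interaction:
            if pair not in PAIR_ARMS:
                raise ValueError(f"stressor_interaction key {pair!r} is not a pair arm")

    # -- truth ------------------------------------------------------------

    def cell_mean(self, population: str, arm: str, trait: str) -> float:
        """Noiseless expected trait value for one population x arm cell."""
        return (
            self.trait_intercepts.get(trait, 0.0)
            + self.population_effects.get(population, {}).get(trait, 0.0)
            + self.treatment_effects.get(arm, {}).get(trait, 0.0)
            + self.pop_arm_effects.get((population, arm), {}).get(trait, 0.0)
            + self.stressor_interaction.get(arm, {}).get(trait, 0.0)
        )

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "hazard" in d and isinstance(d["hazard"], Mapping):
            d["hazard"] = WeibullHazard(**d["hazard"])
        if "pop_arm_effects" in d:
            d["pop_arm_effects"] = {
                (k.split(":")[0], k.split(":")[1]) if isinstance(k, str) else tuple(k): v
                for k, v in d["pop_arm_effects"].items()
            }
        for key in ("populations", "arms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def additive_treatment_effects(
    single_effects: Mapping[str, Mapping[str, float]],
) -> dict[str, dict[str, float]]:
    """Expand single-arm effects into a full treatment_effects dict whose
    pair arms are exactly the sum of their components (additive truth).

    Deviations from additivity belong in ``stressor_interaction``, not here.
    """
    out = {arm: dict(vals) for arm, vals in single_effects.items()}
    for pair, (a, b) in PAIR_COMPONENTS.items():
        combined: dict[str, float] = {}
        for trait in set(single_effects.get(a, {})) | set(single_effects.get(b, {})):
            combined[trait] = (
                single_effects.get(a, {}).get(trait, 0.0)
                + single_effects.get(b, {}).get(trait, 0.0)
            )
        out[pair] = combined
    return out


def truth_interaction_class(config: SyntheticConfig, trait: str, pair: str) -> str:
    """Expected interaction label implied by the configured parameters.

    Zero configured interaction shift means the pair arm is exactly the sum
    of its single-stressor effects (additive). A shift with the same sign as
    the summed single effects inflates the joint response (synergistic); an
    opposite-sign shift attenuates it (antagonistic).
    """
    if pair not in PAIR_ARMS:
        raise KeyError(f"{pair!r} is not a stressor-pair arm")
    if trait not in TRAITS:
        raise KeyError(f"unknown trait {trait!r}")
    shift = config.stressor_interaction.get(pair, {}).get(trait, 0.0)
    if shift == 0:
        return "additive"
    a, b = PAIR_COMPONENTS[pair]
    single_sum = (
        config.treatment_effects.get(a, {}).get(trait, 0.0)
        + config.treatment_effects.get(b, {}).get(trait, 0.0)
    )
    if single_sum == 0 or np.sign(shift) == np.sign(single_sum):
        return "synergistic"
    return "antagonistic"


@dataclass
class GroundTruth:
    """Realized and implied truth for one generated dataset."""

    cell_means: pd.DataFrame          # population, arm, trait, mean
    genotype_intercepts: pd.DataFrame  # population, genotype, trait, value
    batch_offsets: pd.DataFrame        # batch, trait, value
    decompositions: pd.DataFrame       # transition, trait, component, value
    interaction_classes: dict[str, dict[str, str]]  # pair -> trait -> label
    survival_at_censor: pd.DataFrame   # population, arm, survival

    def to_json(self, path) -> None:
        payload = {
            "cell_means": self.cell_means.to_dict(orient="records"),
            "genotype_intercepts": self.genotype_intercepts.to_dict(orient="records"),
            "batch_offsets": self.batch_offsets.to_dict(orient="records"),
            "decompositions": self.decompositions.to_dict(orient="records"),
            "interaction_classes": self.interaction_classes,
            "survival_at_censor": self.survival_at_censor.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# transitions for which truth decompositions are pre-computed; mirrors
# mechanisms.HISTORICAL_TRANSITIONS (kept literal here to avoid a cycle)
_TRUTH_TRANSITIONS = (
    ("T1_T2_multistress", "EP", "PP", "HALI", "HAHI"),
    ("T2_T3_multistress", "PP", "CWP", "HAHI", "LALI"),
    ("T1_T2_insecticide", "EP", "PP", "LI", "HI"),
    ("T2_T3_algae", "PP", "CWP", "HA", "LA"),
    ("T2_T3_insecticide", "PP", "CWP", "HI", "LI"),
)


def _truth_decompositions(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for label, anc, desc, env0, env1 in _TRUTH_TRANSITIONS:
        if not {anc, desc} <= set(config.populations) or not {env0, env1} <= set(config.arms):
            continue
        for trait in TRAITS:
            m = {(p, a): config.cell_mean(p, a, trait)
                 for p in (anc, desc) for a in (env0, env1)}
            plasticity = m[(anc, env1)] - m[(anc, env0)]
            genetic = m[(desc, env0)] - m[(anc, env0)]
            gxe = (m[(desc, env1)] - m[(desc, env0)]) - (m[(anc, env1)] - m[(anc, env0)])
            rows += [
                {"transition": label, "trait": trait, "component": "plasticity", "value": plasticity},
                {"transition": label, "trait": trait, "component": "genetic_evolution", "value": genetic},
                {"transition": label, "trait": trait, "component": "evolution_of_plasticity", "value": gxe},
            ]
    return pd.DataFrame(rows)


def generate_experiment(config: SyntheticConfig, seed: int | None = None):
    """Generate one dataset and its ground truth.

    Returns ``(records, truth)`` where ``records`` is a long-format table in
    the :mod:`~multistress.dataio` dialect (one row per animal) and
    ``truth`` is a :class:`GroundTruth`. Identical config and seed give
    identical output.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(int(seed))
    n_pop = len(config.populations)
    n_geno = config.n_genotypes_per_pop
    geno_ss, batch_ss, *animal_ss = ss.spawn(2 + n_pop * n_geno)

    geno_rng = np.random.default_rng(geno_ss)
    batch_rng = np.random.default_rng(batch_ss)

    geno_rows, geno_int = [], {}
    for p in config.populations:
        for g in range(1, n_geno + 1):
            gid = f"{p}-G{g:02d}"
            vals = {t: geno_rng.normal(0.0, config.sd_genotype[t]) for t in TRAITS}
            geno_int[(p, gid)] = vals
            geno_rows.append({"population": p, "genotype": gid, **vals})

    batches = [f"B{b}" for b in range(1, config.n_batches + 1)]
    batch_rows, batch_off = [], {}
    for b in batches:
        vals = {t: batch_rng.normal(0.0, config.sd_batch[t]) for t in TRAITS}
        batch_off[b] = vals
        batch_rows.append({"batch": b, **vals})

    records = []
    stream = iter(animal_ss)
    for p in config.populations:
        for g in range(1, n_geno + 1):
            gid = f"{p}-G{g:02d}"
            rng = np.random.default_rng(next(stream))
            for arm_code_ in config.arms:
                arm = ARMS[arm_code_]
                log_h = (
                    config.hazard.log_hazard_arm.get(arm_code_, 0.0)
                    + config.hazard.log_hazard_pop.get(p, 0.0)
                )
                times = config.hazard.draw_times(rng, log_h, config.n_replicates)
                for r in range(1, config.n_replicates + 1):
                    batch = batches[(r - 1) % config.n_batches]
                    t_event = times[r - 1]
                    event = bool(t_event <= config.censor_day)
                    death_day = float(min(t_event, config.censor_day))
                    traits = {}
                    immature_death = (
                        config.maturity_missingness
                        and event
                        and death_day < config.maturity_day
                    )
                    for trait in TRAITS:
                        mean = (
                            config.cell_mean(p, arm_code_, trait)
                            + geno_int[(p, gid)][trait]
                            + batch_off[batch][trait]
                        )
                        if trait == "fecundity" and config.fecundity_mode == "count":
                            val = float(rng.poisson(max(mean, 1e-9)))
                        else:
                            val = mean + rng.normal(0.0, config.sd_residual[trait])
                            if trait == "fecundity":
                                val = float(max(round(val), 0))
                            else:
                                val = float(max(val, 1e-3))
                        traits[trait] = np.nan if immature_death else val
                    records.append({
                        "population": p, "genotype": gid, "batch": batch,
                        "algae_level": arm.algae_level,
                        "insecticide_level": arm.insecticide_level,
                        "replicate": r, **traits,
                        "death_day": max(round(death_day, 3), 1e-3), "event": event,
                    })

    records = pd.DataFrame(records, columns=list(CSV_COLUMNS))

    cell_rows = [
        {"population": p, "arm": a, "trait": t, "mean": config.cell_mean(p, a, t)}
        for p in config.populations for a in config.arms for t in TRAITS
    ]
    surv_rows = [
        {"population": p, "arm": a,
         "survival": config.hazard.survival_at(config.censor_day, p, a)}
        for p in config.populations for a in config.arms
    ]
    truth = GroundTruth(
        cell_means=pd.DataFrame(cell_rows),
        genotype_intercepts=pd.DataFrame(geno_rows),
        batch_offsets=pd.DataFrame(batch_rows),
        decompositions=_truth_decompositions(config),
        interaction_classes={
            pair: {t: truth_interaction_class(config, t, pair) for t in TRAITS}
            for pair in PAIR_ARMS if pair in config.arms
        },
        survival_at_censor=pd.DataFrame(surv_rows),
    )
    return records, truth
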