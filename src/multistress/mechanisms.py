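"""Decomposition of trait change across a temporal transition.

A transition contrasts an ancestral population (coded 0) with a descendant
population (coded 1) across an ancestral environment (coded 0) and a
descendant environment (coded 1). Writing ``m(pop, env)`` for the cell mean
of a trait, the three components are

* plasticity               ``m(anc, env1) - m(anc, env0)``
* genetic evolution        ``m(desc, env0) - m(anc, env0)``
* evolution of plasticity  ``(m(desc, env1) - m(desc, env0)) - (m(anc, env1) - m(anc, env0))``

which reconstruct the descendant cell exactly:
``m(desc, env1) = m(anc, env0) + plasticity + genetic + GxE``.

Cell means are computed on genotype means first (each genotype weighted
equally regardless of replication). Relative contributions are absolute
values normalized to 100%. Component significance comes from planned
contrasts in a 2x2 model with 0/1 coding and a genotype random intercept:
with treatment coding the environment coefficient is the plasticity
contrast, the population coefficient the genetic-evolution contrast, and
the interaction coefficient the evolution-of-plasticity contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

from .dataio import ARMS, TRAITS, ValidationError, arm_codes

logger = logging.getLogger(__name__)

COMPONENTS = ("plasticity", "genetic_evolution", "evolution_of_plasticity")


@dataclass(frozen=True)
class TransitionSpec:
    """One ancestral->descendant contrast over populations and arms."""

    label: str
    ancestral_population: str
    descendant_population: str
    ancestral_arm: str
    descendant_arm: str

    def __post_init__(self):
        cells = {
            (self.ancestral_population, self.ancestral_arm),
            (self.ancestral_population, self.descendant_arm),
            (self.descendant_population, self.ancestral_arm),
            (self.descendant_population, self.descendant_arm),
        }
        if len(cells) != 4:
            raise ValueError("transition cells are not distinct")
        for arm in (self.ancestral_arm, self.descendant_arm):
            if arm not in ARMS:
                raise ValueError(f"unknown arm {arm!r}")


#: the two historical multistress transitions plus three hypothetical
#: single-stress variants
HISTORICAL_TRANSITIONS = (
    TransitionSpec("T1_T2_multistress", "EP", "PP", "HALI", "HAHI"),
    TransitionSpec("T2_T3_multistress", "PP", "CWP", "HAHI", "LALI"),
    TransitionSpec("T1_T2_insecticide", "EP", "PP", "LI", "HI"),
    TransitionSpec("T2_T3_algae", "PP", "CWP", "HA", "LA"),
    TransitionSpec("T2_T3_insecticide", "PP", "CWP", "HI", "LI"),
)


@dataclass
class DecompositionResult:
    trait: str
    transition: str
    plasticity: float
    genetic_evolution: float
    evolution_of_plasticity: float
    #: percentages keyed by component; all-NaN when every component is 0
    relative_contribution: dict[str, float] = field(default_factory=dict)
    #: per-component chisq/df/p, or None when tests were not requested
    contrast_tests: pd.DataFrame | None = None

    @property
    def components(self) -> dict[str, float]:
        return {
            "plasticity": self.plasticity,
            "genetic_evolution": self.genetic_evolution,
            "evolution_of_plasticity": self.evolution_of_plasticity,
        }

    def to_rows(self) -> pd.DataFrame:
        rows = []
        for comp, est in self.components.items():
            row = {
                "transition": self.transition,
                "trait": self.trait,
                "component": comp,
                "estimate": est,
                "rel_contribution_pct": self.relative_contribution.get(comp, np.nan),
                "chisq": np.nan, "df": np.nan, "p": np.nan,
            }
            if self.contrast_tests is not None:
                hit = self.contrast_tests.loc[self.contrast_tests["component"] == comp]
                if not hit.empty:
                    row.update(chisq=hit.iloc[0]["chisq"], df=hit.iloc[0]["df"],
                               p=hit.iloc[0]["p"])
            rows.append(row)
        return pd.DataFrame(rows)


def _cell_means(sub: pd.DataFrame, spec: TransitionSpec, trait: str) -> dict:
    """Mean of genotype means per (population, arm) cell."""
    means = {}
    for pop in (spec.ancestral_population, spec.descendant_population):
        for arm in (spec.ancestral_arm, spec.descendant_arm):
            cell = sub.loc[(sub["population"] == pop) & (sub["_arm"] == arm), trait]
            if cell.empty:
                raise ValidationError(
                    f"empty cell ({pop}, {arm}) for trait {trait!r} "
                    f"in transition {spec.label!r}"
                )
            gm = (
                sub.loc[(sub["population"] == pop) & (sub["_arm"] == arm)]
                .groupby("genotype", observed=True)[trait]
                .mean()
            )
            means[(pop, arm)] = float(gm.mean())
    return means


def _contrast_tests(sub: pd.DataFrame, spec: TransitionSpec, trait: str) -> pd.DataFrame:
    data = sub.rename(columns={trait: "y"}).copy()
    data["pop01"] = (data["population"] == spec.descendant_population).astype(float)
    data["env01"] = (data["_arm"] == spec.descendant_arm).astype(float)
    data["_geno"] = data["population"] + ":" + data["genotype"].astype(str)
    formula = "y ~ pop01 * env01"

    params = cov = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(formula, data, groups=data["_geno"]).fit(
                reml=True, method="lbfgs"
            )
        if float(res.cov_re.iloc[0, 0]) > 1e-8 * max(res.scale, 1e-12):
            params, cov = res.fe_params, res.cov_params().loc[
                res.fe_params.index, res.fe_params.index
            ]
    except (np.linalg.LinAlgError, ValueError):
        pass
    if params is None:
        ols = smf.ols(formula, data).fit()
        params, cov = ols.params, ols.cov_params()

    mapping = {
        "plasticity": "env01",
        "genetic_evolution": "pop01",
        "evolution_of_plasticity": "pop01:env01",
    }
    rows = []
    for comp, name in mapping.items():
        b = float(params[name])
        se = float(np.sqrt(cov.loc[name, name]))
        chisq = (b / se) ** 2 if se > 0 else np.nan
        rows.append({
            "component": comp, "chisq": chisq, "df": 1,
            "p": float(stats.chi2.sf(chisq, 1)) if np.isfinite(chisq) else np.nan,
        })
    return pd.DataFrame(rows)


def decompose_transition(
    records: pd.DataFrame,
    spec: TransitionSpec,
    trait: str,
    fit_tests: bool = True,
) -> DecompositionResult:
    """Decompose one trait's change across one transition.

    Raises :class:`~multistress.dataio.ValidationError` when any of the four
    (population, arm) cells has no non-missing trait value. Set
    ``fit_tests=False`` to skip the planned-contrast model (e.g. in
    simulation loops where only the estimates matter).
    """
    sub = records.copy()
    sub["_arm"] = arm_codes(sub)
    sub = sub.loc[
        sub["population"].isin([spec.ancestral_population, spec.descendant_population])
        & sub["_arm"].isin([spec.ancestral_arm, spec.descendant_arm])
    ].dropna(subset=[trait])
    means = _cell_means(sub, spec, trait)

    anc, desc = spec.ancestral_population, spec.descendant_population
    e0, e1 = spec.ancestral_arm, spec.descendant_arm
    plasticity = means[(anc, e1)] - means[(anc, e0)]
    genetic = means[(desc, e0)] - means[(anc, e0)]
    gxe = (means[(desc, e1)] - means[(desc, e0)]) - (means[(anc, e1)] - means[(anc, e0)])

    total = abs(plasticity) + abs(genetic) + abs(gxe)
    if total > 0:
        rel = {
            "plasticity": 100 * abs(plasticity) / total,
            "genetic_evolution": 100 * abs(genetic) / total,
            "evolution_of_plasticity": 100 * abs(gxe) / total,
        }
    else:
        rel = {c: np.nan for c in COMPONENTS}

    tests = _contrast_tests(sub, spec, trait) if fit_tests else None
    return DecompositionResult(
        trait=trait, transition=spec.label,
        plasticity=plasticity, genetic_evolution=genetic,
        evolution_of_plasticity=gxe,
        relative_contribution=rel, contrast_tests=tests,
    )


def run_historical_transitions(
    records: pd.DataFrame,
    traits=TRAITS,
    transitions=HISTORICAL_TRANSITIONS,
    fit_tests: bool = True,
) -> pd.DataFrame:
    """Run every transition x trait decomposition that the data support.

    Transitions whose arms or populations are absent are skipped with a
    logged reason. Returns the long-format result table
    (``transition,trait,component,estimate,rel_contribution_pct,chisq,df,p``).
    """
    arm_col = arm_codes(records)
    present_arms = set(arm_col)
    present_pops = set(records["population"])
    frames = []
    for spec in transitions:
        needed_arms = {spec.ancestral_arm, spec.descendant_arm}
        needed_pops = {spec.ancestral_population, spec.descendant_population}
        if not needed_arms <= present_arms or not needed_pops <= present_pops:
            logger.warning(
                "skipping transition %s: missing arms %s or populations %s",
                spec.label, needed_arms - present_arms, needed_pops - present_pops,
            )
            continue
        for trait in traits:
            try:
                res = decompose_transition(records, spec, trait, fit_tests=fit_tests)
            except ValidationError as exc:
                logger.warning("skipping %s/%s: %s", spec.label, trait, exc)
                continue
            frames.append(res.to_rows())
    if not frames:
        return pd.DataFrame(
            columns=["transition", "trait", "component", "estimate",
                     "rel_contribution_pct", "chisq", "df", "p"]
        )
    return pd.concat(frames, ignore_index=True)
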