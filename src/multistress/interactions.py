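"""Additive-null-model classification of stressor-pair interactions.

For each trait and population, the effect of a single stressor arm is the
standardized mean difference d = (mean(treatment) - mean(control)) / sigma,
where sigma is by default the sample SD of the concatenated treatment and
control values. The additive prediction for a pair arm is the sum of its
two single-stressor effects (e.g. LAHI is predicted by d(LA) + d(HI)).

The pair is called *additive* when the prediction falls inside the 95%
bootstrap CI of the observed joint effect; otherwise *synergistic* when the
observed effect is larger in magnitude along the direction of the
prediction, and *antagonistic* when it is smaller (an observed effect whose
sign opposes the prediction is flagged as a reversal and counted
antagonistic). A one-sample t-test across genotype-level interaction
contrasts (d_mix,g - d_A,g - d_B,g) quantifies the deviation from
additivity when per-genotype replication allows it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import (
    PAIR_ARMS,
    PAIR_COMPONENTS,
    SINGLE_ARMS,
    TRAITS,
    ValidationError,
    arm_codes,
    is_control,
)

logger = logging.getLogger(__name__)

CLASSES = ("additive", "synergistic", "antagonistic")


@dataclass
class EffectSize:
    """Standardized mean difference of one arm vs control."""

    d: float
    n_treatment: int
    n_control: int
    ci_low: float
    ci_high: float
    sd_pooled: float
    trait: str = ""
    population: str = ""
    arm: str = ""

    def __post_init__(self):
        if not (self.ci_low <= self.d <= self.ci_high):
            raise ValueError("effect size must lie inside its own CI")


def _point_d(treat: np.ndarray, ctrl: np.ndarray, sd_mode: str) -> tuple[float, float]:
    if sd_mode == "concatenated":
        sd = np.concatenate([treat, ctrl]).std(ddof=1)
    elif sd_mode == "two_group_pooled":
        n_t, n_c = len(treat), len(ctrl)
        sd = np.sqrt(
            ((n_t - 1) * treat.var(ddof=1) + (n_c - 1) * ctrl.var(ddof=1))
            / (n_t + n_c - 2)
        )
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    if sd == 0:
        raise ValidationError("pooled standard deviation is zero")
    return float((treat.mean() - ctrl.mean()) / sd), float(sd)


def effect_size(
    treatment_values,
    control_values,
    *,
    n_boot: int = 2000,
    rng: np.random.Generator | int | None = None,
    sd_mode: str = "concatenated",
    trait: str = "",
    population: str = "",
    arm: str = "",
) -> EffectSize:
    """Standardized effect size with a bias-corrected bootstrap 95% CI.

    Bootstrap resamples are drawn within each group (2000 by default);
    pass a seeded ``numpy.random.Generator`` (or an int seed) for
    reproducibility.
    """
    treat = np.asarray(pd.Series(treatment_values).dropna(), dtype=float)
    ctrl = np.asarray(pd.Series(control_values).dropna(), dtype=float)
    if len(treat) < 2 or len(ctrl) < 2:
        raise ValidationError("need >= 2 non-missing values on each side")
    d, sd = _point_d(treat, ctrl, sd_mode)

    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    it = rng.integers(0, len(treat), size=(n_boot, len(treat)))
    ic = rng.integers(0, len(ctrl), size=(n_boot, len(ctrl)))
    bt, bc = treat[it], ctrl[ic]
    if sd_mode == "concatenated":
        bsd = np.concatenate([bt, bc], axis=1).std(ddof=1, axis=1)
    else:
        n_t, n_c = len(treat), len(ctrl)
        bsd = np.sqrt(
            ((n_t - 1) * bt.var(ddof=1, axis=1) + (n_c - 1) * bc.var(ddof=1, axis=1))
            / (n_t + n_c - 2)
        )
    valid = bsd > 0
    boot = (bt.mean(axis=1) - bc.mean(axis=1))[valid] / bsd[valid]

    if len(boot) == 0 or np.ptp(boot) == 0:
        lo = hi = d
    else:
        # bias-corrected percentile interval
        prop = np.clip(np.mean(boot < d), 1 / (len(boot) + 1), 1 - 1 / (len(boot) + 1))
        z0 = stats.norm.ppf(prop)
        zcrit = stats.norm.ppf(0.975)
        alpha_lo = stats.norm.cdf(2 * z0 - zcrit)
        alpha_hi = stats.norm.cdf(2 * z0 + zcrit)
        lo, hi = np.quantile(boot, [alpha_lo, alpha_hi])
    lo, hi = min(lo, d), max(hi, d)
    return EffectSize(
        d=d, n_treatment=len(treat), n_control=len(ctrl),
        ci_low=float(lo), ci_high=float(hi), sd_pooled=sd,
        trait=trait, population=population, arm=arm,
    )


@dataclass
class InteractionCall:
    trait: str
    population: str
    pair: str
    d_a: float
    d_b: float
    e_mix_predicted: float
    observed: EffectSize
    classification: str
    reversal: bool = False
    t_statistic: float = np.nan
    df: float = np.nan
    p_value: float = np.nan

    def to_row(self) -> dict:
        return {
            "population": self.population, "trait": self.trait, "pair": self.pair,
            "dA": self.d_a, "dB": self.d_b, "e_mix": self.e_mix_predicted,
            "d_obs": self.observed.d,
            "ci_low": self.observed.ci_low, "ci_high": self.observed.ci_high,
            "class": self.classification, "reversal": self.reversal,
            "t": self.t_statistic, "df": self.df, "p": self.p_value,
        }


def classify_interaction(
    d_a: EffectSize,
    d_b: EffectSize,
    observed_joint: EffectSize,
    *,
    genotype_contrasts=None,
    rule: str = "magnitude",
) -> InteractionCall:
    """Classify one pair arm against its additive prediction.

    ``rule="magnitude"`` (default) compares |observed| with |predicted|
    along the direction of the prediction once the CI excludes the
    prediction; ``rule="literal"`` applies the raw smaller/larger-than-CI
    wording (equivalent for deleterious, negative effects; flips for
    positive ones).
    """
    for e in (d_a, d_b):
        if (e.trait, e.population) != (observed_joint.trait, observed_joint.population):
            raise ValidationError("effect sizes disagree on trait/population")
    e_mix = d_a.d + d_b.d
    obs = observed_joint
    reversal = False
    if obs.ci_low <= e_mix <= obs.ci_high:
        label = "additive"
    elif rule == "literal":
        label = "synergistic" if e_mix > obs.ci_high else "antagonistic"
    elif rule == "magnitude":
        if e_mix != 0 and obs.d != 0 and np.sign(obs.d) != np.sign(e_mix):
            label, reversal = "antagonistic", True
        elif abs(obs.d) > abs(e_mix):
            label = "synergistic"
        else:
            label = "antagonistic"
    else:
        raise ValueError(f"unknown rule {rule!r}")

    t = df = p = np.nan
    if genotype_contrasts is not None:
        contrasts = np.asarray(pd.Series(genotype_contrasts).dropna(), dtype=float)
        if len(contrasts) >= 2:
            tt = stats.ttest_1samp(contrasts, 0.0)
            t, df, p = float(tt.statistic), float(len(contrasts) - 1), float(tt.pvalue)

    return InteractionCall(
        trait=obs.trait, population=obs.population, pair=obs.arm,
        d_a=d_a.d, d_b=d_b.d, e_mix_predicted=float(e_mix),
        observed=obs, classification=label, reversal=reversal,
        t_statistic=t, df=df, p_value=p,
    )


def _genotype_contrasts(sub, ctrl, pair, trait, sd_mode):
    """Per-genotype (d_mix - d_A - d_B); NaN where a genotype lacks data."""
    a, b = PAIR_COMPONENTS[pair]
    out = []
    for geno, gctrl in ctrl.groupby("genotype", observed=True):
        cvals = gctrl[trait].dropna().to_numpy()
        if len(cvals) < 2:
            continue
        ds = {}
        for arm in (a, b, pair):
            tvals = (
                sub.loc[(sub["_arm"] == arm) & (sub["genotype"] == geno), trait]
                .dropna().to_numpy()
            )
            if len(tvals) < 2:
                break
            try:
                ds[arm], _ = _point_d(tvals, cvals, sd_mode)
            except ValidationError:
                break
        if len(ds) == 3:
            out.append(ds[pair] - ds[a] - ds[b])
    return np.asarray(out)


def interaction_survey(
    records: pd.DataFrame,
    *,
    n_boot: int = 2000,
    seed: int = 0,
    rule: str = "magnitude",
    sd_mode: str = "concatenated",
    traits=TRAITS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every population x trait x pair cell present in the data.

    Returns ``(calls, summary)``: the per-cell call table and the class
    percentages overall and per trait, computed over classified cells only.
    Cells whose single-stressor or pair arm is missing are skipped with a
    log entry and excluded from denominators.
    """
    data = records.copy()
    data["_arm"] = arm_codes(data)
    rng = np.random.default_rng(seed)
    rows = []
    for pop in sorted(data["population"].unique()):
        psub = data.loc[data["population"] == pop]
        ctrl = psub.loc[is_control(psub)]
        for trait in traits:
            cvals = ctrl[trait].dropna()
            if len(cvals) < 2:
                logger.warning("%s/%s: insufficient control data; skipped", pop, trait)
                continue
            singles = {}
            for arm in SINGLE_ARMS:
                tvals = psub.loc[psub["_arm"] == arm, trait].dropna()
                if len(tvals) >= 2:
                    try:
                        singles[arm] = effect_size(
                            tvals, cvals, n_boot=n_boot, rng=rng, sd_mode=sd_mode,
                            trait=trait, population=pop, arm=arm,
                        )
                    except ValidationError as exc:
                        logger.warning("%s/%s/%s: %s", pop, trait, arm, exc)
            for pair in PAIR_ARMS:
                a, b = PAIR_COMPONENTS[pair]
                tvals = psub.loc[psub["_arm"] == pair, trait].dropna()
                if a not in singles or b not in singles or len(tvals) < 2:
                    logger.warning("%s/%s/%s: missing arm data; cell skipped",
                                   pop, trait, pair)
                    continue
                try:
                    obs = effect_size(
                        tvals, cvals, n_boot=n_boot, rng=rng, sd_mode=sd_mode,
                        trait=trait, population=pop, arm=pair,
                    )
                except ValidationError as exc:
                    logger.warning("%s/%s/%s: %s", pop, trait, pair, exc)
                    continue
                contrasts = _genotype_contrasts(psub, ctrl, pair, trait, sd_mode)
                call = classify_interaction(
                    singles[a], singles[b], obs,
                    genotype_contrasts=contrasts if len(contrasts) >= 2 else None,
                    rule=rule,
                )
                rows.append(call.to_row())

    calls = pd.DataFrame(rows)
    summary = summarize_calls(calls)
    return calls, summary


def summarize_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Class percentages overall and per trait over classified cells."""
    rows = []
    if calls.empty:
        return pd.DataFrame(columns=["scope", "class", "n", "pct"])
    scopes = [("all", calls)] + [
        (trait, grp) for trait, grp in calls.groupby("trait", observed=True)
    ]
    for scope, grp in scopes:
        counts = grp["class"].value_counts()
        total = int(counts.sum())
        for cls in CLASSES:
            n = int(counts.get(cls, 0))
            rows.append({
                "scope": scope, "class": cls, "n": n,
                "pct": 100.0 * n / total if total else np.nan,
            })
    return pd.DataFrame(rows)
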