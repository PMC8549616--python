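"""Trait mixed-model ANOVAs and parametric survival fits.

Trait models are Gaussian linear mixed models with a random intercept for
genotype nested within population (implemented as a random intercept over
the population:genotype identifier, which is the nesting-safe encoding when
genotype labels are unique within population). Fixed-effect terms are
tested with Wald chi-square statistics, Type II by default: the statistic
for a term is the joint Wald test of that term's coefficients in the model
that contains every term *not* containing it (higher-order relatives
excluded), which respects marginality and reduces to the classical ANOVA
on balanced designs.

When the genotype variance is estimated at the boundary (0) or the mixed
model fails to converge, the fit falls back to ordinary least squares with
a logged warning; on such data the two give identical fixed-effect tests.

Survival is a Weibull accelerated-failure-time model on (death day, event
flag), fitted with lifelines, with the same factorial fixed terms and the
same per-term Wald testing scheme.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats

import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from lifelines import WeibullAFTFitter

from .dataio import PAIR_ARMS, ValidationError, arm_codes

logger = logging.getLogger(__name__)

#: design token -> (patsy RHS, treatment arms entering the subset)
DESIGNS = {
    "pop_algae": ("C(population) * C(algae_level)", ("HA", "LA")),
    "pop_insecticide": ("C(population) * C(insecticide_level)", ("HI", "LI")),
    "threeway": (
        "C(population) * C(algae_level) * C(insecticide_level)",
        PAIR_ARMS,
    ),
}

_DESIGN_ALIASES = {
    "pop*algae": "pop_algae",
    "pop*insecticide": "pop_insecticide",
    "pop*algae*insecticide": "threeway",
}


def _resolve_design(design: str) -> str:
    design = _DESIGN_ALIASES.get(design, design)
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {sorted(DESIGNS)}")
    return design


def _pretty_term(term: patsy.Term) -> str:
    def clean(code: str) -> str:
        return code.removeprefix("C(").removesuffix(")")
    return ":".join(clean(f.name()) for f in term.factors) or "Intercept"


def _term_formula(lhs: str, terms: list[patsy.Term]) -> str:
    rhs = " + ".join(t.name() for t in terms if t.factors)
    return f"{lhs} ~ {rhs}" if rhs else f"{lhs} ~ 1"


def _type2_term_sets(formula: str):
    """Yield (term, formula-for-that-term's-test) per non-intercept term."""
    desc = patsy.ModelDesc.from_formula(formula)
    terms = [t for t in desc.rhs_termlist if t.factors]
    lhs = desc.lhs_termlist[0].name()
    for term in terms:
        tf = set(f.name() for f in term.factors)
        kept = [
            u for u in terms
            if u == term or not tf <= set(f.name() for f in u.factors)
        ]
        yield term, _term_formula(lhs, kept)


@dataclass
class AnovaTable:
    """Per-term chi-square tests for one fitted trait model."""

    trait: str
    formula: str
    method: str  # "lmm" or "ols-fallback" or "ols"
    random_structure: str
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)  # term, chisq, df, p

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        out.insert(0, "trait", self.trait)
        return out

    def to_csv(self, path) -> None:
        self.rows.rename(columns={"p": "p"}).to_csv(path, index=False)

    def term(self, name: str) -> pd.Series:
        match = self.rows.loc[self.rows["term"] == name]
        if match.empty:
            raise KeyError(f"no term {name!r} in table ({list(self.rows['term'])})")
        return match.iloc[0]


def _fit_once(formula: str, data: pd.DataFrame, engine: str):
    """Fit one model; return (params, cov, design_info, extra)."""
    if engine == "lmm":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups=data["_geno"])
            res = None
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    res = model.fit(reml=True, method=method)
                    break
                except (np.linalg.LinAlgError, ValueError):
                    continue
            if res is None:
                raise np.linalg.LinAlgError(f"mixed model failed for {formula!r}")
        params = res.fe_params
        cov = res.cov_params().loc[params.index, params.index]
        re_var = float(res.cov_re.iloc[0, 0])
        boundary = re_var <= 1e-8 * max(res.scale, 1e-12)
        return params, cov, res.model.data.design_info, {"boundary": boundary, "res": res}
    res = smf.ols(formula, data).fit()
    return res.params, res.cov_params(), res.model.data.design_info, {"res": res}


def _wald_term(params, cov, design_info, term: patsy.Term):
    # select by design-column name: fitter parameter order may differ
    sl = design_info.term_slices[term]
    names = design_info.column_names[sl]
    b = np.asarray(pd.Series(params)[names], dtype=float)
    V = np.asarray(pd.DataFrame(cov).loc[names, names], dtype=float)
    chisq = float(b @ np.linalg.solve(V, b))
    df = len(b)
    return chisq, df, float(stats.chi2.sf(chisq, df))


def _trait_subset(records: pd.DataFrame, trait: str, design: str) -> pd.DataFrame:
    formula_rhs, arms = DESIGNS[design]
    sub = records.loc[arm_codes(records).isin(arms)].copy()
    sub = sub.dropna(subset=[trait])
    if sub.empty:
        raise ValidationError(f"no records with non-missing {trait!r} in design {design!r}")
    sub["_geno"] = sub["population"].astype(str) + ":" + sub["genotype"].astype(str)
    return sub.rename(columns={trait: "y"})


def _check_factors(sub: pd.DataFrame, formula_rhs: str) -> None:
    for factor in ("population", "algae_level", "insecticide_level"):
        if f"C({factor})" in formula_rhs and sub[factor].nunique() < 2:
            raise ValidationError(
                f"factor {factor!r} has fewer than 2 levels in the model subset"
            )
    dm = patsy.dmatrix(formula_rhs, sub)
    if np.linalg.matrix_rank(np.asarray(dm)) < dm.shape[1]:
        raise ValidationError(
            f"rank-deficient design for {formula_rhs!r} (empty factorial cell?)"
        )


def fit_trait_model(
    records: pd.DataFrame,
    trait: str,
    design: str = "threeway",
    test_type: str = "wald2",
    engine: str = "auto",
) -> AnovaTable:
    """Fit a factorial trait model and test each fixed term.

    Parameters
    ----------
    records
        Long-format observation table (typically batch-standardized).
    trait
        One of ``fecundity``, ``size_mm``, ``age_days``.
    design
        ``pop_algae`` (arms HA/LA), ``pop_insecticide`` (arms HI/LI) or
        ``threeway`` (the four pair arms). The ``pop*algae``-style aliases
        are accepted.
    test_type
        ``wald2`` (default, marginality-respecting Type II Wald),
        ``wald3`` (joint test of each term in the full model), or
        ``lr`` (Type II likelihood-ratio, ML refits).
    engine
        ``auto`` tries the mixed model and falls back to OLS at the
        variance boundary; ``lmm`` or ``ols`` force an engine.
    """
    design = _resolve_design(design)
    formula_rhs, _ = DESIGNS[design]
    sub = _trait_subset(records, trait, design)
    _check_factors(sub, formula_rhs)
    formula = f"y ~ {formula_rhs}"

    method = engine
    if engine == "auto":
        try:
            _, _, _, extra = _fit_once(formula, sub, "lmm")
            method = "ols-fallback" if extra["boundary"] else "lmm"
            if extra["boundary"]:
                logger.warning(
                    "genotype variance at boundary for %s/%s; falling back to OLS",
                    trait, design,
                )
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("mixed model failed (%s); falling back to OLS", exc)
            method = "ols-fallback"
    fit_engine = "lmm" if method == "lmm" else "ols"

    def _all_rows(fit_engine: str) -> list[dict]:
        rows = []
        if test_type in ("wald2", "lr"):
            for term, term_formula in _type2_term_sets(formula):
                if test_type == "wald2":
                    params, cov, dinfo, _ = _fit_once(term_formula, sub, fit_engine)
                    chisq, df, p = _wald_term(params, cov, dinfo, term)
                else:
                    chisq, df, p = _lr_term(term_formula, term, sub, fit_engine)
                rows.append({"term": _pretty_term(term), "chisq": chisq, "df": df, "p": p})
        elif test_type == "wald3":
            params, cov, dinfo, _ = _fit_once(formula, sub, fit_engine)
            for term in dinfo.terms:
                if not term.factors:
                    continue
                chisq, df, p = _wald_term(params, cov, dinfo, term)
                rows.append({"term": _pretty_term(term), "chisq": chisq, "df": df, "p": p})
        else:
            raise ValueError(f"unknown test_type {test_type!r}")
        return rows

    try:
        rows = _all_rows(fit_engine)
    except np.linalg.LinAlgError as exc:
        if fit_engine != "lmm" or engine == "lmm":
            raise
        logger.warning("mixed model failed during term tests (%s); using OLS", exc)
        method, fit_engine = "ols-fallback", "ols"
        rows = _all_rows("ols")

    return AnovaTable(
        trait=trait,
        formula=formula,
        method=method,
        random_structure="genotype nested in population (random intercept)"
        if method == "lmm" else "none",
        rows=pd.DataFrame(rows),
    )


def _lr_term(term_formula: str, term: patsy.Term, data: pd.DataFrame, engine: str):
    desc = patsy.ModelDesc.from_formula(term_formula)
    reduced_terms = [t for t in desc.rhs_termlist if t.factors and t != term]
    reduced_formula = _term_formula("y", reduced_terms)

    def loglike(f):
        if engine == "lmm":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.mixedlm(f, data, groups=data["_geno"]).fit(
                    reml=False, method="lbfgs"
                )
            return res.llf
        return smf.ols(f, data).fit().llf

    full_info = patsy.dmatrix(term_formula.split("~", 1)[1], data).design_info
    sl = full_info.term_slices[term]
    df = sl.stop - sl.start
    chisq = float(2 * (loglike(term_formula) - loglike(reduced_formula)))
    chisq = max(chisq, 0.0)
    return chisq, df, float(stats.chi2.sf(chisq, df))


def posthoc_population_contrasts(
    records: pd.DataFrame, trait: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey-adjusted pairwise population contrasts on the pair-arm subset.

    The replication unit is the genotype: each genotype contributes its
    mean trait value across the combined-stressor arms (balanced weighting
    over whatever cells it appears in), and populations are compared on
    those genotype means with Tukey's HSD.

    Returns one row per population pair with the mean difference, adjusted
    p-value and rejection flag, plus a ``flag`` column marking, for each
    pair, which population is higher when the contrast is significant.
    """
    sub = records.loc[arm_codes(records).isin(PAIR_ARMS)].dropna(subset=[trait])
    if sub["population"].nunique() < 2:
        raise ValidationError("need at least 2 populations for post hoc contrasts")
    gmeans = (
        sub.groupby(["population", "genotype"], observed=True)[trait]
        .mean()
        .reset_index()
    )
    tk = pairwise_tukeyhsd(gmeans[trait], gmeans["population"], alpha=alpha)
    out = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    out = out.rename(columns={"p-adj": "p_adj"})
    for col in ("meandiff", "p_adj", "lower", "upper"):
        out[col] = out[col].astype(float)
    out["reject"] = out["reject"].astype(bool)
    out["flag"] = [
        (f"{r.group2} higher" if r.meandiff > 0 else f"{r.group1} higher")
        if r.reject else ""
        for r in out.itertuples()
    ]
    return out


@dataclass
class SurvivalFit:
    """Per-term Wald tests and coefficients for one survival model."""

    formula: str
    family: str
    n_events: int
    n_censored: int
    terms: pd.DataFrame    # term, chisq, df, p
    coefs: pd.DataFrame    # coef, se per design column
    baseline: dict
    flag: str = ""

    @property
    def no_mortality_signal(self) -> bool:
        return self.flag == "no_mortality_signal"

    def term(self, name: str) -> pd.Series:
        match = self.terms.loc[self.terms["term"] == name]
        if match.empty:
            raise KeyError(f"no term {name!r}")
        return match.iloc[0]


def _survival_subset(records: pd.DataFrame, design: str) -> pd.DataFrame:
    _, arms = DESIGNS[design]
    sub = records.loc[arm_codes(records).isin(arms)].copy()
    if (sub["death_day"] <= 0).any():
        raise ValidationError("non-positive death_day in survival subset")
    return sub


def _aft_fit(rhs: str, data: pd.DataFrame):
    dm = patsy.dmatrix(rhs, data, return_type="dataframe")
    dinfo = dm.design_info
    cols = [c for c in dm.columns if c != "Intercept"]
    frame = dm[cols].copy()
    frame["death_day"] = data["death_day"].to_numpy()
    frame["event"] = data["event"].astype(bool).to_numpy()
    aft = WeibullAFTFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aft.fit(frame, duration_col="death_day", event_col="event")
    params = aft.params_.loc["lambda_"]
    cov = aft.variance_matrix_.loc["lambda_", "lambda_"]
    return aft, params, cov, dinfo


def fit_survival(
    records: pd.DataFrame,
    design: str = "threeway",
    family: str = "weibull_aft",
    test_type: str = "wald2",
) -> SurvivalFit:
    """Fit a parametric survival model on (death_day, event).

    ``family`` is ``weibull_aft`` (default: Weibull accelerated-failure-time
    model) or ``logistic`` (binomial GLM on the died/survived flag — a
    secondary reading of an ambiguous methods description, provided for
    comparison). Per-term chi-squares use the same Type II Wald scheme as
    the trait models. With zero events the fit is degenerate and returned
    flagged ``no_mortality_signal``.
    """
    design = _resolve_design(design)
    formula_rhs, _ = DESIGNS[design]
    sub = _survival_subset(records, design)
    _check_factors(sub, formula_rhs)
    n_events = int(sub["event"].astype(bool).sum())
    n_censored = int(len(sub) - n_events)
    if n_events == 0:
        logger.warning("no mortality events in subset; returning degenerate fit")
        return SurvivalFit(
            formula=f"(death_day, event) ~ {formula_rhs}", family=family,
            n_events=0, n_censored=n_censored,
            terms=pd.DataFrame(columns=["term", "chisq", "df", "p"]),
            coefs=pd.DataFrame(columns=["coef", "se"]),
            baseline={}, flag="no_mortality_signal",
        )

    if family == "logistic":
        return _logistic_survival(sub, formula_rhs, n_events, n_censored)
    if family != "weibull_aft":
        raise ValueError(f"unknown survival family {family!r}")

    sub = sub.sort_values(list(sub.columns)).reset_index(drop=True)  # order invariance
    aft, params, cov, dinfo = _aft_fit(formula_rhs, sub)

    rows = []
    if test_type == "wald2":
        for term, term_formula in _type2_term_sets(f"y ~ {formula_rhs}"):
            rhs_t = term_formula.split("~", 1)[1]
            _, p_t, c_t, di_t = _aft_fit(rhs_t, sub)
            chisq, df, p = _wald_term(p_t, c_t, di_t, term)
            rows.append({"term": _pretty_term(term), "chisq": chisq, "df": df, "p": p})
    else:
        for term in dinfo.terms:
            if not term.factors:
                continue
            chisq, df, p = _wald_term(params, cov, dinfo, term)
            rows.append({"term": _pretty_term(term), "chisq": chisq, "df": df, "p": p})

    se = pd.Series(np.sqrt(np.diag(cov)), index=params.index)
    coefs = pd.DataFrame({"coef": params, "se": se})
    rho = float(np.exp(aft.params_.loc[("rho_", "Intercept")]))
    lam = float(np.exp(params.get("Intercept", np.nan)))
    return SurvivalFit(
        formula=f"(death_day, event) ~ {formula_rhs}",
        family="weibull_aft",
        n_events=n_events,
        n_censored=n_censored,
        terms=pd.DataFrame(rows),
        coefs=coefs,
        baseline={"distribution": "weibull", "shape_rho": rho, "scale_lambda": lam},
    )


def _logistic_survival(sub, formula_rhs, n_events, n_censored) -> SurvivalFit:
    import statsmodels.api as sm

    data = sub.copy()
    data["died"] = data["event"].astype(int)
    rows = []
    for term, term_formula in _type2_term_sets(f"died ~ {formula_rhs}"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.glm(term_formula, data, family=sm.families.Binomial()).fit()
        dinfo = res.model.data.design_info
        chisq, df, p = _wald_term(res.params, res.cov_params(), dinfo, term)
        rows.append({"term": _pretty_term(term), "chisq": chisq, "df": df, "p": p})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.glm(f"died ~ {formula_rhs}", data, family=sm.families.Binomial()).fit()
    coefs = pd.DataFrame({"coef": res.params, "se": res.bse})
    return SurvivalFit(
        formula=f"died ~ {formula_rhs}", family="logistic",
        n_events=n_events, n_censored=n_censored,
        terms=pd.DataFrame(rows), coefs=coefs,
        baseline={"distribution": "binomial"},
    )
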