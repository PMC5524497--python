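"""Mixed-model analyses of the field and search experiments.

Field data: mixed-effects Cox regression of time-to-predation on the 2x2
colour x texture commonness factors (or on the continuous typicality
distances), with target pattern and block as normal random effects on the
log-hazard.  Factors are tested by the change in deviance between nested
models against a chi-squared distribution.  When the colour x texture
interaction is significant the data are split by colour match and the
texture effect is tested within each stratum.

Search data: log10 reaction times are analysed with a linear mixed model,
and hit/miss outcomes with a binomial generalized linear mixed model, with
the z-scored distances from the colour and texture centroids as continuous
fixed effects and target and background as (crossed) random intercepts.
Miss and timeout trials are excluded from the reaction-time fit; timeouts
count as misses in the binomial fit.  Per-effect chi-squared statistics for
the mixed models are Wald statistics (z^2 on 1 d.f.).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from ._coxfrailty import CoxFitError, CoxFrailtyFit, fit_cox_frailty

__all__ = [
    "CoxFitError",
    "FieldModelFit",
    "TestResult",
    "code_events",
    "fit_field_model",
    "lr_deviance_test",
    "split_by_colour_and_test_texture",
    "fit_rt_model",
    "fit_hit_model",
    "results_table",
]

ALPHA = 0.05

# outcome fates and how survival analysis codes them: only confirmed bird
# predation is an event; other predators, lost targets and survival to the
# end of the trial are censoring
_FATE_EVENT = {"bird": 1, "spider": 0, "slug": 0, "snail": 0, "ant": 0,
               "lost": 0, "survived": 0}


@dataclass(frozen=True)
class TestResult:
    """A chi-squared test with the coefficients of the underlying fit."""

    statistic: float
    df: int
    p_value: float
    coefficients: pd.DataFrame = field(default_factory=pd.DataFrame)
    label: str = ""

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("degrees of freedom must be >= 1")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        object.__setattr__(self, "statistic", float(max(self.statistic, 0.0)))


def code_events(raw: pd.DataFrame, end_time: float = 72.0) -> pd.DataFrame:
    """Translate raw outcome fates into survival records.

    ``raw`` needs columns ``fate`` (bird / spider / slug / snail / ant /
    lost / survived) and ``time`` (hours at the recording inspection).
    Returns a copy with an ``event`` column (1 = bird predation, else
    censored) and survivors censored at ``end_time``.
    """
    unknown = set(raw["fate"]) - set(_FATE_EVENT)
    if unknown:
        raise ValueError(f"unknown fate label(s): {sorted(unknown)}")
    out = raw.copy()
    out["event"] = out["fate"].map(_FATE_EVENT).astype(int)
    out.loc[out["fate"] == "survived", "time"] = end_time
    return out


@dataclass(frozen=True)
class FieldModelFit:
    """A fitted mixed Cox model plus its fixed-term list for nesting checks."""

    fit: CoxFrailtyFit
    fixed_terms: tuple[str, ...]

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def deviance(self) -> float:
        return self.fit.deviance

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": list(self.fit.fixed_names),
            "estimate": self.fit.beta,
            "se": self.fit.se_beta,
        })


def _field_design(records: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    cols = []
    if "colour" in terms or "texture" in terms or "colour:texture" in terms:
        if "treatment" in records.columns:
            colour = records["treatment"].str.contains("Col+", regex=False).astype(float)
            texture = records["treatment"].str.contains("Txt+", regex=False).astype(float)
        else:
            colour = records["colour_common"].astype(float)
            texture = records["texture_common"].astype(float)
    for term in terms:
        if term == "colour":
            cols.append(colour.to_numpy())
        elif term == "texture":
            cols.append(texture.to_numpy())
        elif term == "colour:texture":
            cols.append((colour * texture).to_numpy())
        elif term in ("d_colour", "d_texture"):
            cols.append(records[term].to_numpy(float))
        elif term == "d_colour:d_texture":
            cols.append((records["d_colour"] * records["d_texture"]).to_numpy(float))
        else:
            raise ValueError(f"unknown fixed term {term!r}")
    return np.column_stack(cols) if cols else np.empty((len(records), 0))


def fit_field_model(
    records: pd.DataFrame,
    include_interaction: bool = True,
    terms: tuple[str, ...] | None = None,
    theta: dict[str, float] | None = None,
) -> FieldModelFit:
    """Mixed-effects Cox regression of the field survival records.

    Default fixed effects are the two-level commonness factors ``colour``
    and ``texture`` (from the treatment label) and optionally their
    interaction; pass ``terms`` for other structures (e.g. the continuous
    distances).  Random intercepts: target pattern and block.
    """
    if terms is None:
        terms = ("colour", "texture") + (("colour:texture",) if include_interaction else ())
    if (records["event"] == 1).sum() < 1:
        raise CoxFitError("no bird-predation events in the records")
    X = _field_design(records, terms)
    target_codes, _ = pd.factorize(
        records["tree_id"].astype(str) + "/" + records["patch_id"].astype(str), sort=True
    )
    block_codes, _ = pd.factorize(records["block"], sort=True)
    groups: dict[str, np.ndarray] = {}
    if target_codes.max() > 0:
        groups["target"] = target_codes
    if block_codes.max() > 0:
        groups["block"] = block_codes
    fit = fit_cox_frailty(
        X, records["time"].to_numpy(float), records["event"].to_numpy(int),
        groups=groups, fixed_names=terms, theta=theta,
    )
    return FieldModelFit(fit=fit, fixed_terms=terms)


def lr_deviance_test(full: FieldModelFit, reduced: FieldModelFit) -> TestResult:
    """Likelihood-ratio (change-in-deviance) test between nested Cox fits.

    The statistic is the drop in deviance (-2 integrated log-likelihood),
    the degrees of freedom the difference in fixed-effect counts, and the
    p-value the upper chi-squared tail.
    """
    if not set(reduced.fixed_terms) <= set(full.fixed_terms):
        raise ValueError(
            f"models are not nested: {reduced.fixed_terms} vs {full.fixed_terms}"
        )
    df = len(full.fixed_terms) - len(reduced.fixed_terms)
    if df < 1:
        if full.fixed_terms == reduced.fixed_terms:
            return TestResult(statistic=0.0, df=1, p_value=1.0,
                              coefficients=full.coefficients(), label="identical models")
        raise ValueError("full model has no extra fixed effects")
    stat = reduced.deviance - full.deviance
    if stat < -1e-6:
        warnings.warn(
            f"negative deviance change ({stat:.3g}); variance-component "
            "optimization noise — statistic clamped at 0", RuntimeWarning
        )
    stat = max(stat, 0.0)
    return TestResult(
        statistic=stat, df=df, p_value=float(sp_stats.chi2.sf(stat, df)),
        coefficients=full.coefficients(),
        label="LR " + " vs ".join([str(full.fixed_terms), str(reduced.fixed_terms)]),
    )


def split_by_colour_and_test_texture(records: pd.DataFrame) -> dict[str, TestResult]:
    """Test the texture effect separately within each colour stratum.

    Follows the stratified follow-up to a significant colour x texture
    interaction: split by colour match and run the texture-vs-null deviance
    test in each half.  Returns {"Col+": ..., "Col-": ...}.
    """
    colour = records["treatment"].str.contains("Col+", regex=False)
    out = {}
    for label, mask in (("Col+", colour), ("Col-", ~colour)):
        stratum = records[mask]
        if stratum.empty or (stratum["event"] == 1).sum() == 0:
            raise CoxFitError(f"colour stratum {label} has no events")
        full = fit_field_model(stratum, terms=("texture",))
        null = fit_field_model(stratum, terms=())
        out[label] = lr_deviance_test(full, null)
    return out


def _zscore(x: pd.Series) -> np.ndarray:
    v = x.to_numpy(float)
    return (v - v.mean()) / v.std(ddof=0)


def _wald_table(terms, estimates, ses) -> pd.DataFrame:
    est = np.asarray(estimates, float)
    se = np.asarray(ses, float)
    chi2 = (est / se) ** 2
    return pd.DataFrame({
        "term": list(terms), "estimate": est, "se": se,
        "chi2": chi2, "df": 1, "p": sp_stats.chi2.sf(chi2, 1),
    })


def fit_rt_model(trials: pd.DataFrame, include_interaction: bool = False) -> TestResult:
    """Linear mixed model of log10 reaction time on the z-scored distances.

    Excludes practice, miss and timeout trials; random intercepts for
    target and background (crossed, via variance components).  The returned
    TestResult carries the full coefficient table; its headline statistic
    is the colour-distance effect.
    """
    import statsmodels.formula.api as smf

    d = trials.copy()
    if "is_practice" in d.columns:
        d = d[~d["is_practice"]]
    d = d[(d["hit"] == 1) & (~d["timed_out"])]
    if d.empty:
        raise ValueError("no analysable hit trials")
    d["log_rt"] = np.log10(d["rt"])
    d["zd_colour"] = _zscore(d["d_colour"])
    d["zd_texture"] = _zscore(d["d_texture"])
    d["one_group"] = 1
    rhs = "zd_colour * zd_texture" if include_interaction else "zd_colour + zd_texture"
    vc = {"target": "0 + C(target)", "background": "0 + C(background)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm(
            f"log_rt ~ {rhs}", data=d, groups="one_group",
            vc_formula=vc, re_formula="0",
        ).fit(reml=False)
    terms = [t for t in fit.fe_params.index if t != "Intercept"]
    table = _wald_table(terms, fit.fe_params[terms], fit.bse[terms])
    head = table.iloc[0]
    return TestResult(statistic=float(head["chi2"]), df=1, p_value=float(head["p"]),
                      coefficients=table, label="log10 RT ~ " + rhs)


def fit_hit_model(trials: pd.DataFrame, include_interaction: bool = False) -> TestResult:
    """Binomial GLMM of hit/miss on the z-scored distances.

    Timeouts count as misses; practice trials are excluded.  Fitted by
    variational Bayes (the mixed-logit posterior mean/SD give the Wald
    chi-squared per effect).
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    d = trials.copy()
    if "is_practice" in d.columns:
        d = d[~d["is_practice"]]
    d["hit"] = (d["hit"].astype(int) & ~d["timed_out"]).astype(int)
    if d["hit"].nunique() < 2:
        raise ValueError("hits are all-success or all-failure; binomial model unidentifiable")
    d["zd_colour"] = _zscore(d["d_colour"])
    d["zd_texture"] = _zscore(d["d_texture"])
    rhs = "zd_colour * zd_texture" if include_interaction else "zd_colour + zd_texture"
    vc = {"target": "0 + C(target)", "background": "0 + C(background)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = BinomialBayesMixedGLM.from_formula(
            f"hit ~ {rhs}", vc, d
        ).fit_vb()
    names = list(fit.model.exog_names)
    keep = [i for i, t in enumerate(names) if t != "Intercept"]
    table = _wald_table(
        [names[i] for i in keep], fit.fe_mean[keep], fit.fe_sd[keep]
    )
    head = table.iloc[0]
    return TestResult(statistic=float(head["chi2"]), df=1, p_value=float(head["p"]),
                      coefficients=table, label="hit ~ " + rhs)


def results_table(results: dict[str, TestResult]) -> pd.DataFrame:
    """Flatten named test results into one table (model, term, estimate, ...)."""
    rows = []
    for name, res in results.items():
        if len(res.coefficients):
            for _, r in res.coefficients.iterrows():
                rows.append({
                    "model": name, "term": r["term"],
                    "estimate": r.get("estimate", np.nan), "se": r.get("se", np.nan),
                    "chi2": r.get("chi2", res.statistic),
                    "df": r.get("df", res.df), "p": r.get("p", res.p_value),
                })
        rows.append({"model": name, "term": "(test)", "estimate": np.nan,
                     "se": np.nan, "chi2": res.statistic, "df": res.df,
                     "p": res.p_value})
    return pd.DataFrame(rows)
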