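"""Effect analysis of life-history traits and fitness-score comparison.

Each trait is modelled with a generalized linear model of generation,
rearing temperature and their interaction (reference levels: generation
P, or F1 when P is absent, and 5 degC). Families follow the nature of the
response: gaussian-identity for durations, Poisson with a log link for
counts (switching to negative binomial when the Pearson dispersion
exceeds 1.5), and binomial-logit with clutch-size weights for hatching
percentage. Confidence intervals and p-values use the Wald z
approximation on the link scale. Standardized coefficients come from
refitting on a standardized dataset. Fitness scores are compared among
generation x temperature groups with the tie-corrected Kruskal-Wallis
test, followed by pairwise rank-sum post-hocs with multiplicity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

GAUSSIAN_TRAITS = (
    "lifespan_days",
    "mean_interoviposition_days",
    "age_at_first_oviposition_days",
    "mean_hatching_time_days",
)
COUNT_TRAITS = ("n_molts", "n_ovipositions", "fecundity", "eggs_laid")
PROPORTION_TRAITS = ("hatching_percentage",)

#: Pearson dispersion above which a Poisson count model is refit as
#: negative binomial.
OVERDISPERSION_SWITCH = 1.5


@dataclass(frozen=True)
class GlmSpec:
    """What to fit: a response trait, a family, and predictor terms.

    family is one of "gaussian-identity", "poisson-log", "negbin-log",
    "binomial-logit" or "auto" (chosen from the response name).
    predictors are patsy-style terms over the trait-table columns, e.g.
    ("generation", "temperature", "generation:temperature") or
    ("clutch_index",) for clutch-level models.
    """

    response: str
    family: str = "auto"
    predictors: tuple[str, ...] = (
        "generation",
        "temperature",
        "generation:temperature",
    )

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("predictors must be non-empty")


def resolve_family(spec: GlmSpec, data: pd.DataFrame) -> str:
    """Resolve "auto" to a concrete family from the response name."""
    if spec.family != "auto":
        return spec.family
    if spec.response in PROPORTION_TRAITS:
        return "binomial-logit"
    if spec.response in COUNT_TRAITS:
        return "poisson-log"  # may still switch to negbin on dispersion
    return "gaussian-identity"


def _prepare(data: pd.DataFrame, response: str) -> pd.DataFrame:
    df = data.copy()
    if "generation" in df.columns:
        present = [g for g in ("P", "F1", "F2") if g in set(df["generation"])]
        df["generation"] = pd.Categorical(
            df["generation"], categories=present, ordered=False
        )
    if "rearing_temperature_C" in df.columns:
        temps = sorted(set(df["rearing_temperature_C"]))
        df["temperature"] = pd.Categorical(
            df["rearing_temperature_C"].astype(str),
            categories=[str(t) for t in temps],
        )
    return df.dropna(subset=[response])


def _moment_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB dispersion: solves sum((y-mu)^2 - mu) =
    alpha * sum(mu^2)."""
    num = float(np.sum((y - mu) ** 2 - mu))
    den = float(np.sum(mu**2))
    return max(num / den, 1e-6) if den > 0 else 1e-6


def _fit(formula: str, df: pd.DataFrame, family: str, freq_weights=None):
    fam = {
        "gaussian-identity": sm.families.Gaussian(),
        "poisson-log": sm.families.Poisson(),
        "binomial-logit": sm.families.Binomial(),
    }
    if family in fam:
        model = smf.glm(
            formula, data=df, family=fam[family], freq_weights=freq_weights
        )
        return model.fit()
    if family == "negbin-log":
        # two-stage: Poisson fit for mu, then MoM alpha, then NB refit
        pois = smf.glm(formula, data=df, family=sm.families.Poisson()).fit()
        alpha = _moment_alpha(pois.model.endog, pois.fittedvalues.to_numpy())
        model = smf.glm(
            formula, data=df, family=sm.families.NegativeBinomial(alpha=alpha)
        )
        return model.fit()
    raise ValueError(f"unknown family {family!r}")


def fit_trait_glm(
    data: pd.DataFrame, spec: GlmSpec, standardized: bool = False
) -> pd.DataFrame:
    """Fit a GLM for one trait and return per-term effect estimates.

    Returns a DataFrame with columns term, coefficient (link scale),
    std_error, ci_low, ci_high (95% Wald z), p_value, family, plus
    standardized_coefficient when ``standardized`` fits are requested via
    :func:`standardized_coefficients`.

    For hatching percentage the response is modelled as the per-female
    hatch proportion with fecundity (total eggs) as binomial weights.

    Raises ``ValueError`` naming the offending term when the design is
    singular or a coefficient is inestimable.
    """
    df = _prepare(data, spec.response)
    family = resolve_family(spec, df)
    rhs = " + ".join(spec.predictors)

    freq_weights = None
    response = spec.response
    if family == "binomial-logit" and spec.response == "hatching_percentage":
        df = df.copy()
        df["_hatch_prop"] = df["hatching_percentage"] / 100.0
        weight_col = "fecundity" if "fecundity" in df.columns else "eggs_laid"
        freq_weights = df[weight_col].to_numpy(dtype=float)
        response = "_hatch_prop"

    n_params_guess = len(spec.predictors) + 1
    if len(df) <= n_params_guess:
        raise ValueError(
            f"{spec.response}: {len(df)} observations cannot support "
            f"{n_params_guess}+ parameters"
        )

    formula = f"{response} ~ {rhs}"
    res = _fit(formula, df, family, freq_weights=freq_weights)

    if family == "poisson-log":
        dispersion = res.pearson_chi2 / res.df_resid if res.df_resid > 0 else 1.0
        if dispersion > OVERDISPERSION_SWITCH:
            family = "negbin-log"
            res = _fit(formula, df, family)

    bse = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(bse)):
        bad = [t for t, s in zip(res.params.index, bse) if not np.isfinite(s)]
        raise ValueError(
            f"{spec.response}: inestimable terms (singular design or "
            f"separation): {', '.join(bad)}"
        )
    ci = res.conf_int(alpha=0.05)
    return pd.DataFrame(
        {
            "term": res.params.index,
            "coefficient": res.params.to_numpy(),
            "std_error": bse,
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p_value": np.clip(res.pvalues.to_numpy(), np.nextafter(0, 1), 1.0),
            "family": family,
        }
    ).reset_index(drop=True)


def standardized_coefficients(data: pd.DataFrame, spec: GlmSpec) -> pd.DataFrame:
    """Effect estimates from a refit on standardized data.

    Numeric predictors are centered and scaled to unit SD; so is the
    response when the family is gaussian (for count and binomial families
    the response keeps its natural support and only the predictors are
    standardized, the convention of standardize-and-refit tooling).
    Categorical predictors are untouched. Raises on zero-variance columns.
    """
    df = _prepare(data, spec.response)
    family = resolve_family(spec, df)
    df = df.copy()
    numeric_predictors = [
        p
        for p in spec.predictors
        if p in df.columns and pd.api.types.is_numeric_dtype(df[p])
    ]
    to_scale = list(numeric_predictors)
    if family == "gaussian-identity":
        to_scale.append(spec.response)
    for col in to_scale:
        sd = df[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero-variance column {col!r}")
        df[col] = (df[col] - df[col].mean()) / sd
    out = fit_trait_glm(df, GlmSpec(spec.response, family, spec.predictors))
    return out.rename(columns={"coefficient": "standardized_coefficient"})


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p_value: float
    group_ids: tuple[str, ...]
    posthoc: pd.DataFrame = field(repr=False)


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]],
    posthoc_correction: str = "bonferroni",
) -> KWResult:
    """Tie-corrected Kruskal-Wallis H test over named groups, with
    pairwise two-sided rank-sum post-hoc tests.

    When every pooled value is identical the statistic is 0 and p = 1.
    ``posthoc_correction`` is "bonferroni" (default) or "holm". The
    posthoc table is a symmetric DataFrame of adjusted p-values with NaN
    on the diagonal.
    """
    ids = tuple(str(k) for k in groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in groups]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need >= 2 groups, each with >= 1 observation")
    k = len(arrays)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = st.kruskal(*arrays)
    raw, pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            if np.all(arrays[i] == arrays[i][0]) and np.all(
                arrays[j] == arrays[j][0]
            ) and arrays[i][0] == arrays[j][0]:
                pu = 1.0
            else:
                pu = float(
                    st.mannwhitneyu(
                        arrays[i], arrays[j], alternative="two-sided"
                    ).pvalue
                )
            raw.append(pu)
            pairs.append((i, j))
    method = {"bonferroni": "bonferroni", "holm": "holm"}[posthoc_correction]
    adj = multipletests(raw, method=method)[1] if raw else []
    table = pd.DataFrame(np.nan, index=ids, columns=ids)
    for (i, j), p_adj in zip(pairs, adj):
        table.iloc[i, j] = table.iloc[j, i] = p_adj
    return KWResult(
        H=float(H), df=k - 1, p_value=float(p), group_ids=ids, posthoc=table
    )


def compare_fitness(
    fitness: pd.DataFrame, posthoc_correction: str = "bonferroni"
) -> KWResult:
    """Kruskal-Wallis comparison of fitness scores among
    generation x rearing-temperature groups."""
    groups = {
        f"{gen}@{temp}C": sub["score"].to_numpy()
        for (gen, temp), sub in fitness.groupby(
            ["generation", "rearing_temperature_C"], observed=True, sort=True
        )
    }
    return kruskal_wallis(groups, posthoc_correction=posthoc_correction)
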