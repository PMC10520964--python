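"""Composite per-female fitness score.

Four traits enter the score: fecundity and total hatched eggs (the more
the better, min-max normalized to [0, 1]) and mean egg hatching time and
age at first oviposition (the earlier the better, inverted min-max
normalized so the minimum maps to 1). The score is the mean of the four
normalized components. Females that never laid eggs, or none of whose
eggs hatched, receive a score of exactly zero regardless of the other
traits — hatched offspring being the precondition for contributing to
the next generation.

Normalization bounds are pooled once over all scored females by default,
so every score lives on one common scale; per-group pooling (within
rearing temperature, or within generation x temperature) is available
for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: trait column -> (component name, inverted?)
FITNESS_TRAITS = {
    "fecundity": ("c_fecundity", False),
    "total_hatched_eggs": ("c_hatched", False),
    "mean_hatching_time_days": ("c_hatch_time", True),
    "age_at_first_oviposition_days": ("c_age_first", True),
}


@dataclass(frozen=True)
class NormalizationBounds:
    trait_name: str
    pool_min: float
    pool_max: float

    def __post_init__(self) -> None:
        if self.pool_min > self.pool_max:
            raise ValueError(
                f"{self.trait_name}: pool_min {self.pool_min} > pool_max {self.pool_max}"
            )

    @property
    def degenerate(self) -> bool:
        return self.pool_min == self.pool_max


@dataclass(frozen=True)
class FitnessScore:
    female_id: str
    c_fecundity: float
    c_hatched: float
    c_hatch_time: float
    c_age_first: float
    score: float
    zero_rule_applied: bool

    def components(self) -> tuple[float, float, float, float]:
        return (self.c_fecundity, self.c_hatched, self.c_hatch_time, self.c_age_first)


def compute_bounds(traits: pd.DataFrame, trait_name: str) -> NormalizationBounds:
    """Min and max of ``trait_name`` over the females for which it is
    defined. Raises ``ValueError`` if no female has a defined value."""
    vals = traits[trait_name].dropna()
    if vals.empty:
        raise ValueError(f"no defined values for trait {trait_name!r}")
    return NormalizationBounds(trait_name, float(vals.min()), float(vals.max()))


def minmax_normalize(x: float, bounds: NormalizationBounds) -> float:
    """(x - min) / (max - min); a degenerate pool (max == min) maps to the
    neutral value 0.5."""
    if x < bounds.pool_min or x > bounds.pool_max:
        raise ValueError(
            f"{bounds.trait_name}: value {x} outside pool "
            f"[{bounds.pool_min}, {bounds.pool_max}]"
        )
    if bounds.degenerate:
        return 0.5
    return (x - bounds.pool_min) / (bounds.pool_max - bounds.pool_min)


def inverted_minmax_normalize(x: float, bounds: NormalizationBounds) -> float:
    """1 - (x - min) / (max - min); the pool minimum maps to 1."""
    if bounds.degenerate:
        if x != bounds.pool_min:
            raise ValueError(
                f"{bounds.trait_name}: value {x} outside pool "
                f"[{bounds.pool_min}, {bounds.pool_max}]"
            )
        return 0.5
    return 1.0 - minmax_normalize(x, bounds)


def score_female(
    row: pd.Series, bounds: dict[str, NormalizationBounds]
) -> FitnessScore:
    """Score one female given bounds computed from her scoring pool.

    The zero rule fires when fecundity is 0 or no egg hatched; the score
    is then exactly 0 and the direction-of-benefit components are left at
    NaN where undefined. Otherwise the score is the mean of the defined
    components (all four are defined for any female with at least one
    clutch and one hatched egg).
    """
    zero = row["fecundity"] == 0 or row["total_hatched_eggs"] == 0
    comps = {}
    for trait, (name, inverted) in FITNESS_TRAITS.items():
        x = row[trait]
        if pd.isna(x):
            comps[name] = np.nan
            continue
        f = inverted_minmax_normalize if inverted else minmax_normalize
        comps[name] = f(float(x), bounds[trait])
    if zero:
        score = 0.0
    else:
        defined = [v for v in comps.values() if not np.isnan(v)]
        score = float(np.mean(defined))
    return FitnessScore(
        female_id=str(row["female_id"]),
        score=score,
        zero_rule_applied=bool(zero),
        **comps,
    )


def score_cohort(traits: pd.DataFrame, pool: str = "all") -> pd.DataFrame:
    """Score every female in a derived-trait table.

    Parameters
    ----------
    traits
        Output of :func:`tardistress.life_history.derive_traits`.
    pool
        "all" (default): one min/max pool over all scored females.
        "per-temperature": bounds computed within each rearing
        temperature. Zero-rule females contribute to fecundity and
        hatched-egg bounds (those traits are defined, value 0) but not to
        hatch-time or age bounds when undefined for them.

    Returns a DataFrame with female_id, generation, temperature, the four
    components, the score, and the zero-rule flag.
    """
    if len(traits) < 2:
        raise ValueError("need at least 2 females to pool bounds")
    if pool not in ("all", "per-temperature"):
        raise ValueError(f"unknown pool {pool!r}")
    groups = (
        [(None, traits)]
        if pool == "all"
        else list(traits.groupby("rearing_temperature_C", sort=False))
    )
    out = []
    for _, sub in groups:
        bounds = {t: compute_bounds(sub, t) for t in FITNESS_TRAITS}
        for _, row in sub.iterrows():
            s = score_female(row, bounds)
            out.append(
                {
                    "female_id": s.female_id,
                    "generation": row["generation"],
                    "rearing_temperature_C": row["rearing_temperature_C"],
                    "c_fecundity": s.c_fecundity,
                    "c_hatched": s.c_hatched,
                    "c_hatch_time": s.c_hatch_time,
                    "c_age_first": s.c_age_first,
                    "score": s.score,
                    "zero_rule_applied": s.zero_rule_applied,
                }
            )
    res = pd.DataFrame(out)
    # restore input female order regardless of pooling
    return (
        res.set_index("female_id")
        .loc[traits["female_id"].astype(str)]
        .reset_index()
    )
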