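"""Synthetic cohorts and expression experiments with known ground truth.

Every generator is a pure function of its config and seed, and every
generated dataset satisfies the invariants of the module that consumes
it. The life-history generator emulates individually reared females in a
generation x rearing-temperature layout, including planted zero-fitness
females (no eggs laid, or no egg hatched); the expression generator
emulates the 4-temperature x 2-exposure x 3-replicate count design with
planted monotone DEGs, optional correlated batch structure and optional
outlier samples. Default trait parameters loosely echo the biology of a
cold-adapted parthenogenetic tardigrade (first oviposition around day
34, eggs hatching in about 22 days at 5 degC, oviposition roughly once a
fortnight) but are configuration, not claims about any real population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tardistress.life_history import ClutchRecord, FemaleRecord


# ---------------------------------------------------------------------------
# life-history cohorts


@dataclass(frozen=True)
class GroupParams:
    """Trait distribution for one generation x temperature group.

    Durations are lognormal with the given mean/SD (in days, matched by
    moments); clutch sizes are 1 + Poisson with an order-dependent mean
    (slope > 0 makes clutches grow over the life span); each egg hatches
    independently with ``hatch_prob``. ``n_no_egg`` females lay nothing;
    ``n_no_hatch`` females lay eggs none of which hatch; both are planted
    zero-fitness females on top of ``n`` ordinary ones.
    """

    n: int = 20
    lifespan_mean: float = 350.0
    lifespan_sd: float = 120.0
    age_first_mean: float = 34.0
    age_first_sd: float = 6.0
    interval_mean: float = 14.0
    interval_sd: float = 3.0
    clutch_base_mean: float = 2.5
    clutch_slope: float = 0.15
    hatch_prob: float = 0.55
    hatch_time_mean: float = 22.0
    hatch_time_sd: float = 3.0
    n_no_egg: int = 0
    n_no_hatch: int = 0


def _default_groups() -> dict:
    """Two rearing temperatures, generations F1 and F2; the warm F2 group
    carries 13 no-egg and 13 no-hatch females, mirroring the observed 26
    zero-fitness females in that condition."""
    warm = dict(
        lifespan_mean=90.0, lifespan_sd=25.0, age_first_mean=20.0,
        age_first_sd=4.0, interval_mean=10.0, interval_sd=2.0,
        clutch_base_mean=2.0, clutch_slope=0.1, hatch_prob=0.75,
        hatch_time_mean=11.0, hatch_time_sd=2.0,
    )
    return {
        ("F1", 5): GroupParams(n=30),
        ("F2", 5): GroupParams(n=30, lifespan_mean=300.0, hatch_prob=0.45),
        ("F1", 15): GroupParams(n=30, **warm),
        ("F2", 15): GroupParams(n=24, n_no_egg=13, n_no_hatch=13, **warm),
    }


@dataclass(frozen=True)
class LifeHistoryGenConfig:
    groups: Mapping[tuple[str, int], GroupParams] = field(
        default_factory=_default_groups
    )
    seed: int = 0


def _lognormal(rng, mean: float, sd: float, size=None):
    """Lognormal draws matching the requested mean and SD by moments."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def generate_lifehistory_cohort(
    config: LifeHistoryGenConfig | None = None, seed: int | None = None
) -> tuple[list[FemaleRecord], pd.DataFrame]:
    """Generate a cohort of females plus per-female truth labels.

    Ordinary females are guaranteed at least one clutch and one hatched
    egg, so zero-fitness females downstream are exactly the planted
    no-egg and no-hatch ones. Truth labels carry each female's group and
    planted category ("normal", "no_egg", "no_hatch").
    """
    config = config or LifeHistoryGenConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cohort: list[FemaleRecord] = []
    truth_rows = []
    counter = 0
    for (gen, temp), gp in config.groups.items():
        cats = (
            ["normal"] * gp.n + ["no_egg"] * gp.n_no_egg
            + ["no_hatch"] * gp.n_no_hatch
        )
        for cat in cats:
            counter += 1
            fid = f"{gen}-{temp}C-{counter:03d}"
            lifespan = max(int(round(_lognormal(rng, gp.lifespan_mean, gp.lifespan_sd))), 2)
            clutches: list[ClutchRecord] = []
            if cat != "no_egg":
                day = max(int(round(_lognormal(rng, gp.age_first_mean, gp.age_first_sd))), 1)
                lifespan = max(lifespan, day + 1)
                order = 0
                while day <= lifespan:
                    order += 1
                    lam = max(gp.clutch_base_mean + gp.clutch_slope * (order - 1) - 1.0, 0.05)
                    eggs = 1 + int(rng.poisson(lam))
                    p = 0.0 if cat == "no_hatch" else gp.hatch_prob
                    hatched = int(rng.binomial(eggs, p))
                    times = tuple(
                        float(max(int(round(t)), 1))
                        for t in _lognormal(
                            rng, gp.hatch_time_mean, gp.hatch_time_sd, size=hatched
                        )
                    )
                    clutches.append(
                        ClutchRecord(order, day, eggs, hatched, times)
                    )
                    day += max(int(round(_lognormal(rng, gp.interval_mean, gp.interval_sd))), 1)
                if cat == "normal" and sum(c.eggs_hatched for c in clutches) == 0:
                    # guarantee the planted category: force one hatched egg
                    c0 = clutches[0]
                    t = float(max(int(round(_lognormal(rng, gp.hatch_time_mean, gp.hatch_time_sd))), 1))
                    clutches[0] = ClutchRecord(
                        c0.clutch_index, c0.oviposition_day, c0.eggs_laid, 1, (t,)
                    )
            n_molts = len(clutches) + int(rng.poisson(1.0))
            cohort.append(
                FemaleRecord(
                    female_id=fid,
                    generation=gen,
                    rearing_temperature_C=temp,
                    lifespan_days=lifespan,
                    n_molts=n_molts,
                    clutches=tuple(clutches),
                )
            )
            truth_rows.append(
                {
                    "female_id": fid,
                    "generation": gen,
                    "rearing_temperature_C": temp,
                    "planted_category": cat,
                    **{f"param_{k}": v for k, v in asdict(gp).items()},
                }
            )
    return cohort, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# expression experiments


@dataclass(frozen=True)
class ExpressionGenConfig:
    """Planted-truth count experiment over the temperature gradient.

    DEG genes change monotonically with temperature: a gene with
    direction d and per-step log2 fold change f has mean
    base * 2^(d * f * step) at temperature step 0..3 (5, 10, 15, 20
    degC). Batch structure, when enabled, multiplies a random fraction of
    genes by 2^(+-batch_log2fc) in second-batch samples (gene-specific
    sign), i.e. correlated unwanted variation that library-size
    normalization cannot absorb. Outlier samples get a random half of
    their gene means multiplied by ``outlier_fold``.
    """

    n_genes: int = 2000
    frac_de: float = 0.1
    per_step_log2fc: float = 1.0
    dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (8e5, 1.2e6)
    n_replicates: int = 3
    temperatures: tuple[int, ...] = (5, 10, 15, 20)
    exposures: tuple[str, ...] = ("ST", "LT")
    batch_log2fc: float = 0.0
    batch_gene_fraction: float = 0.5
    n_outliers: int = 0
    outlier_fold: float = 10.0
    base_mean_log: float = np.log(60.0)
    base_mean_sdlog: float = 1.2
    seed: int = 0


def generate_expression_experiment(
    config: ExpressionGenConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (counts, design, truth) for a temperature-gradient
    experiment.

    counts is genes x samples (non-negative integers, NB-distributed);
    design has one row per sample with temperature_C, exposure, replicate
    and batch; truth is a dict with a per-gene DataFrame (is_de,
    direction, per-temperature log2 fold changes, batch-affected flag)
    and a per-sample DataFrame (batch, is_outlier).
    """
    cfg = config or ExpressionGenConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if not 0.0 <= cfg.frac_de <= 1.0:
        raise ValueError("frac_de must lie in [0, 1]")
    if cfg.dispersion <= 0:
        raise ValueError("dispersion must be > 0")

    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    samples, temps, expos, reps = [], [], [], []
    for e in cfg.exposures:
        for t in cfg.temperatures:
            for r in range(1, cfg.n_replicates + 1):
                samples.append(f"{e}_{t}C_r{r}")
                temps.append(t)
                expos.append(e)
                reps.append(r)
    n_samples = len(samples)
    design = pd.DataFrame(
        {"temperature_C": temps, "exposure": expos, "replicate": reps},
        index=pd.Index(samples, name="sample_id"),
    )
    # batch: last replicate of each cell forms the second batch, so batch
    # is orthogonal to temperature and exposure
    batch = np.where(design["replicate"] == cfg.n_replicates, "B", "A")
    design["batch"] = batch

    n_de = int(round(cfg.frac_de * cfg.n_genes)) if cfg.per_step_log2fc != 0 else 0
    is_de = np.zeros(cfg.n_genes, dtype=bool)
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False) if n_de else []
    is_de[de_idx] = True
    direction = np.where(rng.random(cfg.n_genes) < 0.5, 1, -1)
    direction[~is_de] = 0

    base = rng.lognormal(cfg.base_mean_log, cfg.base_mean_sdlog, cfg.n_genes)
    steps = np.array([cfg.temperatures.index(t) for t in temps])
    log2fc_matrix = (
        direction[:, None] * cfg.per_step_log2fc * steps[None, :] * is_de[:, None]
    )

    batch_affected = np.zeros(cfg.n_genes, dtype=bool)
    batch_sign = np.zeros(cfg.n_genes)
    if cfg.batch_log2fc != 0.0:
        n_b = int(round(cfg.batch_gene_fraction * cfg.n_genes))
        b_idx = rng.choice(cfg.n_genes, size=n_b, replace=False)
        batch_affected[b_idx] = True
        batch_sign[b_idx] = np.where(rng.random(n_b) < 0.5, 1.0, -1.0)
    in_batch_b = (batch == "B").astype(float)
    log2fc_matrix = log2fc_matrix + (
        batch_sign[:, None] * cfg.batch_log2fc * in_batch_b[None, :]
    )

    is_outlier = np.zeros(n_samples, dtype=bool)
    if cfg.n_outliers:
        out_idx = rng.choice(n_samples, size=cfg.n_outliers, replace=False)
        is_outlier[out_idx] = True
        for j in out_idx:
            shifted = rng.random(cfg.n_genes) < 0.5
            log2fc_matrix[shifted, j] += np.log2(cfg.outlier_fold)

    lib = rng.uniform(*cfg.lib_size_range, size=n_samples)
    rel = base[:, None] * np.exp2(log2fc_matrix)
    mean_lib = rel.sum(axis=0)
    mu = rel * (lib / mean_lib)[None, :]
    r = 1.0 / cfg.dispersion
    counts = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12)))
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)

    gene_truth = pd.DataFrame(
        {
            "is_de": is_de,
            "direction": np.where(direction > 0, "up", np.where(direction < 0, "down", "flat")),
            "batch_affected": batch_affected,
            **{
                f"true_log2_fc_{t}C": direction * cfg.per_step_log2fc * i * is_de
                for i, t in enumerate(cfg.temperatures)
                if i > 0
            },
        },
        index=genes,
    )
    sample_truth = pd.DataFrame(
        {"batch": batch, "is_outlier": is_outlier}, index=design.index
    )
    return counts_df, design, {"genes": gene_truth, "samples": sample_truth}


# ---------------------------------------------------------------------------
# hit tables and annotations


def generate_hit_table(
    true_map: Mapping[str, str | None],
    n_decoys: int = 2,
    seed: int = 0,
) -> list:
    """Hit records whose best hit per contig is its true protein.

    ``true_map`` sends each contig to its protein (or None for contigs
    that should stay singletons and get no rows). Decoy hits against
    other proteins carry strictly lower bitscores.
    """
    from tardistress.expression import HitRecord

    rng = np.random.default_rng(seed)
    proteins = sorted({p for p in true_map.values() if p is not None})
    records = []
    for contig, prot in true_map.items():
        if prot is None:
            continue
        top = float(rng.uniform(150, 400))
        length = int(rng.integers(80, 400))
        records.append(
            HitRecord(
                contig, prot, float(rng.uniform(60, 100)), length,
                int(rng.integers(0, 20)), int(rng.integers(0, 3)),
                1, length, 1, length,
                float(10 ** -rng.uniform(20, 80)), top,
            )
        )
        decoy_pool = [p for p in proteins if p != prot]
        for d in rng.choice(decoy_pool, size=min(n_decoys, len(decoy_pool)), replace=False):
            length = int(rng.integers(60, 300))
            records.append(
                HitRecord(
                    contig, str(d), float(rng.uniform(40, 90)), length,
                    int(rng.integers(0, 40)), int(rng.integers(0, 5)),
                    1, length, 1, length,
                    float(10 ** -rng.uniform(3, 19)),
                    float(top * rng.uniform(0.3, 0.9)),
                )
            )
    return records


def generate_annotation(
    universe: Sequence[str],
    deg_set: Sequence[str],
    annotated_in_universe: int,
    observed_in_set: int,
    term_id: str = "TERM:0001",
    n_background_terms: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Build an annotation table where ``term_id`` has an exact planted
    overlap: K genes annotated in the universe of size N, exactly k of
    them inside the DEG set of size n. Raises on infeasible (N, K, n, k).
    Optional background terms annotate random gene subsets.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    deg = [g for g in deg_set]
    N, K, n, k = len(universe), annotated_in_universe, len(deg), observed_in_set
    if not set(deg) <= set(universe):
        raise ValueError("deg_set must be a subset of the universe")
    if K < 1 or K > N:
        raise ValueError(f"annotated count K={K} infeasible for universe N={N}")
    if k > min(n, K) or K - k > N - n:
        raise ValueError(f"overlap k={k} infeasible for (N={N}, K={K}, n={n})")
    outside = [g for g in universe if g not in set(deg)]
    chosen = list(rng.choice(deg, size=k, replace=False)) + list(
        rng.choice(outside, size=K - k, replace=False)
    )
    rows = [{"gene_id": g, "term_id": term_id} for g in chosen]
    for b in range(n_background_terms):
        size = int(rng.integers(1, max(N // 3, 2)))
        for g in rng.choice(universe, size=size, replace=False):
            rows.append({"gene_id": g, "term_id": f"BG:{b:04d}"})
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])
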