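"""Post-quantification expression analysis for a temperature-gradient
design.

The samples come from a 4-temperature (5, 10, 15, 20 degC) x 2-exposure
(ST = 1 day, LT = 15 days) x replicate layout with 5 degC as the control
group. The chain implemented here: CPM/log-CPM transforms; collapsing
assembled contigs into genes by shared best protein hit; selection of
empirical control genes as the least-varying in a first-pass omnibus
analysis; estimation of unwanted-variation factors from those controls;
PCA-based outlier sample flagging; per-gene negative-binomial DEG
calling against the control temperature with an omnibus likelihood-ratio
test at FDR < 0.01; classification of each significant gene as up- or
down-regulated with temperature; and hypergeometric term enrichment
requiring FDR < 0.05 and observed/expected > 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from tardistress import nb_glm

DEFAULT_DEG_FDR = 0.01
DEFAULT_ENRICH_FDR = 0.05
DEFAULT_MIN_OE = 3.0
CONTROL_TEMPERATURE_C = 5


# ---------------------------------------------------------------------------
# containers and validation


def validate_counts(counts: pd.DataFrame) -> None:
    """Counts: genes x samples, non-negative, every sample with reads."""
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("count matrix has negative entries")
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")


def validate_design(design: pd.DataFrame, counts: pd.DataFrame | None = None) -> None:
    required = {"temperature_C", "exposure"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design is missing columns: {sorted(missing)}")
    bad_t = set(design["temperature_C"]) - {5, 10, 15, 20}
    if bad_t:
        raise ValueError(f"unknown temperatures: {sorted(bad_t)}")
    bad_e = set(design["exposure"]) - {"ST", "LT"}
    if bad_e:
        raise ValueError(f"unknown exposures: {sorted(bad_e)}")
    if counts is not None and not set(counts.columns) <= set(design.index):
        extra = sorted(set(counts.columns) - set(design.index))
        raise ValueError(f"samples missing from design: {extra}")


def read_counts(path) -> pd.DataFrame:
    """TSV with gene ids in the first column, samples in the rest."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


# ---------------------------------------------------------------------------
# transforms


def cpm_transform(
    counts: pd.DataFrame,
    log: bool = False,
    row_normalize: bool = False,
    prior: float = 1.0,
) -> pd.DataFrame:
    """Counts per million per sample; optionally log2(cpm + prior) and/or
    row mean centering (the display transform used for heat maps)."""
    validate_counts(counts)
    lib = counts.sum(axis=0).astype(float)
    out = counts * 1e6 / lib
    if log:
        out = np.log2(out + prior)
    if row_normalize:
        out = out.sub(out.mean(axis=1), axis=0)
    return out


# ---------------------------------------------------------------------------
# contig -> gene grouping


@dataclass(frozen=True)
class HitRecord:
    """One row of 12-column tabular protein-search output."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bitscore: float


def read_hit_table(path) -> list[HitRecord]:
    """Read BLAST/diamond tabular output (outfmt 6 column order)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=[
            "query_id", "subject_id", "percent_identity", "alignment_length",
            "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
            "e_value", "bitscore",
        ],
    )
    return [HitRecord(**row) for row in df.to_dict("records")]


def group_genes_by_best_hit(
    hits: Iterable[HitRecord], contigs: Sequence[str]
) -> dict[str, str]:
    """Collapse contigs into genes by shared best protein hit.

    Each contig's best hit is its highest-bitscore record, with ties
    broken by lower e-value and then lexicographically smallest subject
    id; contigs sharing a best-hit subject become one gene named after
    that subject. Contigs without hits are singleton genes under their
    own id. Returns contig id -> gene id covering every listed contig.
    """
    contig_set = set(contigs)
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.query_id not in contig_set:
            raise ValueError(f"hit references unknown contig {h.query_id!r}")
        cur = best.get(h.query_id)
        if cur is None or (-h.bitscore, h.e_value, h.subject_id) < (
            -cur.bitscore, cur.e_value, cur.subject_id
        ):
            best[h.query_id] = h
    return {
        c: (best[c].subject_id if c in best else c) for c in contigs
    }


def collapse_counts(counts: pd.DataFrame, grouping: Mapping[str, str]) -> pd.DataFrame:
    """Sum contig-level counts into gene-level counts per the grouping."""
    genes = counts.index.map(lambda c: grouping.get(c, c))
    return counts.groupby(genes).sum()


# ---------------------------------------------------------------------------
# filtering, controls and unwanted variation


def expression_filter(
    counts: pd.DataFrame, design: pd.DataFrame, min_cpm: float = 1.0
) -> pd.Index:
    """Genes with cpm > min_cpm in at least as many samples as the
    smallest temperature x exposure group."""
    validate_design(design, counts)
    groups = design.loc[counts.columns].groupby(
        ["temperature_C", "exposure"], observed=True
    ).size()
    min_group = int(groups.min())
    cpm = cpm_transform(counts)
    keep = (cpm > min_cpm).sum(axis=1) >= min_group
    return counts.index[keep]


def _group_codes(design: pd.DataFrame, samples, cols) -> np.ndarray:
    labels = design.loc[samples, list(cols)].astype(str).agg("|".join, axis=1)
    return pd.factorize(labels)[0]


def omnibus_nb_test(
    counts: pd.DataFrame,
    group_codes: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Omnibus NB likelihood-ratio test of any group difference, per gene.

    The full model is intercept + group dummies (+ covariates); the
    reduced model drops all group terms. Returns a DataFrame indexed by
    gene with columns statistic, p_value, and the full-model group
    coefficients (log scale, first group as reference).
    """
    arr = counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    n = arr.shape[1]
    levels = np.unique(group_codes)
    dummies = np.zeros((n, len(levels) - 1))
    for j, g in enumerate(levels[1:]):
        dummies[:, j] = group_codes == g
    parts = [np.ones((n, 1)), dummies]
    red_parts = [np.ones((n, 1))]
    if covariates is not None and covariates.size:
        parts.append(covariates)
        red_parts.append(covariates)
    X_full = np.column_stack(parts)
    X_red = np.column_stack(red_parts)
    if covariates is not None and covariates.size:
        alphas = nb_glm.estimate_dispersions_glm(arr, X_full, lib)
    else:
        alphas = nb_glm.estimate_dispersions(arr, group_codes, lib)
    stat, p, beta = nb_glm.lrt_omnibus(arr, X_full, X_red, alphas, lib)
    out = pd.DataFrame({"statistic": stat, "p_value": p}, index=counts.index)
    for j, g in enumerate(levels[1:]):
        out[f"log_fc_group{g}"] = beta[:, 1 + j]
    return out


def select_empirical_controls(
    counts: pd.DataFrame, design: pd.DataFrame, n_controls: int = 1000
) -> list[str]:
    """Empirical control genes: the least-varying genes from a first-pass
    all-groups analysis.

    An omnibus NB test over every temperature x exposure cell is run on
    the expression-filtered genes; genes are ranked by ascending omnibus
    statistic and the lowest ``n_controls`` returned. If fewer genes are
    available than requested, all are returned with a warning.
    """
    import warnings

    validate_counts(counts)
    keep = expression_filter(counts, design)
    sub = counts.loc[keep]
    codes = _group_codes(design, sub.columns, ("temperature_C", "exposure"))
    res = omnibus_nb_test(sub, codes)
    if n_controls > len(res):
        warnings.warn(
            f"requested {n_controls} controls but only {len(res)} genes "
            "pass the expression filter; returning all",
            stacklevel=2,
        )
        n_controls = len(res)
    order = res["statistic"].sort_values(kind="mergesort")
    return order.index[:n_controls].tolist()


@dataclass(frozen=True)
class UnwantedFactors:
    """Nuisance factors estimated from control genes; W is samples x k
    with unit-norm columns and enters DEG models as covariates."""

    W: np.ndarray
    k: int
    control_genes: tuple[str, ...]
    sample_ids: tuple[str, ...]


def estimate_unwanted_factors(
    counts: pd.DataFrame, controls: Sequence[str], k: int
) -> UnwantedFactors:
    """Estimate k unwanted-variation factors from empirical controls.

    W holds the first k left singular vectors of the samples x controls
    matrix of gene-centered log-cpm: directions of shared variation among
    genes assumed unaffected by the experimental conditions (the
    factor-analysis reading of control-gene batch removal).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    n = counts.shape[1]
    if k > n - 1:
        raise ValueError(f"k={k} exceeds samples - 1 = {n - 1}")
    if k == 0:
        return UnwantedFactors(
            np.zeros((n, 0)), 0, tuple(controls), tuple(counts.columns)
        )
    if not controls:
        raise ValueError("need control genes when k > 0")
    logcpm = cpm_transform(counts.loc[list(controls)], log=True)
    mat = logcpm.sub(logcpm.mean(axis=1), axis=0).to_numpy().T  # samples x genes
    U, _, _ = np.linalg.svd(mat, full_matrices=False)
    return UnwantedFactors(
        U[:, :k].copy(), k, tuple(controls), tuple(counts.columns)
    )


def detect_outlier_samples(
    counts: pd.DataFrame, design: pd.DataFrame, c: float = 2.5
) -> list[str]:
    """Flag samples far from their group centroid in PCA space.

    PCA is run on gene-centered log-cpm and each sample's deviation from
    its temperature x exposure group centroid in the first two
    components is computed. Each component is first whitened by a robust
    (MAD-based) estimate of the within-group spread along that axis, so
    that an aberrant sample that captures a whole component cannot
    deflate its own apparent distance by collapsing the others onto one
    axis. Whitened distances are strictly positive and right-skewed, so
    the flagging rule works on their logarithms: a sample is an outlier
    when its log distance exceeds the pooled median log distance by more
    than ``c`` normalized median absolute deviations (MAD x 1.4826).
    Because one aberrant sample also drags the PCA and its own group
    centroid, flagging is iterative (peeling): only the single most
    distant sample is flagged per round, removed, and everything
    recomputed, until no sample exceeds the cutoff. Deterministic
    replacement for flagging outliers by eye on MDS/PCA plots.
    """
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    validate_design(design, counts)
    flagged: list[str] = []
    remaining = list(counts.columns)
    while len(remaining) >= 3:
        sub = counts[remaining]
        logcpm = cpm_transform(sub, log=True)
        mat = logcpm.sub(logcpm.mean(axis=1), axis=0).to_numpy().T
        U, s, _ = np.linalg.svd(mat, full_matrices=False)
        scores = U[:, :2] * s[:2]
        codes = _group_codes(design, remaining, ("temperature_C", "exposure"))
        dev = np.full_like(scores, np.nan)
        for g in np.unique(codes):
            idx = codes == g
            if idx.sum() < 2:
                continue  # singleton group: deviation undefined
            dev[idx] = scores[idx] - scores[idx].mean(axis=0)
        ok = np.all(np.isfinite(dev), axis=1)
        if not ok.any() or np.all(dev[ok] == 0):
            break
        scale = 1.4826 * np.median(np.abs(dev[ok]), axis=0)
        fallback = dev[ok].std(axis=0)
        scale = np.where(scale > 0, scale, np.where(fallback > 0, fallback, 1.0))
        dist = np.where(ok, np.linalg.norm(dev / scale, axis=1), np.nan)
        pos = np.isfinite(dist) & (dist > 0)
        if not pos.any():
            break
        logd = np.log(dist[pos])
        med = float(np.median(logd))
        mad = float(np.median(np.abs(logd - med)))
        cutoff = med + c * 1.4826 * mad
        worst = int(np.nanargmax(np.where(pos, dist, -np.inf)))
        if mad > 0 and np.log(dist[worst]) > cutoff:
            flagged.append(remaining.pop(worst))
        else:
            break
    return sorted(flagged, key=list(counts.columns).index)


# ---------------------------------------------------------------------------
# DEG calling and pattern classification


def call_degs(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    W: UnwantedFactors | np.ndarray | None = None,
    exposure: str = "both",
    fdr_threshold: float = DEFAULT_DEG_FDR,
    exclude_15C: bool = False,
) -> pd.DataFrame:
    """Call temperature-responsive genes against the 5 degC control.

    Per gene, a negative-binomial log-linear model with a temperature
    factor (plus any unwanted-variation covariates) is compared with the
    intercept-only model by likelihood-ratio test — an omnibus test of
    any temperature effect, analogous to a one-way ANOVA. P-values are
    Benjamini-Hochberg adjusted; a gene is significant at
    fdr < ``fdr_threshold`` (default 0.01). Per-temperature log2 fold
    changes against 5 degC and a monotone direction label (up/down/flat
    with temperature) are reported for every tested gene.

    Parameters
    ----------
    exposure
        "ST", "LT" or "both": which exposure-time samples to analyze.
    exclude_15C
        Drop 15 degC samples before testing (used in the long-term
        analysis when that group is too heterogeneous).

    Returns a DataFrame indexed by gene with columns log2_fc_10C/15C/20C
    (NaN for excluded temperatures), statistic, p_value, fdr, direction,
    significant; genes failing the expression filter are excluded and
    listed in ``result.attrs['filtered_genes']``.
    """
    validate_counts(counts)
    validate_design(design, counts)
    samples = list(counts.columns)
    sub_design = design.loc[samples]
    if exposure in ("ST", "LT"):
        samples = [s for s in samples if sub_design.loc[s, "exposure"] == exposure]
    elif exposure != "both":
        raise ValueError(f"exposure must be ST, LT or both, got {exposure!r}")
    if exclude_15C:
        samples = [s for s in samples if design.loc[s, "temperature_C"] != 15]
    sub = counts[samples]
    temps = design.loc[samples, "temperature_C"].to_numpy()
    uniq_temps = np.unique(temps)
    if len(uniq_temps) < 2 or min(
        (temps == t).sum() for t in uniq_temps
    ) < 2:
        raise ValueError(
            "need >= 2 temperature groups with >= 2 replicates each"
        )
    keep = expression_filter(sub, design)
    filtered_out = [g for g in sub.index if g not in set(keep)]
    sub = sub.loc[keep]

    if isinstance(W, UnwantedFactors):
        w_full = pd.DataFrame(W.W, index=list(W.sample_ids))
        cov = w_full.loc[samples].to_numpy()
    elif W is None:
        cov = None
    else:
        cov = np.asarray(W, dtype=float)

    codes = pd.factorize(pd.Categorical(temps, categories=sorted(uniq_temps)))[0]
    res = omnibus_nb_test(sub, codes, covariates=cov)
    res["fdr"] = bh_adjust(res["p_value"].to_numpy())
    res["significant"] = res["fdr"] < fdr_threshold

    # per-temperature log2 fold change vs the 5 degC control
    sorted_temps = sorted(uniq_temps)
    rename = {}
    for j, t in enumerate(sorted_temps[1:]):
        rename[f"log_fc_group{j + 1}"] = f"log2_fc_{t}C"
        res[f"log_fc_group{j + 1}"] /= np.log(2.0)
    res = res.rename(columns=rename)
    for t in (10, 15, 20):
        if f"log2_fc_{t}C" not in res.columns:
            res[f"log2_fc_{t}C"] = np.nan

    mean_logcpm = group_mean_logcpm(sub, design.loc[samples])
    res["direction"] = [
        classify_temperature_pattern(mean_logcpm.loc[g]) for g in res.index
    ]
    res = res[
        ["log2_fc_10C", "log2_fc_15C", "log2_fc_20C", "statistic",
         "p_value", "fdr", "direction", "significant"]
    ]
    res.attrs["filtered_genes"] = filtered_out
    res.attrs["exposure"] = exposure
    return res


def group_mean_logcpm(counts: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Mean log2-cpm per temperature group (columns sorted by degC)."""
    logcpm = cpm_transform(counts, log=True)
    temps = design.loc[counts.columns, "temperature_C"]
    return logcpm.T.groupby(temps.to_numpy()).mean().T.sort_index(axis=1)


def classify_temperature_pattern(mean_by_temp: pd.Series) -> str:
    """Label a gene by the least-squares slope of its group-mean log
    expression against numeric temperature: "up", "down" or "flat"."""
    t = np.asarray(mean_by_temp.index, dtype=float)
    y = mean_by_temp.to_numpy(dtype=float)
    slope = np.polyfit(t, y, 1)[0] if len(t) >= 2 else 0.0
    if abs(slope) < 1e-12:
        return "flat"
    return "up" if slope > 0 else "down"


# ---------------------------------------------------------------------------
# enrichment


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; order-preserving with the
    input, monotone, and idempotent. P-values must lie in (0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_annotation(path) -> pd.DataFrame:
    """2-column TSV: gene_id, term_id (one pair per row)."""
    return pd.read_csv(path, sep="\t", names=["gene_id", "term_id"], header=None)


def hypergeometric_enrichment(
    deg_set: Iterable[str],
    universe: Iterable[str],
    annotation: pd.DataFrame,
    fdr_threshold: float = DEFAULT_ENRICH_FDR,
    min_oe: float = DEFAULT_MIN_OE,
) -> pd.DataFrame:
    """Term enrichment of a DEG set against the expressed-gene universe.

    For each term annotated to K of the N universe genes, with k of the n
    DEG-set genes carrying it, the upper-tail hypergeometric p-value
    P(overlap >= k) is computed; expected = nK/N and O/E = k/expected.
    P-values are BH-adjusted across the tested terms and a term is
    significant when fdr < ``fdr_threshold`` and O/E > ``min_oe``. Terms
    with no annotated universe gene are skipped.
    """
    universe = set(universe)
    deg_set = set(deg_set)
    if not deg_set <= universe:
        raise ValueError("DEG set must be a subset of the universe")
    ann = annotation[annotation["gene_id"].isin(universe)]
    N, n = len(universe), len(deg_set)
    rows = []
    for term, genes in ann.groupby("term_id")["gene_id"]:
        gset = set(genes)
        K = len(gset)
        if K == 0:
            continue
        k = len(gset & deg_set)
        expected = n * K / N
        rows.append(
            {
                "term_id": term,
                "universe_size": N,
                "annotated": K,
                "set_size": n,
                "observed": k,
                "expected": expected,
                "o_over_e": k / expected if expected > 0 else 0.0,
                "p_value": float(hypergeom.sf(k - 1, N, K, n)),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "universe_size", "annotated", "set_size",
                 "observed", "expected", "o_over_e", "p_value"],
    )
    if out.empty:
        out["fdr"] = []
        out["significant"] = []
        return out
    out["p_value"] = out["p_value"].clip(upper=1.0)
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = (out["fdr"] < fdr_threshold) & (out["o_over_e"] > min_oe)
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
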