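"""Expression-matrix analyses: marker summaries, gene ranking, gene-set
derivation, and gene set enrichment analysis (GSEA).

The scientific question here is which epithelial differentiation state
expands during colitis. Individual marker genes answer this for goblet
cells, enterocytes, enteroendocrine and stem cells, but transit-amplifying
cells (TACs) are defined functionally, so their enrichment is assessed with
a weighted Kolmogorov-Smirnov running-sum statistic over a ranked gene
list (signal-to-noise ranking between inflamed and noninflamed samples),
normalized and FDR-corrected against a permutation null.

The enrichment statistic: walking down the ranked list, hits increment the
running sum by |metric|^p / sum over hits of |metric|^p, misses decrement
by 1/(N - N_hits); the enrichment score (ES) is the signed maximum
deviation from zero and the leading edge is the subset of hit genes up to
that extremum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


@dataclass(frozen=True)
class DerivedSet(GeneSet):
    """A gene set derived from data; unlike curated sets it may be empty
    (e.g. when no transcript clears a strict specificity threshold)."""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    running_sum: np.ndarray
    leading_edge: tuple[str, ...]
    n_hits: int


def mean_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center every gene row at zero mean (idempotent)."""
    return matrix.sub(matrix.mean(axis=1), axis=0)


def log2fc_vs_control(values, control_mean: float, floor: float | None = None):
    """log2 fold change of values against a control mean, with a positivity floor.

    Values at or below zero are raised to ``floor`` (default: the smallest
    positive observed value) before taking the ratio; a boolean mask of
    floored entries is returned alongside the fold changes.
    """
    values = np.asarray(values, dtype=float)
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    if floor is None:
        positive = values[values > 0]
        if not len(positive):
            raise ValueError("no positive values to derive a floor from")
        floor = float(positive.min())
    if floor <= 0:
        raise ValueError("floor must be positive")
    flagged = values < floor
    return np.log2(np.maximum(values, floor) / control_mean), flagged


def rank_genes(matrix: pd.DataFrame, labels, pos_label: str | None = None) -> pd.DataFrame:
    """Signal-to-noise ranking of genes between two sample groups.

    metric = (mu_pos - mu_neg) / (sigma_pos + sigma_neg), with each group
    standard deviation floored at 0.2 x |group mean| (0.2 absolute when the
    mean is ~0) as in the canonical GSEA implementation. Sorted descending;
    ties break alphabetically by gene name. ``pos_label`` defaults to the
    first label encountered.
    """
    labels = pd.Series(np.asarray(labels), index=matrix.columns)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two label groups, got {uniq}")
    pos = pos_label if pos_label is not None else uniq[0]
    if pos not in uniq:
        raise ValueError(f"pos_label {pos!r} not among labels {uniq}")
    neg = uniq[1] if pos == uniq[0] else uniq[0]
    X1 = matrix.loc[:, (labels == pos).to_numpy()].to_numpy(float)
    X2 = matrix.loc[:, (labels == neg).to_numpy()].to_numpy(float)
    if X1.shape[1] < 2 or X2.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples for a dispersion-based metric")
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    s1 = _floored_sd(X1.std(axis=1, ddof=1), m1)
    s2 = _floored_sd(X2.std(axis=1, ddof=1), m2)
    metric = (m1 - m2) / (s1 + s2)
    out = pd.DataFrame({"gene": matrix.index, "metric": metric})
    out = out.sort_values(["metric", "gene"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def _floored_sd(sd: np.ndarray, mean: np.ndarray, frac: float = 0.2) -> np.ndarray:
    floor = frac * np.abs(mean)
    floor[np.abs(mean) < 1e-12] = frac
    return np.maximum(sd, floor)


def enrichment_score(ranked: pd.DataFrame, gene_set, p: float = 1.0):
    """Weighted KS enrichment score over a ranked gene list.

    ``ranked`` has columns gene/metric, descending. Returns
    ``(es, running_sum, leading_edge)``.
    """
    genes = ranked["gene"].to_numpy()
    metric = ranked["metric"].to_numpy(float)
    members = set(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    hit = np.isin(genes, list(members))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set shares no genes with the ranked list")
    running = _running_sum(metric, hit, p)
    es, extremum = _es_from_running(running)
    if es >= 0:
        leading = tuple(genes[: extremum + 1][hit[: extremum + 1]])
    else:
        leading = tuple(genes[extremum:][hit[extremum:]])
    return es, running, leading


def _running_sum(metric: np.ndarray, hit: np.ndarray, p: float) -> np.ndarray:
    n = len(metric)
    n_hits = int(hit.sum())
    weights = np.abs(metric) ** p
    # sequential (not pairwise) summation keeps the walk reproducible by a
    # plain cumulative-loop recomputation
    hit_total = float(sum(weights[hit].tolist()))
    if hit_total == 0:
        # all hit metrics are zero: fall back to unweighted hits
        increments = np.where(hit, 1.0 / n_hits, 0.0)
    else:
        increments = np.where(hit, weights / hit_total, 0.0)
    n_miss = n - n_hits
    if n_miss:
        increments = increments - np.where(~hit, 1.0 / n_miss, 0.0)
    return np.cumsum(increments)


def _es_from_running(running: np.ndarray) -> tuple[float, int]:
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def gsea(
    matrix: pd.DataFrame,
    labels,
    gene_sets: dict[str, list[str]] | list[GeneSet],
    n_perm: int = 1000,
    mode: str = "auto",
    seed: int | np.random.SeedSequence = 0,
    weight: float = 1.0,
    pos_label: str | None = None,
) -> list[EnrichmentResult]:
    """GSEA with permutation-based NES, nominal p and sign-stratified FDR.

    ``mode`` is ``phenotype`` (shuffle sample labels; requires enough
    distinct shuffles for ``n_perm``), ``gene`` (random same-size gene
    sets), or ``auto`` which prefers phenotype permutation and falls back
    to gene permutation with a logged warning when the design is too small.
    Deterministic for a fixed seed.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if mode not in ("auto", "phenotype", "gene"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    if isinstance(gene_sets, dict):
        sets = [GeneSet(name, tuple(genes)) for name, genes in gene_sets.items()]
    else:
        sets = [gs if isinstance(gs, GeneSet) else GeneSet(*gs) for gs in gene_sets]
    labels = pd.Series(np.asarray(labels), index=matrix.columns)
    present = set(matrix.index)
    kept_sets = []
    for gs in sets:
        kept = tuple(g for g in gs.genes if g in present)
        dropped = len(gs.genes) - len(kept)
        if dropped:
            logger.warning("gene set %s: dropped %d members absent from the matrix", gs.name, dropped)
        if not kept:
            raise ValueError(f"gene set {gs.name!r} shares no genes with the matrix")
        kept_sets.append(GeneSet(gs.name, kept))

    counts = labels.value_counts()
    n_distinct = comb(int(counts.sum()), int(counts.iloc[0]))
    if mode in ("auto", "phenotype") and n_distinct < n_perm:
        if mode == "phenotype":
            logger.warning(
                "only %d distinct label shuffles available for %d permutations; "
                "switching to gene-permutation mode", n_distinct, n_perm,
            )
        mode = "gene"
    elif mode == "auto":
        mode = "phenotype"

    rng = np.random.default_rng(seed)
    ranked = rank_genes(matrix, labels, pos_label=pos_label)
    observed = [enrichment_score(ranked, gs, p=weight) for gs in kept_sets]

    genes = ranked["gene"].to_numpy()
    metric = ranked["metric"].to_numpy(float)
    es_perm = np.zeros((len(kept_sets), n_perm))
    if mode == "gene":
        for j in range(n_perm):
            perm_positions = rng.permutation(len(genes))
            for i, gs in enumerate(kept_sets):
                hit = np.zeros(len(genes), dtype=bool)
                hit[perm_positions[: len(gs.genes)]] = True
                running = _running_sum(metric, hit, weight)
                es_perm[i, j], _ = _es_from_running(running)
    else:
        label_values = labels.to_numpy()
        hits = [np.isin(genes, list(gs.genes)) for gs in kept_sets]
        for j in range(n_perm):
            shuffled = rng.permutation(label_values)
            r = rank_genes(matrix, shuffled, pos_label=pos_label)
            perm_metric = r["metric"].to_numpy(float)
            order_genes = r["gene"].to_numpy()
            for i, gs in enumerate(kept_sets):
                hit = np.isin(order_genes, list(gs.genes))
                running = _running_sum(perm_metric, hit, weight)
                es_perm[i, j], _ = _es_from_running(running)

    results = []
    nes_obs = np.zeros(len(kept_sets))
    nes_perm = np.full_like(es_perm, np.nan)
    for i in range(len(kept_sets)):
        es_i = observed[i][0]
        pos_mean = np.mean(es_perm[i, es_perm[i] > 0]) if np.any(es_perm[i] > 0) else np.nan
        neg_mean = np.mean(np.abs(es_perm[i, es_perm[i] < 0])) if np.any(es_perm[i] < 0) else np.nan
        denom = pos_mean if es_i >= 0 else neg_mean
        nes_obs[i] = es_i / denom if np.isfinite(denom) and denom > 0 else np.sign(es_i)
        with np.errstate(invalid="ignore"):
            nes_perm[i] = np.where(
                es_perm[i] >= 0,
                es_perm[i] / pos_mean if np.isfinite(pos_mean) else np.nan,
                es_perm[i] / neg_mean if np.isfinite(neg_mean) else np.nan,
            )
    flat = nes_perm[np.isfinite(nes_perm)]
    for i, gs in enumerate(kept_sets):
        es_i, running, leading = observed[i]
        same_sign = es_perm[i, np.sign(es_perm[i]) == np.sign(es_i)] if es_i != 0 else es_perm[i]
        p_nom = (
            float(np.mean(np.abs(same_sign) >= abs(es_i))) if len(same_sign) else 0.0
        )
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                es=es_i,
                nes=float(nes_obs[i]),
                p_value=p_nom,
                fdr_q=_fdr_q(float(nes_obs[i]), nes_obs, flat),
                running_sum=running,
                leading_edge=leading,
                n_hits=len(gs.genes),
            )
        )
    return results


def _fdr_q(nes: float, nes_obs: np.ndarray, nes_perm_flat: np.ndarray) -> float:
    """Sign-stratified permutation FDR: (null tail fraction)/(observed tail fraction)."""
    if nes >= 0:
        null_pool = nes_perm_flat[nes_perm_flat >= 0]
        obs_pool = nes_obs[nes_obs >= 0]
        num = np.mean(null_pool >= nes) if len(null_pool) else 0.0
        den = np.mean(obs_pool >= nes) if len(obs_pool) else 1.0
    else:
        null_pool = nes_perm_flat[nes_perm_flat < 0]
        obs_pool = nes_obs[nes_obs < 0]
        num = np.mean(null_pool <= nes) if len(null_pool) else 0.0
        den = np.mean(obs_pool <= nes) if len(obs_pool) else 1.0
    if den == 0:
        return 0.0
    return float(min(1.0, num / den))


def derive_specific_set(
    matrix: pd.DataFrame,
    cell_type_labels,
    target: str,
    fold: float = 2.0,
    alpha: float = 0.05,
    name: str | None = None,
) -> GeneSet:
    """Derive a cell-type-specific gene set from replicate expression data.

    A gene is included iff, against *every* other cell type, it shows (a)
    mean fold change >= ``fold`` and (b) a Benjamini-Hochberg-adjusted
    two-sided Welch t-test q < ``alpha`` (BH applied across all genes,
    separately per pairwise comparison).
    """
    if fold <= 0:
        raise ValueError("fold threshold must be positive")
    labels = pd.Series(np.asarray(cell_type_labels), index=matrix.columns)
    types = list(dict.fromkeys(labels))
    if target not in types:
        raise ValueError(f"target {target!r} not among cell types {types}")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per cell type")
    X_t = matrix.loc[:, (labels == target).to_numpy()].to_numpy(float)
    mean_t = X_t.mean(axis=1)
    keep = np.ones(len(matrix), dtype=bool)
    tiny = 1e-12
    for other in types:
        if other == target:
            continue
        X_o = matrix.loc[:, (labels == other).to_numpy()].to_numpy(float)
        mean_o = X_o.mean(axis=1)
        fc = mean_t / np.maximum(mean_o, tiny)
        _, pvals = stats.ttest_ind(X_t, X_o, axis=1, equal_var=False)
        q = bh_fdr(np.nan_to_num(pvals, nan=1.0))
        keep &= (fc >= fold) & (q < alpha)
    return DerivedSet(name or f"{target}_specific", tuple(matrix.index[keep]))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# --------------------------------------------------------------------------
# GMT gene-set files
# --------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: GMT lines need name, description, >=1 gene")
            name, _desc, *genes = fields
            sets[name] = [g.strip() for g in genes if g.strip()]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_value": [r.p_value for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "n_hits": [r.n_hits for r in results],
            "leading_edge_size": [len(r.leading_edge) for r in results],
        }
    )
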