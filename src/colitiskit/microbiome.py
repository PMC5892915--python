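"""Microbiome composition, Bray-Curtis dissimilarity and PCoA ordination.

Fecal 16S profiling yields per-sample taxon count tables (upstream read
processing and taxonomy assignment are out of scope; this module consumes
counts). Compositions are compared with Bray-Curtis dissimilarity
BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i), computed on relative abundances
to remove sequencing-depth artefacts, and ordinated by classical scaling
(principal coordinates analysis). The paired design — each animal sampled
before and after treatment — is summarized by comparing within-animal
pre/post dissimilarities to between-animal dissimilarities within and
across inflammation groups: a drug that does not move the microbiome
leaves within-animal pairs as similar as same-group pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

_LEVELS = {"kingdom": 0, "phylum": 1, "class": 2, "order": 3, "family": 4, "genus": 5,
           "species": 6}


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample row by its total count."""
    totals = counts.sum(axis=1)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValueError(f"samples with zero total counts: {list(empty.index)}")
    if (counts.to_numpy(float) < 0).any():
        raise ValueError("counts must be non-negative")
    return counts.div(totals, axis=0)


def aggregate_taxa(table: pd.DataFrame, level: str | int, sep: str = ";") -> pd.DataFrame:
    """Sum abundances sharing a taxonomy prefix at the given rank.

    Column names are hierarchical taxonomy strings ("k__...;p__...;g__...");
    ``level`` is a rank name (e.g. "phylum") or a 0-based prefix depth.
    Total abundance per sample is conserved.
    """
    depth = _LEVELS[level] if isinstance(level, str) else int(level)
    prefixes = [sep.join(str(c).split(sep)[: depth + 1]) for c in table.columns]
    return table.T.groupby(pd.Index(prefixes, name=table.columns.name)).sum().T


@dataclass
class DissimilarityMatrix:
    """Symmetric zero-diagonal Bray-Curtis matrix with sample order."""

    values: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or len(self.sample_ids) != v.shape[0]:
            raise ValueError("matrix must be square with one id per row")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("matrix must be symmetric with a zero diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("Bray-Curtis values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.sample_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)


def bray_curtis(table: pd.DataFrame) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarities between composition rows."""
    X = table.to_numpy(float)
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    if (X.sum(axis=1) <= 0).any():
        raise ValueError("every sample needs positive total abundance")
    D = squareform(pdist(X, metric="braycurtis"))
    return DissimilarityMatrix(D, tuple(str(i) for i in table.index))


@dataclass
class OrdinationResult:
    """Classical-scaling embedding of a dissimilarity matrix."""

    eigenvalues: np.ndarray              # all, descending (negatives included)
    coordinates: pd.DataFrame            # samples x retained positive axes
    proportion_explained: np.ndarray     # per retained axis, of positive total


def pcoa(D: DissimilarityMatrix | np.ndarray, n_axes: int | None = None,
         sample_ids=None) -> OrdinationResult:
    """Principal coordinates analysis (Torgerson classical scaling).

    Double-centers -0.5 D^2, eigendecomposes, and returns coordinates
    eigenvector * sqrt(eigenvalue) on the positive axes. Negative
    eigenvalues (non-Euclidean residue of the dissimilarity) are reported
    but their axes are dropped, with no correction applied. Axis signs are
    fixed so the largest-|coordinate| sample scores positive.
    """
    if isinstance(D, DissimilarityMatrix):
        ids = list(D.sample_ids)
        M = D.values
    else:
        M = np.asarray(D, dtype=float)
        ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(M))]
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    n = M.shape[0]
    A = -0.5 * M**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-9 * max(abs(eigvals[0]), 1.0)
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    for a in range(coords.shape[1]):
        j = int(np.argmax(np.abs(coords[:, a])))
        if coords[j, a] < 0:
            coords[:, a] *= -1.0
    if n_axes is not None:
        coords = coords[:, :n_axes]
    pos_total = eigvals[positive].sum()
    prop = eigvals[positive][: coords.shape[1]] / pos_total if pos_total > 0 else np.array([])
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"PCo{a + 1}" for a in range(coords.shape[1])]
    )
    return OrdinationResult(eigenvalues=eigvals, coordinates=frame, proportion_explained=prop)


def paired_vs_between(D: DissimilarityMatrix, metadata: pd.DataFrame) -> dict:
    """Compare within-animal pre/post dissimilarity to between-animal spread.

    ``metadata`` is indexed by sample id with columns ``animal_id``,
    ``group`` (e.g. control/inflamed) and ``phase`` ("pre"/"post"). Animals
    missing either phase are excluded with a logged warning. Returns a dict
    with a tidy ``summary`` table (n, mean, median per distribution) and
    two-sided Mann-Whitney rank-sum p-values comparing within-animal vs
    same-group and same-group vs cross-group distributions.
    """
    required = {"animal_id", "group", "phase"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    Dm = D.to_frame()
    meta = metadata.loc[[s for s in D.sample_ids if s in metadata.index]]
    within = []
    for animal, sub in meta.groupby("animal_id"):
        phases = dict(zip(sub["phase"], sub.index))
        if "pre" not in phases or "post" not in phases:
            logger.warning("animal %s lacks a pre or post sample; excluded from paired analysis",
                           animal)
            continue
        within.append(Dm.loc[phases["pre"], phases["post"]])
    same_group, cross_group = [], []
    samples = list(meta.index)
    for i, si in enumerate(samples):
        for sj in samples[i + 1:]:
            if meta.loc[si, "animal_id"] == meta.loc[sj, "animal_id"]:
                continue
            (same_group if meta.loc[si, "group"] == meta.loc[sj, "group"] else cross_group
             ).append(Dm.loc[si, sj])
    dists = {
        "within_animal": np.asarray(within, float),
        "between_same_group": np.asarray(same_group, float),
        "between_cross_group": np.asarray(cross_group, float),
    }
    summary = pd.DataFrame(
        {
            "distribution": list(dists),
            "n": [len(v) for v in dists.values()],
            "mean": [v.mean() if len(v) else np.nan for v in dists.values()],
            "median": [float(np.median(v)) if len(v) else np.nan for v in dists.values()],
        }
    )
    out = {"summary": summary, "distributions": dists}
    for key, (a, b) in {
        "p_within_vs_same": ("within_animal", "between_same_group"),
        "p_same_vs_cross": ("between_same_group", "between_cross_group"),
    }.items():
        va, vb = dists[a], dists[b]
        if len(va) and len(vb) and (np.ptp(np.concatenate([va, vb])) > 0):
            out[key] = float(mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        else:
            out[key] = np.nan
    return out
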