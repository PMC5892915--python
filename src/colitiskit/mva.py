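"""Latent-variable modelling of multiplexed signaling panels.

The molecular readout of each animal is a 54-analyte vector mixing cytokine
concentrations (pg/ml, spanning orders of magnitude) and phosphoprotein
fluorescence (RFU). Two latent-space models are supported:

* **PCA** — unsupervised; in this disease model a single dominant component
  captures the shared inflammation axis, separating control, focal and
  continuous animals.
* **PLSR** — the same panel regressed onto a scalar phenotype (mean distal
  crypt height) via NIPALS; latent variable 1 (LV1) is the inflammation-
  predictive direction.

Fitted models are frozen objects carrying their own preprocessing
statistics, so perturbed cohorts (drug-treated animals, organoid panels)
can be projected onto the training latent space without refitting. Class
regions (Gaussian ellipses over training scores) turn the projection into
a classifier via minimal Mahalanobis distance.

Default preprocessing is log1p + autoscaling for concentration-scale
analytes and autoscaling alone for fluorescence channels; autoscaling makes
loadings comparable across analytes with wildly different dynamic ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: severity ordering used for assignment tie-breaks (less inflamed wins)
_SEVERITY = {"control": 0, "focal": 1, "continuous": 2}

TRANSFORMS = ("log1p", "identity")


@dataclass(frozen=True)
class Preprocessor:
    """Per-analyte transform + training-panel centering/scaling."""

    analytes: tuple[str, ...]
    transforms: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray

    def apply(self, panel: pd.DataFrame) -> np.ndarray:
        _check_analytes(panel, self.analytes)
        X = panel[list(self.analytes)].to_numpy(float).copy()
        for j, t in enumerate(self.transforms):
            if t == "log1p":
                X[:, j] = np.log1p(X[:, j])
        return (X - self.center) / self.scale


def _check_analytes(panel: pd.DataFrame, analytes: tuple[str, ...]) -> None:
    have, want = set(panel.columns), set(analytes)
    if have != want:
        diff = sorted(have.symmetric_difference(want))
        raise ValueError(f"panel analytes do not match the model; symmetric difference: {diff}")


def transforms_from_units(units) -> tuple[str, ...]:
    """log1p for concentration (pg/ml) channels, identity for RFU."""
    return tuple("log1p" if u == "pg/ml" else "identity" for u in units)


def fit_preprocessor(panel: pd.DataFrame, transform_policy="identity") -> Preprocessor:
    """Fit per-analyte transform/center/scale on a training panel.

    ``transform_policy`` may be a single transform name applied to every
    analyte, a mapping analyte -> transform, or a sequence aligned with the
    panel's columns. Constant analytes are rejected by name.
    """
    if len(panel) < 3:
        raise ValueError("need at least 3 training samples")
    if panel.isna().any().any():
        raise ValueError("panel contains missing values")
    analytes = tuple(panel.columns)
    if isinstance(transform_policy, str):
        transforms = tuple(transform_policy for _ in analytes)
    elif isinstance(transform_policy, dict):
        transforms = tuple(transform_policy.get(a, "identity") for a in analytes)
    else:
        transforms = tuple(transform_policy)
        if len(transforms) != len(analytes):
            raise ValueError("transform sequence length must match analyte count")
    bad = [t for t in transforms if t not in TRANSFORMS]
    if bad:
        raise ValueError(f"unknown transforms: {sorted(set(bad))}")
    X = panel.to_numpy(float).copy()
    for j, t in enumerate(transforms):
        if t == "log1p":
            if np.any(X[:, j] < 0):
                raise ValueError(f"analyte {analytes[j]!r}: log1p requires non-negative values")
            X[:, j] = np.log1p(X[:, j])
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    constant = [analytes[j] for j in np.nonzero(scale < 1e-12)[0]]
    if constant:
        raise ValueError(f"constant analytes cannot be autoscaled: {constant}")
    return Preprocessor(analytes, transforms, center, scale)


@dataclass
class LatentModel:
    """A frozen PCA or PLSR decomposition supporting projection."""

    kind: str  # "pca" | "plsr"
    preprocessor: Preprocessor
    n_components: int
    loadings: np.ndarray          # analytes x k
    scores: np.ndarray            # training samples x k
    explained_variance: np.ndarray            # X-variance fraction per component
    sample_ids: tuple[str, ...] = ()
    weights: np.ndarray | None = None          # analytes x k (PLSR)
    y_loadings: np.ndarray | None = None       # k (PLSR)
    y_explained_variance: np.ndarray | None = None
    y_center: float | None = None
    y_scale: float | None = None
    total_variance: float = 0.0

    @property
    def analytes(self) -> tuple[str, ...]:
        return self.preprocessor.analytes


def _fix_signs(loadings: np.ndarray, *companions: np.ndarray) -> None:
    """Per component, make the largest-|loading| analyte positive (in place)."""
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1.0
            for c in companions:
                if c is not None:
                    if c.ndim == 1:
                        c[a] *= -1.0
                    else:
                        c[:, a] *= -1.0


def fit_pca(panel: pd.DataFrame, preprocessor: Preprocessor, k: int) -> LatentModel:
    """PCA by SVD of the preprocessed panel; scores = Z @ loadings."""
    Z = preprocessor.apply(panel)
    n, p = Z.shape
    k_max = min(n - 1, p)
    if not 1 <= k <= k_max:
        raise ValueError(f"k must lie in [1, {k_max}]")
    # training preprocessing already centers columns; SVD of Z gives the PCs
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[:k].T.copy()
    var = s**2 / (n - 1)
    total = float(var.sum())
    _fix_signs(loadings)
    scores = Z @ loadings
    return LatentModel(
        kind="pca",
        preprocessor=preprocessor,
        n_components=k,
        loadings=loadings,
        scores=scores,
        explained_variance=var[:k] / total,
        total_variance=total,
        sample_ids=tuple(str(i) for i in panel.index),
    )


def fit_plsr(
    panel: pd.DataFrame,
    y,
    preprocessor: Preprocessor,
    k: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> LatentModel:
    """PLS regression of a scalar phenotype on the panel, via NIPALS.

    X and y are deflated after each component; the response is centered and
    scaled by its training statistics. With a univariate response the inner
    NIPALS loop converges in one pass, but the generic iteration (weight
    change < ``tol``, at most ``max_iter`` sweeps) is retained.
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = preprocessor.apply(panel)
    n, p = Z.shape
    if len(y) != n:
        raise ValueError("y must have one value per panel sample")
    if k < 1 or k > min(n - 1, p):
        raise ValueError(f"k must lie in [1, {min(n - 1, p)}]")
    y_center, y_scale = float(y.mean()), float(y.std(ddof=1))
    if y_scale < 1e-12:
        raise ValueError("response is constant")
    u = (y - y_center) / y_scale
    X = Z.copy()
    ss_x_total = float((Z**2).sum())
    ss_y_total = float((u**2).sum())
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    T = np.zeros((n, k))
    q = np.zeros(k)
    xvar = np.zeros(k)
    yvar = np.zeros(k)
    y_res = u.copy()
    for a in range(k):
        w = X.T @ y_res
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            raise ValueError(f"residual X'y vanished at component {a + 1}")
        w /= norm
        for it in range(max_iter):
            t = X @ w
            c = float(y_res @ t) / float(t @ t)
            u_score = y_res * c  # univariate y: u is proportional to y residual
            w_new = X.T @ u_score
            w_new /= np.linalg.norm(w_new)
            delta = np.linalg.norm(w_new - w)
            w = w_new
            if delta < tol:
                break
        else:
            raise RuntimeError(f"NIPALS did not converge within {max_iter} iterations")
        t = X @ w
        tt = float(t @ t)
        p_vec = (X.T @ t) / tt
        q_a = float(y_res @ t) / tt
        X = X - np.outer(t, p_vec)
        y_res = y_res - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_vec, t, q_a
        xvar[a] = tt * float(p_vec @ p_vec) / ss_x_total
        yvar[a] = (q_a**2) * tt / ss_y_total
    _fix_signs(P, W, T, q)
    return LatentModel(
        kind="plsr",
        preprocessor=preprocessor,
        n_components=k,
        loadings=P,
        scores=T,
        explained_variance=xvar,
        weights=W,
        y_loadings=q,
        y_explained_variance=yvar,
        y_center=y_center,
        y_scale=y_scale,
        total_variance=ss_x_total / max(n - 1, 1),
        sample_ids=tuple(str(i) for i in panel.index),
    )


def rotation_matrix(model: LatentModel) -> np.ndarray:
    """Map from preprocessed space to latent scores (x-rotation)."""
    if model.kind == "pca":
        return model.loadings
    return model.weights @ np.linalg.inv(model.loadings.T @ model.weights)


def project(model: LatentModel, new_panel: pd.DataFrame) -> pd.DataFrame:
    """Project new samples onto a frozen latent space.

    Applies the *training* preprocessor, then the model's rotation:
    ``t = Z P`` for PCA, ``t = Z W (P'W)^-1`` for PLSR. Projecting the
    training panel reproduces the stored training scores.
    """
    Z = model.preprocessor.apply(new_panel)
    scores = Z @ rotation_matrix(model)
    cols = [f"LV{a + 1}" if model.kind == "plsr" else f"PC{a + 1}" for a in range(model.n_components)]
    return pd.DataFrame(scores, index=new_panel.index, columns=cols)


def predict_phenotype(model: LatentModel, new_panel: pd.DataFrame) -> np.ndarray:
    """PLSR response prediction on the original phenotype scale."""
    if model.kind != "plsr":
        raise ValueError("phenotype prediction requires a PLSR model")
    t = project(model, new_panel).to_numpy()
    return (t @ model.y_loadings) * model.y_scale + model.y_center


@dataclass
class ClassRegion:
    """Gaussian coverage ellipse of one class in the first two latent dims.

    ``covariance`` is the class's own score covariance (used to draw the
    ellipse); ``pooled_covariance`` is the within-class pooled covariance
    shared by all regions from the same fit and used for assignment, so a
    class that happens to sprawl does not swallow distant samples.
    """

    label: str
    centroid: np.ndarray      # length 2
    covariance: np.ndarray    # 2 x 2
    pooled_covariance: np.ndarray
    n: int
    level: float = 0.95

    @property
    def mahalanobis_radius(self) -> float:
        """Ellipse radius (in Mahalanobis units) enclosing ``level`` mass."""
        return float(np.sqrt(stats.chi2.ppf(self.level, df=2)))


def _regularize(cov: np.ndarray) -> np.ndarray:
    cov = np.atleast_2d(cov)
    if np.linalg.det(cov) < 1e-12:
        cov = cov + 1e-8 * np.eye(cov.shape[0])
    return cov


def fit_class_regions(scores, labels, level: float = 0.95) -> list[ClassRegion]:
    """One Gaussian ellipse per class over the first two score columns.

    Classes with fewer than two samples fall back to the pooled covariance;
    near-singular covariances are ridge-regularized.
    """
    S = np.asarray(scores, dtype=float)[:, :2]
    labels = np.asarray(labels)
    if len(labels) != len(S):
        raise ValueError("one label per score row required")
    uniq = list(dict.fromkeys(labels))  # preserve first-appearance order
    # pooled within-class covariance (classes centered on their own means)
    centered = np.vstack([S[labels == lab] - S[labels == lab].mean(axis=0) for lab in uniq])
    dof = len(S) - len(uniq)
    pooled = _regularize(
        centered.T @ centered / dof if dof > 0 else np.eye(2)
    )
    regions = []
    for label in uniq:
        pts = S[labels == label]
        cov = _regularize(np.cov(pts, rowvar=False)) if len(pts) >= 2 else pooled.copy()
        regions.append(ClassRegion(str(label), pts.mean(axis=0), cov, pooled, len(pts), level))
    return regions


def assign_class(score, regions: list[ClassRegion], metric: str = "pooled") -> str:
    """Minimal-Mahalanobis-distance class for one latent score.

    ``metric="pooled"`` (default) measures every distance in the shared
    within-class covariance; ``metric="class"`` uses each region's own
    covariance. Ties break toward the less-inflamed class (control < focal
    < continuous; unknown labels rank after those, alphabetically), and the
    result does not depend on the order of ``regions``.
    """
    if metric not in ("pooled", "class"):
        raise ValueError(f"unknown metric {metric!r}")
    x = np.asarray(score, dtype=float).ravel()[:2]
    best = None
    for r in regions:
        d = x - r.centroid
        cov = r.pooled_covariance if metric == "pooled" else r.covariance
        d2 = float(d @ np.linalg.solve(cov, d))
        rank = (_SEVERITY.get(r.label, len(_SEVERITY)), r.label)
        key = (round(d2, 10), rank)
        if best is None or key < best[0]:
            best = (key, r.label)
    if best is None:
        raise ValueError("no class regions given")
    return best[1]


def top_loadings(model: LatentModel, n: int = 20, component: int = 1) -> pd.DataFrame:
    """Analytes ranked by |loading| on one component (ties: alphabetical)."""
    if not 1 <= component <= model.n_components:
        raise ValueError(f"component must lie in [1, {model.n_components}]")
    load = model.loadings[:, component - 1]
    df = pd.DataFrame({"analyte": list(model.analytes), "loading": load})
    df["_abs"] = df["loading"].abs()
    df = df.sort_values(["_abs", "analyte"], ascending=[False, True]).drop(columns="_abs")
    return df.head(n).reset_index(drop=True)


def score_phenotype_fit(scores_component, phenotype) -> float:
    """R^2 of ordinary least squares of a phenotype on one score column."""
    t = np.asarray(scores_component, dtype=float).ravel()
    y = np.asarray(phenotype, dtype=float).ravel()
    if len(t) != len(y) or len(t) < 3:
        raise ValueError("need >= 3 paired observations")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("phenotype is constant")
    return 1.0 - float((resid**2).sum()) / ss_tot


# --------------------------------------------------------------------------
# serialization (structured text, bit-stable projection)
# --------------------------------------------------------------------------

def model_to_json(model: LatentModel) -> str:
    def arr(a):
        return None if a is None else np.asarray(a).tolist()

    payload = {
        "kind": model.kind,
        "n_components": model.n_components,
        "analytes": list(model.analytes),
        "transforms": list(model.preprocessor.transforms),
        "center": arr(model.preprocessor.center),
        "scale": arr(model.preprocessor.scale),
        "loadings": arr(model.loadings),
        "scores": arr(model.scores),
        "explained_variance": arr(model.explained_variance),
        "weights": arr(model.weights),
        "y_loadings": arr(model.y_loadings),
        "y_explained_variance": arr(model.y_explained_variance),
        "y_center": model.y_center,
        "y_scale": model.y_scale,
        "total_variance": model.total_variance,
        "sample_ids": list(model.sample_ids),
    }
    return json.dumps(payload, indent=1)


def model_from_json(text: str) -> LatentModel:
    d = json.loads(text)

    def arr(x):
        return None if x is None else np.asarray(x, dtype=float)

    pre = Preprocessor(
        analytes=tuple(d["analytes"]),
        transforms=tuple(d["transforms"]),
        center=arr(d["center"]),
        scale=arr(d["scale"]),
    )
    return LatentModel(
        kind=d["kind"],
        preprocessor=pre,
        n_components=int(d["n_components"]),
        loadings=arr(d["loadings"]),
        scores=arr(d["scores"]),
        explained_variance=arr(d["explained_variance"]),
        weights=arr(d["weights"]),
        y_loadings=arr(d["y_loadings"]),
        y_explained_variance=arr(d["y_explained_variance"]),
        y_center=d["y_center"],
        y_scale=d["y_scale"],
        total_variance=d["total_variance"],
        sample_ids=tuple(d["sample_ids"]),
    )
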