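"""SIMPLS partial least squares regression with a discriminant-analysis wrapper.

PLS finds score directions in the predictor space that maximise covariance
with the response matrix.  SIMPLS extracts them by working directly on the
cross-product matrix ``S = Xcᵀ Yc`` of the column-centred data: each
component takes its x-weight from the dominant singular direction of the
current ``S``, forms the score ``t = Xc w``, accumulates x- and y-loadings,
and deflates ``S`` against the orthonormalised basis of x-loadings so that
successive scores are mutually orthogonal.  Unlike NIPALS, the weights apply
to the *original* centred data, so the regression coefficients are simply
``B = W Qᵀ`` and prediction is ``ŷ = (x − x̄)·B + ȳ``.  For a single-response
``Y`` the two algorithms coincide.

For classification (PLS-DA) the class labels are dummy-coded into a 0/1
indicator matrix, the regression is fitted to it, and a new sample is
assigned to the class with the largest continuous predicted response.

The VIP (variable importance in projection) score summarises how much each
wavelength contributes across components, weighting each component's squared
normalised weight by the share of Y-variance that component explains:

    VIPⱼ = sqrt( p · Σₐ SSYₐ (wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ )

where ``SSYₐ = ‖qₐ‖² tₐᵀtₐ`` is the Y-variance captured by component ``a``
summed over all response (dummy) columns.  The mean of the squared scores is
1 by construction, so wavelengths with VIP above 1 are more important than
average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectra import SpectraSet, WavelengthGrid

__all__ = [
    "ClassEncoding",
    "PLSModel",
    "VIPProfile",
    "encode_classes",
    "fit_simpls",
    "fit_plsda",
    "fit_one_vs_all",
    "predict_scores",
    "predict_class",
    "vip_scores",
    "save_model",
    "load_model",
    "one_vs_all_labels",
]


@dataclass(frozen=True)
class ClassEncoding:
    """Ordered class labels and the dummy-coding rule (one 1 per row)."""

    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class labels")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "ClassEncoding":
        """Encoding over the sorted distinct labels (deterministic order)."""
        return cls(tuple(sorted(set(labels))))


def encode_classes(labels: Sequence[str], encoding: ClassEncoding) -> np.ndarray:
    """Dummy-code ``labels`` into an ``n × c`` 0/1 indicator matrix."""
    index = {c: j for j, c in enumerate(encoding.classes)}
    Y = np.zeros((len(labels), encoding.n_classes))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(f"label {lab!r} not in encoding classes {encoding.classes}")
        Y[i, index[lab]] = 1.0
    return Y


@dataclass
class PLSModel:
    """Fitted SIMPLS state.

    ``weights`` (p×A) apply to centred X directly; ``x_loadings`` (p×A) and
    ``y_loadings`` (c×A) reconstruct X and Y from scores; ``score_norms[a]``
    is the inner product tₐᵀtₐ of the a-th (unnormalised) training score,
    retained so explained-variance bookkeeping for VIP is explicit.
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    score_norms: np.ndarray
    coefficients: np.ndarray
    n_components: int
    encoding: ClassEncoding | None = None
    grid: WavelengthGrid | None = None

    @property
    def n_features(self) -> int:
        return self.x_mean.size

    def coefficients_at(self, a: int) -> np.ndarray:
        """Regression coefficients of the model truncated to ``a`` components."""
        if not 1 <= a <= self.n_components:
            raise ValueError(f"components must be in 1..{self.n_components}, got {a}")
        return self.weights[:, :a] @ self.y_loadings[:, :a].T


def fit_simpls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    grid: WavelengthGrid | None = None,
    encoding: ClassEncoding | None = None,
) -> PLSModel:
    """Fit a SIMPLS regression of ``Y`` (n×c) on ``X`` (n×p).

    Both blocks are column-centred before decomposition.  ``n_components``
    must satisfy ``1 ≤ A ≤ min(n−1, p)``; extraction stops with an error if
    the cross-product matrix deflates to zero earlier (rank exhausted).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"X has {n} rows but Y has {Y.shape[0]}")
    c = Y.shape[1]
    A = int(n_components)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"n_components must be in 1..min(n-1, p)={min(n - 1, p)}, got {A}")
    if grid is not None and len(grid) != p:
        raise ValueError(f"grid has {len(grid)} points but X has {p} columns")
    if encoding is not None and encoding.n_classes != c:
        raise ValueError(f"encoding has {encoding.n_classes} classes but Y has {c} columns")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean

    S = Xc.T @ Yc  # p×c cross-product; all decompositions act on this small matrix
    scale = np.linalg.norm(S)
    if scale == 0.0:
        raise ValueError("degenerate data: X and Y are uncorrelated after centering")

    W = np.empty((p, A))
    P = np.empty((p, A))
    Q = np.empty((c, A))
    tt = np.empty(A)
    V = np.empty((p, A))  # orthonormal basis spanning extracted x-loadings

    for a in range(A):
        if np.linalg.norm(S) <= 1e-12 * scale:
            raise ValueError(
                f"rank exhausted after {a} components; requested {A}"
            )
        # dominant left singular vector of the deflated p×c cross-product
        U, _, _ = np.linalg.svd(S, full_matrices=False)
        w = U[:, 0]
        t = Xc @ w
        norm2 = float(t @ t)
        if norm2 <= 1e-24:
            raise ValueError(f"zero-variance score at component {a + 1}")
        P[:, a] = Xc.T @ t / norm2
        Q[:, a] = Yc.T @ t / norm2
        W[:, a] = w
        tt[a] = norm2

        v = P[:, a].copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ v)
        v /= np.linalg.norm(v)
        V[:, a] = v
        S = S - np.outer(v, v @ S)

    B = W @ Q.T
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        score_norms=tt,
        coefficients=B,
        n_components=A,
        encoding=encoding,
        grid=grid,
    )


def fit_plsda(
    s: SpectraSet,
    labels: Sequence[str],
    n_components: int,
    encoding: ClassEncoding | None = None,
) -> PLSModel:
    """Fit PLS-DA on a spectra set with one label per row."""
    if len(labels) != s.n_rows:
        raise ValueError(f"{s.n_rows} rows but {len(labels)} labels")
    if encoding is None:
        encoding = ClassEncoding.from_labels(labels)
    Y = encode_classes(list(labels), encoding)
    grid = getattr(s, "grid", None)
    grid = grid if isinstance(grid, WavelengthGrid) else None
    return fit_simpls(s.matrix, Y, n_components, grid=grid, encoding=encoding)


def one_vs_all_labels(labels: Sequence[str], target: str) -> list[str]:
    """Collapse labels to a binary target / 'not target' task."""
    return [lab if lab == target else f"not {target}" for lab in labels]


def fit_one_vs_all(s: SpectraSet, target: str, n_components: int) -> PLSModel:
    """Fit a binary model predicting whether each sample is ``target`` or not."""
    labels = [m.type_label for m in s.metas]
    if target not in labels:
        raise ValueError(f"target class {target!r} not present in the data")
    binary = one_vs_all_labels(labels, target)
    encoding = ClassEncoding((target, f"not {target}"))
    return fit_plsda(s, binary, n_components, encoding=encoding)


def predict_scores(m: PLSModel, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Continuous per-class responses ``(X − x̄)·B + ȳ``.

    ``n_components`` truncates the fitted model to its first components,
    which is how accuracy-versus-components curves are evaluated from a
    single fit.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != m.n_features:
        raise ValueError(f"model expects {m.n_features} features, got {X.shape[1]}")
    B = m.coefficients if n_components is None else m.coefficients_at(n_components)
    return (X - m.x_mean) @ B + m.y_mean


def predict_class(
    m: PLSModel,
    X: np.ndarray,
    n_components: int | None = None,
    rule: str = "argmax",
) -> list[str]:
    """Assign each row to a class from the continuous responses.

    ``rule='argmax'`` picks the class with the largest response, ties broken
    toward the earlier class in encoding order.  ``rule='threshold'`` is the
    binary alternative: the first class iff its response exceeds 0.5.
    """
    if m.encoding is None:
        raise ValueError("model was fitted without a class encoding")
    scores = predict_scores(m, X, n_components)
    classes = m.encoding.classes
    if rule == "argmax":
        idx = np.argmax(scores, axis=1)  # np.argmax returns first maximum: earlier class wins ties
        return [classes[i] for i in idx]
    if rule == "threshold":
        if len(classes) != 2:
            raise ValueError("threshold rule requires a binary encoding")
        return [classes[0] if s0 > 0.5 else classes[1] for s0 in scores[:, 0]]
    raise ValueError(f"unknown assignment rule {rule!r}")


@dataclass(frozen=True)
class VIPProfile:
    """Per-wavelength variable-importance scores; Σⱼ VIPⱼ² = p."""

    scores: np.ndarray
    grid: WavelengthGrid | None = None

    def top_wavelength(self) -> float:
        """Wavelength (nm) of the most important variable."""
        if self.grid is None:
            raise ValueError("profile has no wavelength grid")
        return float(self.grid.wavelengths[int(np.argmax(self.scores))])


def vip_scores(m: PLSModel, n_components: int | None = None) -> VIPProfile:
    """VIP profile of a fitted model (optionally truncated to fewer components)."""
    A = m.n_components if n_components is None else int(n_components)
    if not 1 <= A <= m.n_components:
        raise ValueError(f"components must be in 1..{m.n_components}, got {A}")
    W = m.weights[:, :A]
    Q = m.y_loadings[:, :A]
    tt = m.score_norms[:A]
    p = W.shape[0]
    # Y-variance explained by each component, summed over response columns
    ssy = np.sum(Q**2, axis=0) * tt
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains zero Y-variance; VIP undefined")
    w_norm2 = np.sum(W**2, axis=0)
    vip = np.sqrt(p * ((W**2 / w_norm2) @ ssy) / total)
    return VIPProfile(scores=vip, grid=m.grid)


def save_model(m: PLSModel, path: str | Path) -> None:
    """Serialise a fitted model to JSON (matrices row-major, full precision)."""
    obj = {
        "x_mean": m.x_mean.tolist(),
        "y_mean": m.y_mean.tolist(),
        "weights": m.weights.tolist(),
        "x_loadings": m.x_loadings.tolist(),
        "y_loadings": m.y_loadings.tolist(),
        "score_norms": m.score_norms.tolist(),
        "coefficients": m.coefficients.tolist(),
        "n_components": m.n_components,
        "classes": list(m.encoding.classes) if m.encoding else None,
        "wavelengths": m.grid.wavelengths.tolist() if m.grid else None,
    }
    Path(path).write_text(json.dumps(obj))


def load_model(path: str | Path) -> PLSModel:
    obj = json.loads(Path(path).read_text())
    return PLSModel(
        x_mean=np.array(obj["x_mean"]),
        y_mean=np.array(obj["y_mean"]),
        weights=np.array(obj["weights"]),
        x_loadings=np.array(obj["x_loadings"]),
        y_loadings=np.array(obj["y_loadings"]),
        score_norms=np.array(obj["score_norms"]),
        coefficients=np.array(obj["coefficients"]),
        n_components=int(obj["n_components"]),
        encoding=ClassEncoding(tuple(obj["classes"])) if obj["classes"] else None,
        grid=WavelengthGrid(np.array(obj["wavelengths"])) if obj["wavelengths"] else None,
    )
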