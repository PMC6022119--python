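import numpy as np
import pytest
from hypothesis import settings

import foodspec as fs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid() -> fs.WavelengthGrid:
    return fs.WavelengthGrid.linspace(380, 700, 128)


@pytest.fixture(scope="session")
def tiny_set(small_grid) -> fs.SpectraSet:
    """2-session raw-scan dataset, 4 specimens per type on a 128-point grid."""
    cfg = fs.SimConfig(n_per_type=4, grid=small_grid, seed=7)
    return fs.generate_dataset(cfg)[0]


@pytest.fixture(scope="session")
def separable_sets() -> list[fs.SpectraSet]:
    """Well-separated two-class, two-session data for classification tests."""
    grid = fs.WavelengthGrid.linspace(380, 700, 128)
    cfg = fs.SimConfig(
        grid=grid,
        n_per_type=10,
        noise_sd=0.01,
        specimen_jitter_sd=0.02,
        signatures=(
            fs.ClassSignature("alpha", ((520.0, 25.0, 0.30),)),
            fs.ClassSignature("beta", ((620.0, 25.0, 0.30),)),
        ),
        sessions=(
            fs.SessionEffect("session1"),
            fs.SessionEffect("session2", additive_offset=(0.02, 0.01), gain=1.05, seed_offset=1),
        ),
        seed=11,
    )
    return fs.generate_dataset(cfg)


@pytest.fixture(scope="session")
def separable_preprocessed(separable_sets) -> fs.SpectraSet:
    return fs.preprocess_pipeline(fs.average_scans(separable_sets[0]))


# ---------------------------------------------------------------------------
# Independent oracles (kept free of any foodspec model code)


def nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """Classic NIPALS PLS1: deflate X and y, coefficients via W(PᵀW)⁻¹q.

    Returns fitted values on the training data.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    x_mean, y_mean = X.mean(axis=0), y.mean()
    Xk = X - x_mean
    yk = y - y_mean
    Xc = Xk.copy()
    W, P, q = [], [], []
    for _ in range(n_components):
        w = Xk.T @ yk
        w = w / np.linalg.norm(w)
        t = Xk @ w
        tt = float(t @ t)
        p = Xk.T @ t / tt
        qa = float(yk @ t / tt)
        Xk = Xk - np.outer(t, p)
        yk = yk - qa * t
        W.append(w)
        P.append(p)
        q.append(qa)
    W = np.column_stack(W)
    P = np.column_stack(P)
    q = np.asarray(q)
    B = W @ np.linalg.solve(P.T @ W, q)
    return Xc @ B + y_mean


def ols_fitted(X: np.ndarray, Y: np.ndarray):
    """Least-squares fitted values of column-centred Y on column-centred X."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    return Xc @ B + Y.mean(axis=0)


def savgol_bruteforce(values: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """Per-window least-squares polynomial fit evaluated at the window centre.

    Only interior points (at least a half-window from each edge) are
    meaningful; edge entries are returned unchanged.
    """
    v = np.asarray(values, float)
    h = window // 2
    out = v.copy()
    rel = np.arange(-h, h + 1, dtype=float)
    for i in range(h, v.size - h):
        coeffs = np.polyfit(rel, v[i - h : i + h + 1], polyorder)
        out[i] = np.polyval(coeffs, 0.0)
    return out
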