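import numpy as np
import pytest
from scipy import ndimage

from dtuemp.simulate import TrialSpec, generate_trial, render_keypoints


@pytest.fixture
def clean_spec():
    """Deterministic zero-noise trial: 10 exact 2-second cycles."""
    return TrialSpec(cycle_period_sd_s=0.0, jitter_sd_px=0.0, outlier_rate=0.0, seed=0)


@pytest.fixture
def clean_trial(clean_spec):
    return generate_trial(clean_spec)


@pytest.fixture
def outlier_spec():
    """The standard correction fixture: 5% isolated 80-px wrist outliers."""
    return TrialSpec(jitter_sd_px=1.0, outlier_rate=0.05, outlier_magnitude_px=80.0, seed=0)


@pytest.fixture
def noisy_track(outlier_spec):
    trial = generate_trial(outlier_spec)
    return trial, render_keypoints(trial)


def smooth_texture(seed: int, size: int = 96, sigma: float = 1.5) -> np.ndarray:
    """A smoothed random texture suitable for optical-flow estimation."""
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.random((size, size)), sigma)


def shifted_pair(seed: int, shift, size: int = 64, margin: int = 16):
    """Two frames of one texture, the second translated by ``shift`` (u, v).

    The oracle is the known synthetic translation: content at (x, y) in the
    first frame appears at (x + u, y + v) in the second.
    """
    tex = smooth_texture(seed, size + 2 * margin)
    u, v = shift
    f0 = tex[margin : margin + size, margin : margin + size]
    moved = ndimage.shift(tex, (v, u), order=3)
    f1 = moved[margin : margin + size, margin : margin + size]
    return f0, f1


def cd_lasso_objective(X, y, rho1, rho_l2=0.0, iters=100_000, tol=1e-14):
    """Independent cyclic coordinate-descent oracle for the single-task
    objective ||X w - y_c||^2 + rho1 ||w||_1 + rho_l2 ||w||^2 (y centred).

    Deliberately brute-force and unshared with the package solver.
    """
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    n, p = X.shape
    w = np.zeros(p)
    col_sq = (X**2).sum(axis=0)
    r = yc.copy()
    for _ in range(iters):
        w_old = w.copy()
        for j in range(p):
            r += X[:, j] * w[j]
            rho_j = 2.0 * X[:, j] @ r
            w[j] = np.sign(rho_j) * max(abs(rho_j) - rho1, 0.0) / (2.0 * col_sq[j] + 2.0 * rho_l2)
            r -= X[:, j] * w[j]
        if np.max(np.abs(w - w_old)) < tol:
            break
    obj = float(np.sum((X @ w - yc) ** 2) + rho1 * np.abs(w).sum() + rho_l2 * np.sum(w**2))
    return w, obj
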