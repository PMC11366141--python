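import numpy as np
import pytest

from actimyo.types import AccelRecording, WindowSeries


def make_recording(
    duration_s: float = 600.0,
    fs: float = 10.0,
    x=None,
    y=None,
    z=None,
    leg_id: str = "T1_L",
) -> AccelRecording:
    """Recording with per-axis signals given as callables of t or constants."""
    t = np.arange(int(round(duration_s * fs))) / fs
    axes = []
    for sig in (x, y, z):
        if sig is None:
            axes.append(np.zeros_like(t))
        elif callable(sig):
            axes.append(np.asarray(sig(t), dtype=float))
        else:
            axes.append(np.full_like(t, float(sig)))
    return AccelRecording(t=t, xyz=np.stack(axes, axis=1), sample_rate_hz=fs, leg_id=leg_id)


@pytest.fixture
def four_window_series() -> WindowSeries:
    """The defining bout-detection example: SMA [0.20, 0.20, 0.05, 0.14]."""
    return WindowSeries(
        window_start_s=np.array([0.0, 5.0, 10.0, 15.0]),
        sma_g=np.array([0.20, 0.20, 0.05, 0.14]),
        excluded=np.zeros(4, dtype=bool),
    )


def make_grouped_regression(
    seed: int,
    n_clusters: int = 40,
    per_cluster: int = 3,
    beta=(2.0, -1.0, 0.0, 0.5, 0.0),
    sigma_b: float = 2.0,
    sigma_e: float = 1.0,
    intercept: float = 1.5,
):
    """Small clustered Gaussian regression with known coefficients."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(n_clusters), per_cluster)
    n = n_clusters * per_cluster
    X = rng.normal(size=(n, len(beta)))
    b = rng.normal(0.0, sigma_b, n_clusters) if sigma_b > 0 else np.zeros(n_clusters)
    y = intercept + X @ np.asarray(beta) + b[groups] + rng.normal(0.0, sigma_e, n)
    return X, y, groups
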