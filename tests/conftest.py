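import math

import numpy as np
import pytest

from cochleashape import (
    BaseParameters,
    CochleaRecord,
    HeightProfile,
    PopulationTable,
    RadiusProfile,
    default_config,
    generate,
)


def make_record(
    rid="S0",
    side="left",
    base=None,
    angular_length=900.0,
    step_deg=90.0,
    radius_fn=lambda a: 5.0 - 0.25 * a,
    height_fn=lambda a: 0.15 * a,
    metric_length=None,
):
    """Build a record with profiles sampled from closed-form laws."""
    base = base or BaseParameters(A_a=5.3, A_b=3.7, B_a=3.5, B_b=3.3)
    n = int(math.floor(angular_length / step_deg)) + 1
    alpha = np.radians(np.arange(n) * step_deg)
    return CochleaRecord(
        id=rid,
        side=side,
        base=base,
        radius=RadiusProfile(alpha=alpha, r=np.array([radius_fn(a) for a in alpha])),
        height=HeightProfile(alpha=alpha, h=np.array([height_fn(a) for a in alpha])),
        angular_length=angular_length,
        metric_length_measured=metric_length,
    )


@pytest.fixture(scope="session")
def noiseless_population():
    """n=20 noiseless population from the default generating matrices."""
    cfg = default_config(n=20, seed=7, radius_noise_sd=0.0, height_noise_sd=0.0)
    return generate(cfg)


@pytest.fixture(scope="session")
def noisy_population():
    """n=30 population with default measurement noise."""
    cfg = default_config(n=30, seed=11)
    return generate(cfg)


def normal_equations_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent OLS oracle: explicit (XᵀX)⁻¹Xᵀy solve."""
    XtX = X.T @ X
    return np.linalg.inv(XtX) @ (X.T @ y)


def polyline_length(xyz: np.ndarray) -> float:
    """Independent arc-length oracle: summed segment lengths."""
    return float(np.sum(np.linalg.norm(np.diff(xyz, axis=0), axis=1)))
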