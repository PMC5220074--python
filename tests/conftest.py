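import numpy as np
import pytest

from cvqc import BoldRun
from cvqc.phantom import ArtifactSpec, NetworkSpec, PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    """Small, fast phantom spec shared by unit tests."""
    return PhantomSpec(grid_shape=(12, 12, 8), n_volumes=40, n_per_group=(3, 3),
                       seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def striped_pair():
    """A stripe-artifacted cohort and its seed-matched clean twin."""
    base = PhantomSpec(grid_shape=(16, 16, 8), n_volumes=60, n_per_group=(2, 2),
                       atrophy_fraction=0.0, seed=7)
    stripe = ArtifactSpec(
        kind="stripe",
        affected_slices=(3, 4),
        affected_volumes=tuple(range(20, 35)),
        amplitude=10.0 * base.noise_sd,
        target_subjects=("pat001",),
    )
    from dataclasses import replace

    artifacted = generate_cohort(replace(base, artifact_specs=(stripe,)))
    clean = generate_cohort(base)
    return artifacted, clean, stripe


def make_run(series: np.ndarray, shape=(8, 8, 8), tr: float = 1.8) -> BoldRun:
    """Broadcast a 1D time series to every voxel of a small run."""
    series = np.asarray(series, dtype=float)
    data = np.broadcast_to(series, shape + series.shape).copy()
    return BoldRun(data=data, tr_seconds=tr)
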