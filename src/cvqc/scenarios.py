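"""Canned phantom study conditions.

These fix the cohort sizes, amplitudes and artifact footprints used
throughout the package's evaluation scripts and tests, so that every
consumer exercises the same frozen conditions.  Amplitudes follow the
package defaults (baseline 1000, noise SD 20, network amplitude 10);
artifact strengths are stated per scenario.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .phantom import (
    ArtifactSpec,
    NetworkSpec,
    PhantomSpec,
    default_networks,
    generate_cohort,
    generate_normative_cohort,
)

__all__ = [
    "qc_detection_spec",
    "recovery_spec",
    "mechanism_spec",
    "csf_contrast_spec",
    "null_spec",
    "STRIPE_SUBJECTS",
    "MECHANISM_ARTIFACT_SUBJECTS",
]

#: the five stripe-artifacted subjects of the QC-detection cohort
STRIPE_SUBJECTS = ("pat001", "pat002", "pat003", "pat004", "con001")
#: the artifacted minority of the mechanism cohort (3 patients, 1 control)
MECHANISM_ARTIFACT_SUBJECTS = ("pat001", "pat002", "pat003", "con001")


def qc_detection_spec(seed: int = 0) -> PhantomSpec:
    """20 clean + 5 stripe-artifacted subjects at the default stripe
    amplitude (10 x noise SD on 3 slices for 20 of 100 volumes)."""
    base = PhantomSpec(seed=seed, n_per_group=(13, 12))
    stripe = ArtifactSpec(
        kind="stripe",
        affected_slices=(5, 6, 7),
        affected_volumes=tuple(range(40, 60)),
        amplitude=10.0 * base.noise_sd,
        target_subjects=STRIPE_SUBJECTS,
    )
    return replace(base, artifact_specs=(stripe,))


def recovery_spec(seed: int = 0) -> PhantomSpec:
    """Artifact-free 10+10 cohort with three disjoint equal-amplitude
    networks, for ICA / dual-regression recovery checks."""
    nets = tuple(
        replace(n, amplitude_patient=n.amplitude_control)
        for n in default_networks((32, 32, 12))
    )
    return PhantomSpec(seed=seed, n_per_group=(10, 10), networks=nets,
                       atrophy_fraction=0.0)


def mechanism_spec(seed: int = 0) -> PhantomSpec:
    """12+12 cohort with a true deficit in the 'dmn' network (patient
    amplitude halved) plus high-amplitude stripe artifacts (15 x noise
    SD, 4 slices, half the volumes) in a minority of subjects."""
    base = PhantomSpec(seed=seed, n_per_group=(12, 12))
    stripe = ArtifactSpec(
        kind="stripe",
        affected_slices=(4, 5, 6, 7),
        affected_volumes=tuple(range(10, 60)),
        amplitude=15.0 * base.noise_sd,
        target_subjects=MECHANISM_ARTIFACT_SUBJECTS,
    )
    return replace(base, artifact_specs=(stripe,))


def csf_contrast_spec(seed: int = 0) -> PhantomSpec:
    """8+8 artifact-free cohort with CSF pulsation at the default
    amplitude, for the wbICA vs gmICA spurious-fluctuation contrast."""
    nets = tuple(
        replace(n, amplitude_patient=n.amplitude_control)
        for n in default_networks((32, 32, 12))
    )
    return PhantomSpec(seed=seed, n_per_group=(8, 8), networks=nets,
                       atrophy_fraction=0.0)


def null_spec(seed: int = 0) -> PhantomSpec:
    """Small exchangeable-groups cohort (no deficit, no atrophy, no
    artifacts) on a 12x12x8 grid with 30 volumes and 6+6 subjects, for
    permutation-test validity checks."""
    grid = (12, 12, 8)
    nets = tuple(
        replace(n, amplitude_patient=n.amplitude_control)
        for n in default_networks(grid)
    )
    return PhantomSpec(
        grid_shape=grid, n_volumes=30, n_per_group=(6, 6), networks=nets,
        atrophy_fraction=0.0, seed=seed,
    )
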