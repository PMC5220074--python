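"""Synthetic multi-subject BOLD phantom cohorts with ground truth.

The phantom emulates the structure of a two-group resting-state fMRI
study on a small pre-aligned grid: an ellipsoidal "brain" with concentric
CSF / white-matter / gray-matter compartments, a handful of coherent
networks embedded in the gray-matter shell, a group connectivity deficit
encoded as reduced network amplitude in patients, gray-matter atrophy in
patients, cardiorespiratory-like pulsation confined to CSF, and two
technical artifact classes:

* ``stripe`` -- an additive offset on a subset of slices (slowest axis)
  for a subset of volumes, the signature of within-volume sudden motion
  or partial k-space corruption;
* ``signal_defect`` -- an additive offset over a large contiguous brain
  region for a subset of volumes, a widespread signal-level defect.

Everything injected is recorded in a ground-truth ledger so that
detection and recovery can be scored exactly.  Registration, head
motion, drift and distortion are deliberately absent: every subject
shares the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bold import BoldRun

__all__ = [
    "NetworkSpec",
    "ArtifactSpec",
    "PhantomSpec",
    "PhantomCohort",
    "tissue_compartments",
    "default_networks",
    "generate_cohort",
    "generate_normative_cohort",
]

# compartment labels
BACKGROUND, CSF, WM, GM = 0, 1, 2, 3

#: resting-state fluctuation band shared by network voxels (Hz)
DEFAULT_NETWORK_BAND = (0.01, 0.1)
#: band of the CSF pulsation regressor (Hz); below Nyquist for TR 1.8 s
CSF_PULSATION_BAND = (0.20, 0.26)


@dataclass(frozen=True)
class NetworkSpec:
    """One embedded network: blob centers + radius inside the GM shell.

    ``amplitude_control`` / ``amplitude_patient`` are the group-level
    connectivity strengths (temporal SD of the network signal, in signal
    units); a patient amplitude below the control amplitude encodes a
    group deficit recoverable by the pipeline.
    """

    name: str
    centers: tuple[tuple[float, float, float], ...]
    radius: float
    amplitude_control: float = 10.0
    amplitude_patient: float = 10.0
    timecourse_band: tuple[float, float] = DEFAULT_NETWORK_BAND

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("network radius must be positive")
        if not self.centers:
            raise ValueError("network needs at least one blob center")


@dataclass(frozen=True)
class ArtifactSpec:
    """One injected technical artifact targeting specific subjects."""

    kind: str  # "stripe" or "signal_defect"
    affected_volumes: tuple[int, ...]
    amplitude: float
    target_subjects: tuple[str, ...]
    affected_slices: tuple[int, ...] = ()  # stripe only

    def __post_init__(self) -> None:
        if self.kind not in ("stripe", "signal_defect"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.amplitude == 0:
            raise ValueError("artifact amplitude must be non-zero")
        if not self.affected_volumes:
            raise ValueError("affected_volumes must be non-empty")
        if not self.target_subjects:
            raise ValueError("target_subjects must be non-empty")
        if self.kind == "stripe" and not self.affected_slices:
            raise ValueError("stripe artifacts need affected_slices")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic cohort; deterministic given seed."""

    grid_shape: tuple[int, int, int] = (32, 32, 12)
    n_volumes: int = 100
    tr_seconds: float = 1.8
    n_per_group: tuple[int, int] = (10, 10)  # (controls, patients)
    networks: tuple[NetworkSpec, ...] | None = None
    noise_sd: float = 20.0
    baseline: float = 1000.0
    csf_pulsation_amplitude: float = 60.0
    atrophy_fraction: float = 0.1
    beta_between_subject_sd: float = 0.15  # relative to amplitude_control
    artifact_specs: tuple[ArtifactSpec, ...] = ()
    voxel_size_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 axes, all >= 8")
        if self.n_volumes < 20:
            raise ValueError("n_volumes must be >= 20")
        if not (0 <= self.atrophy_fraction < 1):
            raise ValueError("atrophy_fraction must be in [0, 1)")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.noise_sd < 0 or self.csf_pulsation_amplitude < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if any(n < 0 for n in self.n_per_group):
            raise ValueError("n_per_group entries must be non-negative")

    def resolved_networks(self) -> tuple[NetworkSpec, ...]:
        if self.networks is not None:
            return self.networks
        return default_networks(self.grid_shape)


@dataclass
class PhantomCohort:
    """Generated cohort: runs, GM maps and the ground-truth ledger.

    ``ground_truth`` keys:

    - ``network_maps``: dict name -> 3D float map (1 inside the network);
    - ``betas``: dict subject_id -> dict name -> realised amplitude;
    - ``artifacts``: list of dicts, one per (artifact, subject) injection,
      with the exact slice/volume/region footprint;
    - ``csf_timecourses``: dict subject_id -> unit-SD pulsation regressor;
    - ``compartments``: 3D int label array (0 bg, 1 CSF, 2 WM, 3 GM).
    """

    spec: PhantomSpec
    runs: list[BoldRun]
    gm_maps: dict[str, np.ndarray]
    ground_truth: dict = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.runs]

    @property
    def groups(self) -> dict[str, str]:
        return {r.subject_id: r.group for r in self.runs}

    def run_for(self, subject_id: str) -> BoldRun:
        for r in self.runs:
            if r.subject_id == subject_id:
                return r
        raise KeyError(subject_id)


def tissue_compartments(grid_shape: Sequence[int]) -> np.ndarray:
    """Concentric tissue labels on an ellipsoidal brain.

    Normalised ellipsoidal radius rho (semi-axes 0.45 x grid): CSF core
    at rho < 0.25, a WM ring at 0.25 <= rho < 0.6 and a GM shell at
    0.6 <= rho <= 1.  Outside rho > 1 is background.
    """
    shape = tuple(int(s) for s in grid_shape)
    center = (np.asarray(shape) - 1) / 2.0
    semi = 0.45 * np.asarray(shape)
    grids = np.indices(shape, dtype=np.float64)
    rho = np.sqrt(sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi)))
    labels = np.full(shape, BACKGROUND, dtype=np.int8)
    labels[rho <= 1.0] = GM
    labels[rho < 0.6] = WM
    labels[rho < 0.25] = CSF
    return labels


def default_networks(grid_shape: Sequence[int]) -> tuple[NetworkSpec, ...]:
    """Three disjoint single-blob networks on the GM shell.

    The first ("dmn"-like) network carries a 50% patient amplitude
    deficit; the other two are group-neutral.  Centers sit at 80% of the
    in-plane semi-axes in three directions, which lands them inside the
    GM shell for any permitted grid.
    """
    shape = np.asarray(grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = 0.45 * shape
    radius = max(2.0, float(min(shape[:2])) / 12.0)

    def at(direction: tuple[float, float, float]) -> tuple[float, float, float]:
        d = np.asarray(direction, dtype=float)
        return tuple(center + 0.8 * semi * d)

    return (
        NetworkSpec("dmn", (at((0.0, -1.0, 0.0)),), radius,
                    amplitude_control=10.0, amplitude_patient=5.0),
        NetworkSpec("sln", (at((1.0, 0.0, 0.0)),), radius,
                    amplitude_control=10.0, amplitude_patient=10.0),
        NetworkSpec("visual", (at((-1.0, 0.0, 0.0)),), radius,
                    amplitude_control=10.0, amplitude_patient=10.0),
    )


def _blob_mask(grid_shape: Sequence[int], net: NetworkSpec) -> np.ndarray:
    grids = np.indices(tuple(grid_shape), dtype=np.float64)
    mask = np.zeros(tuple(grid_shape), dtype=bool)
    for cx, cy, cz in net.centers:
        dist2 = (grids[0] - cx) ** 2 + (grids[1] - cy) ** 2 + (grids[2] - cz) ** 2
        mask |= dist2 <= net.radius**2
    return mask


def bandlimited_timecourse(
    rng: np.random.Generator, n: int, tr_seconds: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-SD Gaussian time course band-limited to ``band`` (Hz)."""
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    spectrum = np.fft.rfft(white)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError(f"band {band} Hz contains no resolvable frequency for "
                         f"n={n}, TR={tr_seconds}")
    spectrum[~keep] = 0
    tc = np.fft.irfft(spectrum, n)
    sd = tc.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate band-limited time course")
    return tc / sd


def _defect_region(labels: np.ndarray) -> np.ndarray:
    """The fixed 'widespread signal defect' region: anterior half-brain."""
    region = labels > BACKGROUND
    half = labels.shape[1] // 2
    region = region.copy()
    region[:, half:, :] = False
    return region


def _validate_artifacts(spec: PhantomSpec, subject_ids: list[str]) -> None:
    known = set(subject_ids)
    per_subject: dict[str, list[ArtifactSpec]] = {}
    nz = spec.grid_shape[2]
    for art in spec.artifact_specs:
        if any(v < 0 or v >= spec.n_volumes for v in art.affected_volumes):
            raise ValueError("artifact affected_volumes out of range")
        if art.kind == "stripe" and any(s < 0 or s >= nz for s in art.affected_slices):
            raise ValueError("artifact affected_slices out of range")
        for sid in art.target_subjects:
            if sid not in known:
                raise ValueError(f"artifact targets unknown subject {sid!r}")
            per_subject.setdefault(sid, []).append(art)
    # reject contradictory overlaps: same subject, overlapping volume and
    # spatial footprint, different amplitude
    for sid, arts in per_subject.items():
        for i in range(len(arts)):
            for j in range(i + 1, len(arts)):
                a, b = arts[i], arts[j]
                if not set(a.affected_volumes) & set(b.affected_volumes):
                    continue
                spatial_overlap = (
                    a.kind == "signal_defect"
                    or b.kind == "signal_defect"
                    or bool(set(a.affected_slices) & set(b.affected_slices))
                )
                if spatial_overlap and a.amplitude != b.amplitude:
                    raise ValueError(
                        f"contradictory overlapping artifacts for subject {sid!r}"
                    )


def _subject_ids(spec: PhantomSpec) -> tuple[list[str], list[str]]:
    n_con, n_pat = spec.n_per_group
    controls = [f"con{i + 1:03d}" for i in range(n_con)]
    patients = [f"pat{i + 1:03d}" for i in range(n_pat)]
    return controls, patients


def generate_cohort(spec: PhantomSpec) -> PhantomCohort:
    """Generate a seeded two-group cohort with ground truth.

    Each subject's series is ``baseline + sum_k beta_sk map_k tc_k(t)``
    inside the brain, plus white noise everywhere, plus a shared
    pulsation regressor in CSF voxels; artifacts are added last as
    additive offsets on their declared footprints.
    """
    labels = tissue_compartments(spec.grid_shape)
    gm_compartment = labels == GM
    networks = spec.resolved_networks()

    net_masks: dict[str, np.ndarray] = {}
    for net in networks:
        blob = _blob_mask(spec.grid_shape, net)
        if not blob.any():
            raise ValueError(f"network {net.name!r} mask is empty / outside grid")
        mask = blob & gm_compartment
        if not mask.any():
            raise ValueError(f"network {net.name!r} lies outside the GM compartment")
        net_masks[net.name] = mask

    controls, patients = _subject_ids(spec)
    subject_ids = controls + patients
    _validate_artifacts(spec, subject_ids)

    # deterministic per-subject substreams
    children = np.random.SeedSequence(spec.seed).spawn(len(subject_ids))

    brain = labels > BACKGROUND
    csf = labels == CSF
    defect_region = _defect_region(labels)

    # GM voxels adjacent to any network get higher atrophy probability
    from scipy.ndimage import binary_dilation

    near_networks = np.zeros(spec.grid_shape, dtype=bool)
    for mask in net_masks.values():
        near_networks |= binary_dilation(mask, iterations=2)

    runs: list[BoldRun] = []
    gm_maps: dict[str, np.ndarray] = {}
    betas: dict[str, dict[str, float]] = {}
    csf_tcs: dict[str, np.ndarray] = {}
    ledger: list[dict] = []

    gm_idx = np.argwhere(gm_compartment)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = spec.voxel_size_mm

    for sid, seedseq in zip(subject_ids, children):
        rng = np.random.default_rng(seedseq)
        group = "control" if sid in set(controls) else "patient"

        # subject GM partial-volume map (atrophy for patients)
        pv = gm_compartment.astype(np.float64)
        if group == "patient" and spec.atrophy_fraction > 0:
            n_remove = int(round(spec.atrophy_fraction * len(gm_idx)))
            weights = np.where(near_networks[tuple(gm_idx.T)], 2.0, 1.0)
            weights = weights / weights.sum()
            chosen = rng.choice(len(gm_idx), size=n_remove, replace=False, p=weights)
            removed = gm_idx[chosen]
            pv[tuple(removed.T)] = 0.0
        gm_maps[sid] = pv

        data = np.zeros(spec.grid_shape + (spec.n_volumes,), dtype=np.float64)
        data[brain] += spec.baseline

        betas[sid] = {}
        for net in networks:
            amp = net.amplitude_control if group == "control" else net.amplitude_patient
            sd = spec.beta_between_subject_sd * net.amplitude_control
            beta = amp if sd == 0 else max(0.0, rng.normal(amp, sd))
            betas[sid][net.name] = float(beta)
            tc = bandlimited_timecourse(rng, spec.n_volumes, spec.tr_seconds,
                                        net.timecourse_band)
            # atrophied voxels lose their network contribution with the tissue
            contrib_mask = net_masks[net.name] & (pv > 0)
            data[contrib_mask] += beta * tc

        # CSF pulsation: shared high-frequency regressor within CSF
        tc_csf = bandlimited_timecourse(rng, spec.n_volumes, spec.tr_seconds,
                                        CSF_PULSATION_BAND)
        csf_tcs[sid] = tc_csf
        if spec.csf_pulsation_amplitude > 0:
            data[csf] += spec.csf_pulsation_amplitude * tc_csf

        if spec.noise_sd > 0:
            data += rng.normal(0.0, spec.noise_sd, size=data.shape)

        # artifacts last, as additive offsets
        for art in spec.artifact_specs:
            if sid not in art.target_subjects:
                continue
            vols = np.asarray(sorted(art.affected_volumes))
            if art.kind == "stripe":
                slices = np.asarray(sorted(art.affected_slices))
                data[:, :, slices[:, None], vols[None, :]] += art.amplitude
                footprint = {"slices": [int(s) for s in slices]}
            else:
                sub = data[defect_region]
                sub[:, vols] += art.amplitude
                data[defect_region] = sub
                footprint = {"region": "anterior_half_brain"}
            ledger.append({
                "subject_id": sid,
                "kind": art.kind,
                "volumes": [int(v) for v in vols],
                "amplitude": float(art.amplitude),
                **footprint,
            })

        runs.append(BoldRun(data=data, tr_seconds=spec.tr_seconds,
                            subject_id=sid, group=group, affine=affine.copy()))

    ground_truth = {
        "network_maps": {name: mask.astype(np.float64) for name, mask in net_masks.items()},
        "betas": betas,
        "artifacts": ledger,
        "csf_timecourses": csf_tcs,
        "compartments": labels,
        "defect_region": defect_region,
    }
    return PhantomCohort(spec=spec, runs=runs, gm_maps=gm_maps,
                         ground_truth=ground_truth)


def generate_normative_cohort(spec: PhantomSpec, n_subjects: int) -> PhantomCohort:
    """Artifact-free, atrophy-free, control-amplitude cohort for building
    the normative CV reference (the stand-in for a large healthy birth
    cohort scanned with identical parameters)."""
    if n_subjects < 2:
        raise ValueError("a normative cohort needs >= 2 subjects (SD undefined)")
    norm_spec = replace(
        spec,
        n_per_group=(n_subjects, 0),
        artifact_specs=(),
        atrophy_fraction=0.0,
        # distinct stream from the study cohort built on the same base seed
        seed=int(np.random.SeedSequence((spec.seed, 0x5EED)).generate_state(1)[0]
                 % (2**31 - 1)),
    )
    cohort = generate_cohort(norm_spec)
    for run in cohort.runs:
        run.subject_id = "norm" + run.subject_id[3:]
    cohort.gm_maps = {"norm" + k[3:]: v for k, v in cohort.gm_maps.items()}
    gt = cohort.ground_truth
    gt["betas"] = {"norm" + k[3:]: v for k, v in gt["betas"].items()}
    gt["csf_timecourses"] = {"norm" + k[3:]: v for k, v in gt["csf_timecourses"].items()}
    return cohort
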