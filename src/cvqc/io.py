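"""NIfTI / manifest / sidecar input-output.

Cohorts on disk are: one 4D NIfTI per subject, one 3D GM partial-volume
NIfTI per subject, a tab-separated manifest (subject_id, group,
bold_path, gm_path) and, for phantoms, a JSON ground-truth sidecar with
the realised network amplitudes and the artifact ledger, plus one 3D
NIfTI per ground-truth network map.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .bold import BoldRun
from .phantom import PhantomCohort

__all__ = [
    "save_map",
    "load_map",
    "save_run",
    "load_run",
    "write_cohort",
    "load_cohort",
]

MANIFEST_COLUMNS = ["subject_id", "group", "bold_path", "gm_path"]


def save_map(values: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a 3D (or 4D) array as NIfTI-1."""
    if affine is None:
        affine = np.diag([4.0, 4.0, 4.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def load_map(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine


def save_run(run: BoldRun, path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    img.header.set_zooms((*run.voxel_size_mm, run.tr_seconds))
    nib.save(img, str(path))


def load_run(path, subject_id: str = "sub-00", group: str = "control",
             tr_seconds: float | None = None) -> BoldRun:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.8
    return BoldRun(data=data, tr_seconds=tr_seconds, subject_id=subject_id,
                   group=group, affine=img.affine)


def write_cohort(cohort: PhantomCohort, outdir) -> Path:
    """Write a cohort to ``outdir``; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for run in cohort.runs:
        bold_path = outdir / f"{run.subject_id}_bold.nii"
        gm_path = outdir / f"{run.subject_id}_gm.nii"
        save_run(run, bold_path)
        save_map(cohort.gm_maps[run.subject_id], gm_path, run.affine)
        rows.append({
            "subject_id": run.subject_id,
            "group": run.group,
            "bold_path": bold_path.name,
            "gm_path": gm_path.name,
        })
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, sep="\t",
                                                        index=False)

    gt = cohort.ground_truth
    if gt:
        net_dir = outdir / "networks"
        net_dir.mkdir(exist_ok=True)
        affine = cohort.runs[0].affine if cohort.runs else None
        for name, net_map in gt.get("network_maps", {}).items():
            save_map(net_map, net_dir / f"{name}.nii", affine)
        sidecar = {
            "tr_seconds": cohort.runs[0].tr_seconds if cohort.runs else None,
            "betas": gt.get("betas", {}),
            "artifacts": gt.get("artifacts", []),
            "network_maps": {
                name: f"networks/{name}.nii" for name in gt.get("network_maps", {})
            },
        }
        (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
    return manifest


def load_cohort(manifest_path) -> PhantomCohort:
    """Load a cohort from a manifest; ground truth is restored when the
    JSON sidecar and network maps are present beside it."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")

    sidecar_path = base / "ground_truth.json"
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    tr = sidecar.get("tr_seconds")

    runs, gm_maps = [], {}
    for row in table.itertuples(index=False):
        run = load_run(base / row.bold_path, subject_id=str(row.subject_id),
                       group=str(row.group), tr_seconds=tr)
        runs.append(run)
        gm_maps[run.subject_id], _ = load_map(base / row.gm_path)

    ground_truth = {}
    if sidecar:
        ground_truth = {
            "betas": sidecar.get("betas", {}),
            "artifacts": sidecar.get("artifacts", []),
            "network_maps": {
                name: load_map(base / rel)[0]
                for name, rel in sidecar.get("network_maps", {}).items()
            },
        }
    return PhantomCohort(spec=None, runs=runs, gm_maps=gm_maps,
                         ground_truth=ground_truth)
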