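"""NIfTI and table I/O, the end-to-end pipeline, and provenance records.

Volumes and masks are NIfTI-1 files on a shared voxel grid; no resampling
or registration is performed — grid mismatches are errors, never silently
fixed.  Feature tables and reports are CSV.  Every pipeline run writes a
machine-readable provenance record (configuration, seed, input checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .evaluation import EvaluationReport, NestedCVConfig, run_nested_cv
from .features import DEFAULT_SPECS, extract_cohort
from .imbalance import CohortTable
from .segmentation import WMLSegmentationConfig, segment_wml
from .synthetic import SyntheticCohortSpec, generate_cohort

__all__ = [
    "SubjectRecord",
    "load_volume",
    "load_mask",
    "save_volume",
    "read_manifest",
    "write_cohort",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject file paths: intensity volume and ROI mask, plus the label."""

    subject_id: str
    label: str
    volume_path: str
    mask_path: str


def load_volume(path) -> Tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI volume; returns the data array and the affine."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} is {data.ndim}D; expected a 3D volume")
    return np.asarray(data, dtype=float), img.affine


def load_mask(path) -> Tuple[np.ndarray, np.ndarray]:
    """Load a binary mask volume; nonzero values are coerced to 1 (warned)."""
    data, affine = load_volume(path)
    vals = np.unique(data)
    if not np.isin(vals, (0, 1)).all():
        warnings.warn(
            f"mask {path} has values outside {{0, 1}}; coercing nonzero to 1",
            stacklevel=2,
        )
    return data > 0, affine


def save_volume(array: np.ndarray, path, affine: Optional[np.ndarray] = None) -> None:
    """Write an array as NIfTI-1 (identity affine by default)."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), str(path))


def read_manifest(path) -> List[SubjectRecord]:
    """Read a subject manifest CSV: subject_id, label, volume_path, mask_path."""
    df = pd.read_csv(path)
    required = {"subject_id", "label", "volume_path", "mask_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    base = Path(path).parent
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                label=str(row["label"]),
                volume_path=str((base / row["volume_path"]).resolve()),
                mask_path=str((base / row["mask_path"]).resolve()),
            )
        )
    return records


def write_cohort(spec: SyntheticCohortSpec, out_dir) -> Path:
    """Generate a synthetic cohort and persist it as NIfTI + manifest CSV.

    Writes ``<id>_vol.nii``, ``<id>_brain.nii``, ``<id>_wm.nii`` and (when
    lesions were simulated) ``<id>_wml.nii`` per subject, plus
    ``subjects.csv`` usable with :func:`read_manifest` (mask column = WM).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects, _ = generate_cohort(spec)
    rows = []
    for s in subjects:
        try:
            save_volume(s.volume, out_dir / f"{s.subject_id}_vol.nii")
            save_volume(s.brain_mask, out_dir / f"{s.subject_id}_brain.nii")
            save_volume(s.wm_mask, out_dir / f"{s.subject_id}_wm.nii")
            if s.wml_mask.any():
                save_volume(s.wml_mask, out_dir / f"{s.subject_id}_wml.nii")
        except OSError as exc:
            raise OSError(f"failed writing subject {s.subject_id}: {exc}") from exc
        rows.append(
            {"subject_id": s.subject_id, "label": s.label,
             "volume_path": f"{s.subject_id}_vol.nii",
             "mask_path": f"{s.subject_id}_wm.nii"}
        )
    manifest = out_dir / "subjects.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _sha256(path, chunk: int = 1 << 20) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        while True:
            block = f.read(chunk)
            if not block:
                break
            h.update(block)
    return h.hexdigest()


def run_pipeline(
    records: Sequence[SubjectRecord],
    out_dir,
    variant: str = "ri",
    slice_axis: int = 2,
    config: NestedCVConfig = NestedCVConfig(),
    smote_mode: str = "within-folds",
    segment_config: Optional[WMLSegmentationConfig] = None,
) -> EvaluationReport:
    """Extract features for every subject, classify, and persist artifacts.

    When ``segment_config`` is given, each subject's mask file is treated as
    a brain mask and the ROI is the automatically segmented WML mask;
    otherwise the mask file is used as the ROI directly.  Writes
    ``features.csv``, ``fold_metrics.csv``, ``summary.csv``, ``summary.txt``
    and ``provenance.json`` under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def subjects():
        for rec in records:
            stage = "load"
            try:
                vol, affine = load_volume(rec.volume_path)
                mask, m_affine = load_mask(rec.mask_path)
                if mask.shape != vol.shape:
                    raise ValueError(
                        f"mask grid {mask.shape} does not match volume grid {vol.shape}"
                    )
                if segment_config is not None:
                    stage = "segment"
                    mask = segment_wml(vol, mask, segment_config, slice_axis=slice_axis)
                stage = "extract"
                yield rec.subject_id, rec.label, vol, mask
            except Exception as exc:
                raise RuntimeError(
                    f"stage '{stage}' failed for subject {rec.subject_id}: {exc}"
                ) from exc

    roi = "wml" if segment_config is not None else "roi"
    table = extract_cohort(subjects(), variant=variant, slice_axis=slice_axis, roi=roi)
    table.to_frame().to_csv(out_dir / "features.csv")

    report = run_nested_cv(table, config=config, smote_mode=smote_mode)
    report.fold_metrics().to_csv(out_dir / "fold_metrics.csv")
    report.summary().to_csv(out_dir / "summary.csv")
    (out_dir / "summary.txt").write_text(report.to_text() + "\n")

    provenance = {
        "config": asdict(config),
        "smote_mode": smote_mode,
        "variant": variant,
        "slice_axis": slice_axis,
        "segmentation": asdict(segment_config) if segment_config else None,
        "inputs": {
            rec.subject_id: {
                "volume": _sha256(rec.volume_path),
                "mask": _sha256(rec.mask_path),
            }
            for rec in records
        },
        "selected_features_per_fold": [list(s) for s in report.selected],
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    logger.info("pipeline artifacts written to %s", out_dir)
    return report
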