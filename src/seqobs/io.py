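"""Formats and configuration: NIfTI volumes, tab-separated event and
summary tables, YAML study configs, and content-hash manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StudyConfig",
    "write_nifti",
    "read_nifti",
    "write_table",
    "read_table",
    "write_manifest",
    "file_sha256",
]


@dataclass
class StudyConfig:
    """Everything needed to regenerate and analyze one synthetic study.

    All randomness is derived from the named seeds, so a config fully
    determines every artifact the pipeline writes.
    """

    n_subjects: int = 6
    grid_shape: tuple[int, int, int] = (8, 8, 8)
    voxel_size_mm: float = 2.0
    tr: float = 2.6
    n_runs: int = 10
    n_volumes: int = 136
    signal_amplitude: float = 0.5
    noise_variance: float = 1.0
    noise_length_scale_mm: float = 4.0
    ar1_coef: float = 0.3
    drift_amplitude: float = 1.0
    bold_noise_scale: float = 1.0
    # behavior
    delta_init_ms: float = 84.0
    delta_exec_ms: float = 115.0
    error_prob: float = 0.12
    # analysis options
    searchlight_k: int = 33
    subset_size: int = 64
    n_subsets: int = 50
    ldc_smoothing_fwhm_mm: float = 4.0
    group_radius_mm: float = 8.0
    subject_radius_mm: float = 6.0
    n_permutations: int = 500
    # named seed streams
    seeds: dict[str, int] = field(
        default_factory=lambda: {
            "pool": 11,
            "allocation": 12,
            "schedule": 13,
            "patterns": 14,
            "bold": 15,
            "behavior": 16,
            "subspace": 17,
        }
    )

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        required = {"pool", "allocation", "schedule", "patterns", "bold", "behavior", "subspace"}
        missing = required - set(self.seeds)
        if missing:
            raise ValueError(f"config must name seeds for {sorted(missing)}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["grid_shape"] = list(self.grid_shape)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def content_hash(self) -> str:
        data = asdict(self)
        data["grid_shape"] = list(self.grid_shape)
        return hashlib.sha256(
            json.dumps(data, sort_keys=True).encode()
        ).hexdigest()[:16]


def write_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write an array as NIfTI-1 (float32 for volumes, uint8 for masks)."""
    arr = np.asarray(data)
    dtype = np.uint8 if arr.dtype == bool else np.float32
    img = nib.Nifti1Image(arr.astype(dtype), np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated table with stable float formatting (determinism)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(outdir: str | Path, config: StudyConfig) -> Path:
    """Manifest of all artifacts in ``outdir`` with content hashes."""
    outdir = Path(outdir)
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config_hash": config.content_hash(),
        "files": {str(p.relative_to(outdir)): file_sha256(p) for p in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
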