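"""NIfTI and table IO.

All maps move through NIfTI-1 (.nii / .nii.gz, gzip transparent via
nibabel); tables are TSV with a header.  Affines are preserved on write and
checked for agreement between modalities — no resampling is performed, so
inputs must already share a grid.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI image; returns (data array, affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_nifti(path: str | Path, data: np.ndarray,
                affine: np.ndarray | None = None) -> Path:
    """Write a NIfTI image (identity affine unless given)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))
    return path


def check_same_grid(a_path: str | Path, b_path: str | Path) -> None:
    """Refuse to combine images on different grids, naming both files."""
    a = nib.load(str(a_path))
    b = nib.load(str(b_path))
    if a.shape[:3] != b.shape[:3] or not np.allclose(a.affine, b.affine, atol=1e-4):
        raise ValueError(
            f"grid mismatch: {a_path} has shape {a.shape[:3]} / affine\n"
            f"{a.affine}\nbut {b_path} has shape {b.shape[:3]} / affine\n{b.affine}"
        )


def write_map_stack(path: str | Path, values: np.ndarray,
                    grid_dims: tuple[int, int, int],
                    affine: np.ndarray | None = None) -> Path:
    """Write an (items, voxels) matrix as a 4D NIfTI, items stacked on the
    4th axis (subjects or components)."""
    values = np.asarray(values, dtype=float)
    vol = values.T.reshape(tuple(grid_dims) + (values.shape[0],))
    return write_nifti(path, vol, affine)


def read_map_stack(path: str | Path) -> np.ndarray:
    """Inverse of write_map_stack: (items, voxels) matrix."""
    data, _ = read_nifti(path)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4D stack (shape {data.shape})")
    return data.reshape(-1, data.shape[3]).T


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path: str | Path, df: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_motion(path: str | Path) -> np.ndarray:
    """Six-column realignment-parameter text table (one row per volume)."""
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got shape {arr.shape}")
    return arr


def align_subjects(left: pd.DataFrame, right: pd.DataFrame,
                   on: str = "subject_id", how: str = "strict") -> pd.DataFrame:
    """Join two subject tables on subject_id.

    In "strict" mode (default) any mismatch between the two id sets is an
    error; "intersect" keeps the common subjects and logs the drop count —
    the complete-case policy is enforced upstream by the pipeline.
    """
    li, ri = set(left[on]), set(right[on])
    if how == "strict" and li != ri:
        raise ValueError(
            f"subject mismatch: {sorted(li - ri)[:5]} only on the left, "
            f"{sorted(ri - li)[:5]} only on the right"
        )
    return left.merge(right, on=on, how="inner")
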