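"""NIfTI and sidecar I/O for stacks, label images, and parameter maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .fitting import ParameterMaps

__all__ = [
    "load_stack",
    "load_labels",
    "save_volume",
    "save_phantom",
    "save_maps",
    "render_montage",
]


def load_stack(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4-D offset stack; returns (data, affine).

    The last axis must index saturation offsets in schedule order.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim < 2:
        raise ValueError(f"{path}: expected an offset stack, got shape {data.shape}")
    return data, img.affine


def load_labels(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()).astype(np.int16)


def save_volume(
    data: np.ndarray, path: str | Path, affine: np.ndarray | None = None
) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def save_phantom(
    stack: np.ndarray,
    labels: np.ndarray,
    truth: dict,
    out_dir: str | Path,
    meta: dict | None = None,
) -> dict[str, Path]:
    """Write a phantom as NIfTI volumes plus a JSON sidecar.

    2-D images are stored as single-slice 3-D volumes so the stack is a
    conventional 4-D NIfTI.  The sidecar echoes generation metadata (seed,
    noise level, tissue table) for provenance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def as3d(a):
        return a[..., None, :] if a.ndim == 3 else (a[..., None] if a.ndim == 2 else a)

    paths["stack"] = out_dir / "stack.nii.gz"
    save_volume(as3d(stack), paths["stack"])
    paths["labels"] = out_dir / "labels.nii.gz"
    nib.save(
        nib.Nifti1Image(as3d(labels).astype(np.int16), np.eye(4)), str(paths["labels"])
    )
    for key in ("f_restricted", "f_free", "t2_free_us", "t2_restricted_us", "s0"):
        if key in truth:
            paths[key] = out_dir / f"truth_{key}.nii.gz"
            save_volume(as3d(truth[key]), paths[key])
    sidecar = dict(meta or {})
    if "tissues" in truth:
        sidecar["tissues"] = {
            str(k): {
                "name": t.name,
                "s0": t.s0,
                "params": None
                if t.params is None
                else {
                    "f_restricted": t.params.f_restricted,
                    "lw_free_hz": t.params.lw_free,
                    "lw_restricted_hz": t.params.lw_restricted,
                },
            }
            for k, t in truth["tissues"].items()
        }
    paths["sidecar"] = out_dir / "phantom.json"
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths


def save_maps(maps: ParameterMaps, out_dir: str | Path) -> dict[str, Path]:
    """Write one 3-D NIfTI per parameter map, the mask, and a QC JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, data in maps.named_maps().items():
        vol = data[..., None] if data.ndim == 2 else data
        paths[name] = out_dir / f"{name}.nii.gz"
        save_volume(vol, paths[name], maps.affine)
    mask = maps.mask[..., None] if maps.mask.ndim == 2 else maps.mask
    paths["mask"] = out_dir / "mask.nii.gz"
    nib.save(
        nib.Nifti1Image(mask.astype(np.uint8), maps.affine if maps.affine is not None else np.eye(4)),
        str(paths["mask"]),
    )
    paths["qc"] = out_dir / "qc.json"
    paths["qc"].write_text(json.dumps(maps.qc, indent=2))
    return paths


def render_montage(maps: ParameterMaps, path: str | Path, slice_index: int = 0) -> Path:
    """Render the four parameter maps plus NRMSD as a one-row PNG montage."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    named = maps.named_maps()
    fig, axes = plt.subplots(1, len(named), figsize=(3 * len(named), 3))
    for ax, (name, data) in zip(axes, named.items()):
        img = data if data.ndim == 2 else data[..., slice_index]
        im = ax.imshow(img.T, origin="lower", interpolation="nearest")
        ax.set_title(name)
        ax.axis("off")
        fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
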