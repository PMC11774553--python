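"""Readers, writers, run configuration and manifests.

Canonical in-memory layout is ``(frames, height, width)``; every reader
converts to it and every manifest records it.  Supported array formats:
NIfTI (``.nii``/``.nii.gz``) via nibabel, NumPy ``.npy``/``.npz``, and
PNG/TIFF (single- or multi-frame) via imageio.  Tables are CSV (UTF-8,
comma, header row, ``.`` decimal); segment maps and run configs are YAML;
every output directory gets a JSON manifest with the config, seed and
library versions needed to reproduce the run.
"""

from __future__ import annotations

import importlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .core import SegmentMap, SegmentedInstance, validate_instance

__all__ = [
    "RunConfig",
    "read_array",
    "write_array",
    "read_instance",
    "write_instance",
    "read_segmap",
    "write_segmap",
    "read_demographics",
    "write_manifest",
    "save_cohort",
    "load_cohort",
    "load_classifier",
]

AXES_CANONICAL = "THW"


@dataclass
class RunConfig:
    """Configuration of an end-to-end explanation run."""

    cohort_dir: str = "."
    output_dir: str = "out"
    subsets: Optional[List[str]] = None  # e.g. ["1", "2", "1+2"]; None = all
    classifier: Optional[str] = None  # "module.path:attribute" plugin reference
    batch_size: int = 16
    seed: int = 0
    axes: str = AXES_CANONICAL

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _permute_axes(array: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a 3-D array described by ``axes`` (e.g. ``\"HWT\"``) to (T, H, W)."""
    axes = axes.upper()
    if sorted(axes) != sorted(AXES_CANONICAL):
        raise ValueError(f"axes spec must be a permutation of 'THW', got {axes!r}")
    return np.transpose(array, [axes.index(a) for a in AXES_CANONICAL])


def read_array(path, axes: str = AXES_CANONICAL) -> np.ndarray:
    """Load an image/mask array from disk into (frames, height, width) layout.

    2-D inputs become single-frame stacks; 3-D inputs are permuted from the
    declared ``axes`` order (never guessed — medical-imaging conventions
    vary).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"array file not found: {path}")
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        array = np.asarray(nib.load(str(path)).dataobj)
    elif path.suffix == ".npy":
        array = np.load(path)
    elif path.suffix == ".npz":
        with np.load(path) as data:
            keys = list(data.keys())
            array = data[keys[0]]
    elif path.suffix.lower() in (".png", ".tif", ".tiff"):
        import imageio.v3 as iio

        array = iio.imread(path)
    else:
        raise ValueError(f"unsupported array format: {path}")
    array = np.asarray(array)
    if array.ndim == 2:
        return array[np.newaxis]
    if array.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D array in {path}, got shape {array.shape}")
    return _permute_axes(array, axes)


def write_array(array: np.ndarray, path, axes: str = AXES_CANONICAL) -> None:
    """Write a (frames, height, width) array, permuting to the declared layout."""
    path = Path(path)
    array = np.asarray(array)
    if array.ndim == 2:
        array = array[np.newaxis]
    out = np.transpose(array, [AXES_CANONICAL.index(a) for a in axes.upper()])
    path.parent.mkdir(parents=True, exist_ok=True)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        out = np.asarray(out)
        if np.issubdtype(out.dtype, np.integer):
            out = out.astype(np.int32)  # NIfTI has no 64-bit integer type
        nib.save(nib.Nifti1Image(out, affine=np.eye(4)), str(path))
    elif path.suffix == ".npy":
        np.save(path, out)
    elif path.suffix == ".npz":
        np.savez_compressed(path, array=out)
    elif path.suffix.lower() in (".png", ".tif", ".tiff"):
        import imageio.v3 as iio

        iio.imwrite(path, np.asarray(out))
    else:
        raise ValueError(f"unsupported array format: {path}")


def read_instance(
    image_path,
    mask_path,
    segmap: SegmentMap,
    instance_id: Optional[str] = None,
    axes: str = AXES_CANONICAL,
    demographics: Optional[dict] = None,
) -> SegmentedInstance:
    """Load an image + mask pair and validate it against the segment map."""
    if not Path(mask_path).exists():
        raise FileNotFoundError(f"mask file not found: {mask_path}")
    pixels = read_array(image_path, axes=axes)
    mask = read_array(mask_path, axes=axes).astype(np.int64)
    if instance_id is None:
        instance_id = Path(image_path).name.split(".")[0]
    instance = SegmentedInstance(
        id=instance_id, pixels=pixels, mask=mask, demographics=demographics
    )
    return validate_instance(instance, segmap)


def write_instance(instance: SegmentedInstance, image_path, mask_path,
                   axes: str = AXES_CANONICAL) -> None:
    write_array(instance.pixels, image_path, axes=axes)
    write_array(instance.mask, mask_path, axes=axes)


def read_segmap(path) -> SegmentMap:
    """Segment map from a YAML mapping of code → name, in file order."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"segment map file {path} must be a mapping of code to name")
    return SegmentMap(tuple((int(c), str(n)) for c, n in data.items()))


def write_segmap(segmap: SegmentMap, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(segmap.to_dict(), fh, sort_keys=False)


def read_demographics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError(f"demographics file {path} lacks an 'id' column")
    df["id"] = df["id"].astype(str)
    return df


def write_manifest(out_dir, command: str, config: dict, seed: int) -> Path:
    """Record everything needed to reproduce a run's deterministic stages."""
    import morphmix

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "axes": AXES_CANONICAL,
        "versions": {
            "morphmix": getattr(morphmix, "__version__", "unknown"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


def save_cohort(out_dir, instances: Sequence[SegmentedInstance],
                demographics: pd.DataFrame, segmap: SegmentMap) -> None:
    """Write a cohort as images/<id>.npy + masks/<id>.npy + CSV + YAML."""
    out_dir = Path(out_dir)
    for inst in instances:
        write_array(inst.pixels, out_dir / "images" / f"{inst.id}.npy")
        write_array(inst.mask, out_dir / "masks" / f"{inst.id}.npy")
    demographics.to_csv(out_dir / "demographics.csv", index=False)
    write_segmap(segmap, out_dir / "segmap.yaml")


def load_cohort(cohort_dir) -> Tuple[List[SegmentedInstance], pd.DataFrame, SegmentMap]:
    """Load a cohort directory written by :func:`save_cohort`."""
    cohort_dir = Path(cohort_dir)
    segmap = read_segmap(cohort_dir / "segmap.yaml")
    demographics = read_demographics(cohort_dir / "demographics.csv")
    demo_by_id = demographics.set_index("id").to_dict("index")
    instances = []
    for row_id in demographics["id"]:
        instances.append(
            read_instance(
                cohort_dir / "images" / f"{row_id}.npy",
                cohort_dir / "masks" / f"{row_id}.npy",
                segmap,
                instance_id=row_id,
                demographics=demo_by_id.get(row_id),
            )
        )
    return instances, demographics, segmap


def load_classifier(spec: Optional[str]):
    """Resolve a classifier plugin from a ``module.path:attribute`` string.

    The attribute must expose ``predict`` (used as-is) or be a zero-argument
    factory returning such an object.  With ``spec=None`` the built-in
    phantom reference classifier is returned.
    """
    if spec is None:
        from .phantoms import ReferenceClassifier

        return ReferenceClassifier()
    module_path, _, attr = spec.partition(":")
    if not attr:
        raise ValueError(f"classifier spec {spec!r} must look like 'module.path:attribute'")
    obj = getattr(importlib.import_module(module_path), attr)
    if hasattr(obj, "predict"):
        return obj
    if callable(obj):
        obj = obj()
        if hasattr(obj, "predict"):
            return obj
    raise TypeError(f"classifier plugin {spec!r} does not expose a predict method")
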