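"""Image, prior-container and checkpoint I/O.

Images live in folder-per-class trees of PNG/JPEG files; priors in a single
HDF5 container with one group per image (dataset ``prior``: float32
``[n1+n2, H/d, W/d]``; attributes ``n1``, ``n2``, ``d``, ``source_shape``,
``source_path``); checkpoints in a single ``.npz`` archive of named
parameter arrays plus a JSON config snapshot and the seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
from PIL import Image, UnidentifiedImageError

from .ltm import LtmPrior
from .uma import to_gray_norm

logger = logging.getLogger(__name__)

_EXTS = {".png", ".jpg", ".jpeg"}

__all__ = [
    "read_image_tree",
    "write_image_tree",
    "write_prior_container",
    "read_prior_container",
    "save_checkpoint",
    "load_checkpoint",
]


def read_image_tree(root) -> Iterator[tuple[np.ndarray, int, str]]:
    """Iterate ``(gray_image, label, path)`` over a folder-per-class tree.

    Class folders and files are visited in lexicographic order, so two reads
    of the same tree enumerate identically; labels are contiguous indices of
    the sorted folder names.  Unreadable files are skipped with a logged
    warning; empty class folders are warned about but keep their label slot.
    """
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class folders under {root}")
    for label, cdir in enumerate(class_dirs):
        files = sorted(p for p in cdir.iterdir() if p.suffix.lower() in _EXTS)
        if not files:
            logger.warning("empty class folder: %s", cdir)
        for f in files:
            try:
                with Image.open(f) as im:
                    arr = np.asarray(im.convert("RGB" if im.mode == "RGB" else "L"))
            except (OSError, UnidentifiedImageError):
                logger.warning("skipping unreadable image: %s", f)
                continue
            yield to_gray_norm(arr), label, str(f)


def write_image_tree(dataset, root) -> None:
    """Serialize a synthetic dataset to a folder-per-class PNG tree."""
    root = Path(root)
    for i, (shape_img, label) in enumerate(dataset.items):
        cdir = root / dataset.class_name(label)
        cdir.mkdir(parents=True, exist_ok=True)
        u8 = np.round((shape_img.pixels + 1.0) * 127.5).astype(np.uint8)
        Image.fromarray(u8, mode="L").save(cdir / f"{i:05d}.png")


_PRIOR_ATTRS = ("n1", "n2", "d", "source_shape")


def write_prior_container(path, priors: dict[str, LtmPrior]) -> None:
    """Write named priors to an HDF5 container, one group per image."""
    with h5py.File(path, "w") as f:
        for name, prior in priors.items():
            # "/" nests groups in HDF5; keep the container flat and record
            # the original path in the source_path attribute
            g = f.create_group(name.replace("/", "__"))
            g.create_dataset("prior", data=prior.maps.astype(np.float32))
            g.attrs["n1"] = prior.n1
            g.attrs["n2"] = prior.n2
            g.attrs["d"] = prior.d
            g.attrs["source_shape"] = prior.source_shape
            g.attrs["source_path"] = name


def read_prior_container(path, expected_d: int | None = None) -> dict[str, LtmPrior]:
    """Read every prior back, in written (file) order.

    Raises a format error naming any missing attribute, and a configuration
    error if ``expected_d`` is given and disagrees with the stored factor.
    """
    out: dict[str, LtmPrior] = {}
    with h5py.File(path, "r") as f:
        for name in f:
            g = f[name]
            for attr in _PRIOR_ATTRS:
                if attr not in g.attrs:
                    raise ValueError(f"prior group {name!r} missing attribute {attr!r}")
            d = int(g.attrs["d"])
            if expected_d is not None and d != expected_d:
                raise ValueError(
                    f"prior {name!r} was built with d={d}, model stem expects {expected_d}"
                )
            out[name] = LtmPrior(
                maps=np.asarray(g["prior"], dtype=np.float64),
                n1=int(g.attrs["n1"]),
                n2=int(g.attrs["n2"]),
                d=d,
                source_shape=tuple(int(v) for v in g.attrs["source_shape"]),
            )
    return out


def save_checkpoint(path, model, config_dict: dict, seed: int) -> None:
    arrays = {name: p.data for name, p in model.named_parameters()}
    meta = json.dumps({"config": config_dict, "seed": seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict, int]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    return arrays, meta["config"], meta["seed"]


def restore_model(model, arrays: dict[str, np.ndarray]) -> None:
    """Load named parameter arrays into a freshly built model in place."""
    named = dict(model.named_parameters())
    missing = set(named) - set(arrays)
    extra = set(arrays) - set(named)
    if missing or extra:
        raise ValueError(f"checkpoint mismatch; missing={missing}, extra={extra}")
    for name, p in named.items():
        if p.data.shape != arrays[name].shape:
            raise ValueError(f"shape mismatch for {name}")
        p.data = np.asarray(arrays[name], dtype=np.float64)
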