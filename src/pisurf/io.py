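"""Image and report input/output.

Readers accept PNG/TIFF/JPEG (via imageio) and single-slice NIfTI-1 (via
nibabel); colour inputs are converted to luminance and every image is
min-max normalized to [0, 1], with the original dtype and range recorded
so writers can reconstruct a sensible bit depth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .image import normalize

_LUMA = np.array([0.2126, 0.7152, 0.0722])  # Rec. 709 weights


class FormatError(ValueError):
    """Input file exists but cannot be interpreted as a 2-D grayscale image."""


@dataclass
class ImageMeta:
    path: str
    dtype: str
    original_min: float
    original_max: float


def _load_nifti(path: Path) -> np.ndarray:
    import nibabel as nib

    data = np.asanyarray(nib.load(str(path)).dataobj)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise FormatError(
            f"{path}: NIfTI volume has {data.ndim} non-singleton dimensions; "
            "only single-slice 2-D images are supported"
        )
    return np.asarray(data, dtype=np.float64)


def read_image(path, with_meta: bool = False):
    """Read a 2-D grayscale image normalized to [0, 1]."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    name = p.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        raw = _load_nifti(p)
        source_dtype = str(raw.dtype)
    else:
        try:
            loaded = np.asarray(iio.imread(p))
        except Exception as exc:
            raise FormatError(f"{p}: unreadable image ({exc})") from exc
        source_dtype = str(loaded.dtype)
        if loaded.ndim == 3 and loaded.shape[-1] in (3, 4):
            raw = loaded[..., :3].astype(np.float64) @ _LUMA
        elif loaded.ndim != 2:
            raise FormatError(
                f"{p}: expected a 2-D grayscale or RGB(A) image, got shape {loaded.shape}"
            )
        else:
            raw = loaded.astype(np.float64)
    meta = ImageMeta(
        path=str(p),
        dtype=source_dtype,
        original_min=float(raw.min()),
        original_max=float(raw.max()),
    )
    img = normalize(raw, warn_constant=True)
    return (img, meta) if with_meta else img


def write_image(img, path, depth: int = 8) -> None:
    """Write a [0, 1] image with linear quantization to 8 or 16 bits."""
    if depth not in (8, 16):
        raise ValueError(f"depth must be 8 or 16, got {depth}")
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    maxv = 2**depth - 1
    q = np.floor(arr * maxv + 0.5)  # round half up
    out = q.astype(np.uint8 if depth == 8 else np.uint16)
    iio.imwrite(Path(path), out)


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written by every CLI run."""

    tool_version: str
    command: str
    config: dict
    seed: int | None
    inputs: dict = field(default_factory=dict)  # path -> sha256
    counts: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def write_keypoints_tsv(path, keypoints) -> None:
    lines = ["x\ty\tscale\torientation\tresponse\tsign"]
    for kp in keypoints:
        lines.append(
            f"{kp.x:.6f}\t{kp.y:.6f}\t{kp.scale:.6f}\t{kp.orientation:.6f}"
            f"\t{kp.response:.6g}\t{kp.sign:d}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_keypoints_tsv(path):
    from .surf import Keypoint

    lines = Path(path).read_text().strip().splitlines()
    out = []
    for line in lines[1:]:
        x, y, scale, orient, resp, sign = line.split("\t")
        out.append(
            Keypoint(
                x=float(x), y=float(y), scale=float(scale),
                orientation=float(orient), response=float(resp), sign=int(sign),
            )
        )
    return out
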