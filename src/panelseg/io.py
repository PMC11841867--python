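"""Image readers/writers and the segmentation manifest format.

PNG, JPEG and TIFF are accepted on input (8-bit grayscale or RGB); crops are
always written as lossless PNG.  A manifest is a JSON document recording the
source file, the assigned image class, every emitted region with its crop
filename, and the effective configuration, so a segmentation run is fully
reproducible from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
from PIL import Image

from .config import FrameworkConfig
from .exceptions import UnsupportedFormatError
from .regions import PanelRegion

try:
    TOOL_VERSION = metadata.version("panelseg")
except metadata.PackageNotFoundError:  # pragma: no cover
    TOOL_VERSION = "unknown"

_ACCEPTED_MODES = {"L", "RGB"}


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale or RGB raster image as a numpy array."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode == "P":
                im = im.convert("RGB")
            if im.mode not in _ACCEPTED_MODES:
                raise UnsupportedFormatError(
                    f"{path}: unsupported image mode {im.mode!r}; "
                    "expected 8-bit grayscale or RGB"
                )
            return np.asarray(im)
    except FileNotFoundError:
        raise
    except UnsupportedFormatError:
        raise
    except Exception as exc:  # unreadable / not an image
        raise UnsupportedFormatError(f"{path}: cannot read image ({exc})") from exc


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an image as PNG (lossless)."""
    Image.fromarray(np.asarray(image)).save(Path(path), format="PNG")


@dataclass
class RegionRecord:
    """One emitted panel region plus the filename its crop was written to."""

    region: PanelRegion
    crop_file: str

    def to_dict(self) -> dict:
        d = self.region.to_dict()
        d["crop_file"] = self.crop_file
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RegionRecord":
        return cls(
            region=PanelRegion.from_dict(data), crop_file=str(data["crop_file"])
        )


@dataclass
class Manifest:
    source: str
    image_class: str
    regions: list[RegionRecord] = field(default_factory=list)
    config_snapshot: dict = field(default_factory=dict)
    tool_version: str = TOOL_VERSION

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "image_class": self.image_class,
            "regions": [r.to_dict() for r in self.regions],
            "config_snapshot": self.config_snapshot,
            "tool_version": self.tool_version,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Manifest":
        return cls(
            source=str(data["source"]),
            image_class=str(data["image_class"]),
            regions=[RegionRecord.from_dict(r) for r in data["regions"]],
            config_snapshot=dict(data["config_snapshot"]),
            tool_version=str(data["tool_version"]),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "Manifest":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def save_truth(path: str | Path, boxes: list[PanelRegion], label: str) -> None:
    """Write ground-truth boxes of a synthetic figure as JSON."""
    payload = {"label": label, "boxes": [b.to_dict() for b in boxes]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def load_truth(path: str | Path) -> tuple[list[PanelRegion], str]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return [PanelRegion.from_dict(b) for b in payload["boxes"]], payload["label"]
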