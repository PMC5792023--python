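"""Multi-frame image stacks with acquisition metadata and TIFF/JSON I/O."""
from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["MovieStack"]


@dataclass
class MovieStack:
    """Frames of one channel plus pixel size, timestamps and exposure.

    data has shape (frames, rows, cols); timestamps_s is one entry per frame
    and must be strictly increasing; exposure_ms applies to every frame.
    """

    data: np.ndarray
    pixel_size_nm: float
    timestamps_s: np.ndarray
    exposure_ms: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("data must be (frames, rows, cols)")
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.timestamps_s.shape != (self.data.shape[0],):
            raise ValueError("one timestamp per frame required")
        if self.data.shape[0] > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def frame_shape(self) -> tuple:
        return self.data.shape[1:]

    def with_data(self, data: np.ndarray) -> "MovieStack":
        return replace(self, data=data)

    def save(self, path: str | Path) -> None:
        """Write ``<path>.tif`` plus a ``<path>.json`` metadata sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(str(path.with_suffix(".tif")), self.data)
        meta = {
            "pixel_size_nm": self.pixel_size_nm,
            "timestamps_s": self.timestamps_s.tolist(),
            "exposure_ms": self.exposure_ms,
            "channel": self.channel,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MovieStack":
        path = Path(path)
        data = tifffile.imread(str(path.with_suffix(".tif")))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            data=data,
            pixel_size_nm=meta["pixel_size_nm"],
            timestamps_s=np.asarray(meta["timestamps_s"], dtype=float),
            exposure_ms=meta["exposure_ms"],
            channel=meta.get("channel", ""),
        )
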