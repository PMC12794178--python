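"""Frame-based trajectory container."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Trajectory:
    """Ordered coordinate frames in Angstrom.

    frames has shape (n_frames, n_atoms, 3); boxes, if present, holds the
    orthorhombic box edge lengths per frame, shape (n_frames, 3).
    frame_spacing is the time between stored frames in ps.
    """

    frames: np.ndarray
    boxes: np.ndarray | None = None
    frame_spacing: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.boxes is not None:
            self.boxes = np.asarray(self.boxes, dtype=float)
            if self.boxes.shape != (self.n_frames, 3):
                raise ValueError("boxes must have shape (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]
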