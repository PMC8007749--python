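"""Streamline connectome container and tractogram I/O.

A :class:`Connectome` is an ordered collection of streamlines — 3-D
polylines in RAS millimetre world space — optionally tagged with bundle
labels.  It stands in for a normative whole-brain structural connectome at
whatever scale the caller provides (the phantom generator produces
toy-scale ones with a few thousand fibres).

I/O goes through ``nibabel.streamlines``: TCK is the native interchange
format, TRK is written with an identity voxel-to-RAS affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import resample_polyline


@dataclass
class Connectome:
    """Streamlines in mm space with optional per-streamline bundle labels."""

    streamlines: list[np.ndarray]
    bundles: np.ndarray | None = None  # per-streamline label (str), or None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        sls = []
        for i, s in enumerate(self.streamlines):
            arr = np.asarray(s, dtype=float)
            if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 3:
                raise ValueError(f"streamline {i} must be an (N>=2, 3) array")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"streamline {i} has non-finite coordinates")
            sls.append(arr)
        self.streamlines = sls
        if self.bundles is not None:
            self.bundles = np.asarray(self.bundles)
            if self.bundles.shape[0] != len(self.streamlines):
                raise ValueError("bundle labels must match streamline count")

    def __len__(self) -> int:
        return len(self.streamlines)

    def bundle_indices(self, name: str) -> np.ndarray:
        """Streamline indices belonging to the named bundle."""
        if self.bundles is None:
            raise ValueError("connectome has no bundle labels")
        return np.flatnonzero(self.bundles == name)

    def subset(self, indices: np.ndarray) -> "Connectome":
        indices = np.asarray(indices, dtype=int)
        return Connectome(
            [self.streamlines[i] for i in indices],
            None if self.bundles is None else self.bundles[indices],
        )

    def resampled(self, step: float = 0.5) -> list[np.ndarray]:
        """All streamlines resampled at fixed arc-length ``step`` (cached)."""
        key = ("resampled", float(step))
        if key not in self._cache:
            self._cache[key] = [resample_polyline(s, step) for s in self.streamlines]
        return self._cache[key]

    # -- I/O --------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write streamlines as TCK or TRK (by extension), identity affine."""
        path = Path(path)
        tractogram = nib.streamlines.Tractogram(
            self.streamlines, affine_to_rasmm=np.eye(4)
        )
        nib.streamlines.save(tractogram, str(path))

    @classmethod
    def load(cls, path: str | Path, bundles: np.ndarray | None = None) -> "Connectome":
        tf = nib.streamlines.load(str(path))
        sls = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
        return cls(sls, bundles)
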