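"""Electrode-constrained streamline counting for structural connectivity.

The final imaging stage consumes precomputed whole-brain tractography
streamlines (TCK/TRK, world-mm coordinates) together with a labelled volume
in which each electrode (or gyrus) ROI carries a unique integer 1..E.  Each
streamline whose two endpoints fall in two *distinct* nonzero labels
increments that pair's count once; structural data carry no direction, so
the count matrix is symmetric with a zero diagonal (within-electrode
connections are set to zero).  Patient counts can then be compared entrywise
against a control-mean matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LabelVolume:
    """Integer-labelled 3D grid (0 = background) with a voxel->world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.data < 0):
            raise ValueError("labels must be nonnegative integers")
        self._inv = np.linalg.inv(self.affine)  # raises if singular

    @classmethod
    def from_nifti(cls, path) -> "LabelVolume":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(data=np.asanyarray(img.dataobj).astype(int), affine=img.affine)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine), str(path))

    @property
    def n_labels(self) -> int:
        return int(self.data.max())

    def label_at(self, world_mm) -> int:
        """Label at a world-mm point via nearest-voxel rounding (0 outside)."""
        vox = self._inv @ np.append(np.asarray(world_mm, dtype=float), 1.0)
        ijk = np.rint(vox[:3]).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= self.data.shape):
            return 0
        return int(self.data[tuple(ijk)])


@dataclass
class TractCountMatrix:
    """Symmetric streamline counts between labelled ROIs; diagonal forced 0."""

    labels: list  # ROI names in label order (index 0 -> label 1)
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be ExE for E labels")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    def value(self, a: str, b: str):
        return self.counts[self.labels.index(a), self.labels.index(b)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def load_streamlines(path) -> list:
    """Load TCK/TRK streamlines as a list of (N_i, 3) world-mm polylines."""
    import nibabel as nib

    tractogram = nib.streamlines.load(str(path)).tractogram
    # nibabel hands back streamlines in RAS+ mm regardless of on-disk convention
    return [np.asarray(s, dtype=float) for s in tractogram.streamlines]


def save_streamlines(streamlines, path, affine=None) -> None:
    """Write world-mm polylines as a TCK file."""
    import nibabel as nib

    t = nib.streamlines.Tractogram([np.asarray(s, dtype=np.float32)
                                    for s in streamlines],
                                   affine_to_rasmm=np.eye(4))
    nib.streamlines.save(t, str(path))


def endpoint_labels(streamline, vol: LabelVolume) -> tuple:
    """ROI labels at the two endpoints of a streamline (0 = background/outside)."""
    sl = np.asarray(streamline, dtype=float)
    if sl.ndim != 2 or sl.shape[1] != 3 or sl.shape[0] < 2:
        raise ValueError("streamline must be an (N, 3) polyline with N >= 2")
    return vol.label_at(sl[0]), vol.label_at(sl[-1])


def _path_labels(streamline, vol: LabelVolume) -> set:
    return {vol.label_at(p) for p in np.asarray(streamline, dtype=float)} - {0}


def tract_count_matrix(streamlines, vol: LabelVolume, labels=None,
                       mode: str = "endpoint") -> TractCountMatrix:
    """Count streamlines connecting distinct ROI pairs.

    mode="endpoint" (default): a streamline counts for pair (a, b) when its two
    endpoints carry labels a != b, both nonzero.  mode="path": it counts for
    every unordered pair of distinct labels its polyline passes through
    (sensitivity check).  Either way each streamline adds at most 1 per pair,
    and same-label or background-touching streamlines are ignored.
    """
    if mode not in ("endpoint", "path"):
        raise ValueError("mode must be 'endpoint' or 'path'")
    E = vol.n_labels
    if labels is None:
        labels = [str(i) for i in range(1, E + 1)]
    if len(labels) != E:
        raise ValueError(f"expected {E} ROI names, got {len(labels)}")
    counts = np.zeros((E, E), dtype=int)
    for sl in streamlines:
        if mode == "endpoint":
            a, b = endpoint_labels(sl, vol)
            pairs = [(a, b)] if (a != 0 and b != 0 and a != b) else []
        else:
            hit = sorted(_path_labels(sl, vol))
            pairs = [(hit[i], hit[j]) for i in range(len(hit))
                     for j in range(i + 1, len(hit))]
        for a, b in pairs:
            counts[a - 1, b - 1] += 1
            counts[b - 1, a - 1] += 1
    return TractCountMatrix(labels=list(labels), counts=counts)


def difference_vs_controls(patient: TractCountMatrix, control_mean) -> np.ndarray:
    """Entrywise patient minus control-mean counts (signed).

    ``control_mean`` may be a TractCountMatrix or a bare matrix with the same
    label set/order.
    """
    if isinstance(control_mean, TractCountMatrix):
        if list(control_mean.labels) != list(patient.labels):
            raise ValueError("label sets differ between patient and controls")
        cm = control_mean.counts
    else:
        cm = np.asarray(control_mean, dtype=float)
        if cm.shape != patient.counts.shape:
            raise ValueError("control matrix shape mismatch")
    return patient.counts.astype(float) - cm
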