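"""SPXY sample-set partitioning.

Samples are ranked by a joint distance combining Euclidean distance in
spectral space and absolute difference in nitrogen content, each normalized
by its maximum over all pairs.  A Kennard-Stone greedy pass on that joint
metric selects the calibration set; the remainder is the validation set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateDistanceError
from .spectra import SpectraSet


@dataclass
class SplitResult:
    """Calibration/validation index partition.

    ``calibration_idx`` is kept in Kennard-Stone selection order;
    ``validation_idx`` is sorted.
    """

    calibration_idx: np.ndarray
    validation_idx: np.ndarray
    ratio: tuple[int, int]

    @property
    def n_cal(self) -> int:
        return len(self.calibration_idx)

    @property
    def n_val(self) -> int:
        return len(self.validation_idx)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "calibration_idx": [int(i) for i in self.calibration_idx],
            "validation_idx": [int(i) for i in self.validation_idx],
            "ratio": list(self.ratio),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitResult":
        payload = json.loads(Path(path).read_text())
        return cls(
            calibration_idx=np.asarray(payload["calibration_idx"], dtype=int),
            validation_idx=np.asarray(payload["validation_idx"], dtype=int),
            ratio=tuple(payload["ratio"]),
        )


def split_sizes(n: int, ratio: tuple[int, int]) -> tuple[int, int]:
    """(n_cal, n_val) under the floor-on-validation rounding rule.

    n_val = floor(n * v / (c + v)); n_cal = n - n_val.  At 2:1 this maps
    176 -> (118, 58).
    """
    c, v = ratio
    if c <= 0 or v <= 0:
        raise ValueError("ratio parts must be positive")
    n_val = (n * v) // (c + v)
    return n - n_val, n_val


def joint_distance_matrix(spectra: SpectraSet) -> np.ndarray:
    """Symmetric n x n joint spectral-concentration distance matrix.

    d(i,j) = d_x(i,j)/max d_x + d_y(i,j)/max d_y with d_x Euclidean between
    spectra and d_y = |N_i - N_j|.  A term whose maximum is zero is dropped;
    if both vanish the distance is degenerate and an error is raised.
    """
    n = spectra.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    dx = squareform(pdist(spectra.reflectance, metric="euclidean"))
    dy = np.abs(spectra.nitrogen[:, None] - spectra.nitrogen[None, :])
    mx, my = dx.max(), dy.max()
    if mx == 0.0 and my == 0.0:
        raise DegenerateDistanceError("all spectra and all nitrogen values identical")
    d = np.zeros((n, n))
    if mx > 0.0:
        d += dx / mx
    if my > 0.0:
        d += dy / my
    return d


def kennard_stone(d: np.ndarray, n_select: int) -> np.ndarray:
    """Greedy max-min selection on a precomputed distance matrix.

    Seeds with the most mutually distant pair, then repeatedly adds the
    candidate whose minimal distance to the selected set is maximal.
    Ties break to the lowest index (first occurrence under argmax).
    """
    n = d.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError("n_select must lie in [2, n]")
    i, j = np.unravel_index(np.argmax(d), d.shape)
    selected = [int(min(i, j)), int(max(i, j))]
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    mindist = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_select:
        mindist_masked = np.where(in_set, -np.inf, mindist)
        nxt = int(np.argmax(mindist_masked))
        selected.append(nxt)
        in_set[nxt] = True
        mindist = np.minimum(mindist, d[nxt])
    return np.asarray(selected, dtype=int)


def spxy_split(spectra: SpectraSet, ratio: tuple[int, int] = (2, 1)) -> SplitResult:
    """Partition into calibration/validation by SPXY Kennard-Stone selection."""
    n = spectra.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    n_cal, n_val = split_sizes(n, ratio)
    d = joint_distance_matrix(spectra)
    cal = kennard_stone(d, n_cal)
    mask = np.ones(n, dtype=bool)
    mask[cal] = False
    return SplitResult(
        calibration_idx=cal,
        validation_idx=np.flatnonzero(mask),
        ratio=ratio,
    )
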