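"""Square-lattice nanopost array geometry.

The array consists of infinitely long parallel posts aligned with the x
axis whose centers form a square lattice of spacing ``S_p`` in the yz
plane.  Two derived lengths characterize the confinement: the passage
(quasi-slit) width ``w_p = S_p - d_p`` between two nearest posts, and the
quasi-channel diameter ``d_c = sqrt(2)*S_p - d_p`` of the interstitial
space enclosed by four neighboring posts.  Here ``d_p = D_p + w`` is the
effective post diameter (bare diameter plus effective bead size).

The yz plane is partitioned into space-filling squares whose vertices
coincide with post centers; a bead sitting in a passage aperture belongs
to the square that contains it.  These cells define the occupation-number
observable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import BEAD_SIZE, R_CUT, SQRT2

__all__ = [
    "PostArrayGeometry",
    "derived_params",
    "cell_index",
    "post_surface_distances",
    "brute_force_post_distances",
    "geometry_table",
    "CONSTANT_SPACING_DIAMETERS",
    "CONSTANT_PASSAGE_DIAMETERS",
]

#: Effective post diameters of the published constant-spacing series (S_p = 12).
CONSTANT_SPACING_DIAMETERS = (
    1.9, 2.9, 3.9, 4.9, 5.9, 6.9, 7.9, 8.9, 9.9, 10.9, 11.4, 11.9,
)
#: Effective post diameters of the constant-passage series (w_p = 2, S_p = d_p + 2).
CONSTANT_PASSAGE_DIAMETERS = (
    1.9, 2.9, 4.9, 6.9, 8.9, 10.9, 12.9, 14.9, 16.9, 20.9, 30.9, 40.9, 50.9, 60.9,
)


class OverlappingPostsError(ValueError):
    """Posts would overlap along the lattice diagonal (d_p > sqrt(2)*S_p)."""


def derived_params(S_p: float, d_p: float) -> dict[str, float]:
    """Derived array parameters from spacing ``S_p`` and effective diameter ``d_p``.

    Returns a dict with the passage width ``w_p``, quasi-channel diameter
    ``d_c``, post volume fraction ``F`` and the ratio ``d_c/w_p`` (``inf``
    for a closed passage, ``w_p = 0``).
    """
    if S_p <= 0:
        raise ValueError(f"post spacing must be positive, got S_p={S_p}")
    if d_p < 0:
        raise ValueError(f"post diameter must be non-negative, got d_p={d_p}")
    if d_p > SQRT2 * S_p:
        raise OverlappingPostsError(
            f"d_p={d_p} exceeds sqrt(2)*S_p={SQRT2 * S_p:.6g}: posts overlap"
        )
    w_p = S_p - d_p
    d_c = SQRT2 * S_p - d_p
    F = math.pi * d_p * d_p / (4.0 * S_p * S_p)
    ratio = d_c / w_p if w_p != 0 else math.inf
    return {"w_p": w_p, "d_c": d_c, "F": F, "ratio": ratio}


@dataclass(frozen=True)
class PostArrayGeometry:
    """Square lattice of parallel posts (axes along x, lattice in yz).

    Parameters
    ----------
    S_p:
        Center-to-center post spacing (sigma).
    d_p:
        Effective post diameter d_p = D_p + w (sigma).
    w:
        Effective bead size entering the d_p <-> D_p mapping; default 0.9.
    origin:
        yz coordinates of one post center.
    """

    S_p: float
    d_p: float
    w: float = BEAD_SIZE
    origin: tuple[float, float] = (0.0, 0.0)
    _derived: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_derived", derived_params(self.S_p, self.d_p))
        if self.D_p < 0:
            raise ValueError(
                f"bare post diameter D_p = d_p - w = {self.D_p} is negative"
            )

    @classmethod
    def from_passage_width(
        cls, S_p: float, w_p: float, w: float = BEAD_SIZE,
        origin: tuple[float, float] = (0.0, 0.0),
    ) -> "PostArrayGeometry":
        return cls(S_p=S_p, d_p=S_p - w_p, w=w, origin=origin)

    @property
    def D_p(self) -> float:
        """Bare post diameter used by the bead-post potential."""
        return self.d_p - self.w

    @property
    def w_p(self) -> float:
        return self._derived["w_p"]

    @property
    def d_c(self) -> float:
        return self._derived["d_c"]

    @property
    def F(self) -> float:
        return self._derived["F"]

    @property
    def ratio(self) -> float:
        """Confinement-strength ratio d_c / w_p."""
        return self._derived["ratio"]

    def cell_center(self, i: int, j: int) -> np.ndarray:
        """yz coordinates of the center of interstitial cell (i, j)."""
        oy, oz = self.origin
        return np.array([oy + (i + 0.5) * self.S_p, oz + (j + 0.5) * self.S_p])


def cell_index(point_yz, array: PostArrayGeometry) -> tuple[int, int]:
    """Interstitial cell containing a yz point.

    Cell (i, j) is the half-open square [i*S_p, (i+1)*S_p) x [j*S_p,
    (j+1)*S_p) relative to the lattice origin, so boundary points go to the
    lower-index cell (floor convention).
    """
    y, z = float(point_yz[0]), float(point_yz[1])
    if not (math.isfinite(y) and math.isfinite(z)):
        raise ValueError("cell_index requires finite coordinates")
    oy, oz = array.origin
    return (
        int(math.floor((y - oy) / array.S_p)),
        int(math.floor((z - oz) / array.S_p)),
    )


def post_surface_distances(
    point_yz, array: PostArrayGeometry
) -> list[tuple[np.ndarray, float]]:
    """Four posts at the vertices of the point's cell with center distances.

    Since the post spacing always exceeds the bead-post interaction range,
    every post a bead can interact with is among the four vertices of its
    cell; ``brute_force_post_distances`` provides the exhaustive check.
    """
    i, j = cell_index(point_yz, array)
    oy, oz = array.origin
    y, z = float(point_yz[0]), float(point_yz[1])
    out = []
    for di in (0, 1):
        for dj in (0, 1):
            center = np.array([oy + (i + di) * array.S_p, oz + (j + dj) * array.S_p])
            r = math.hypot(y - center[0], z - center[1])
            out.append((center, r))
    return out


def brute_force_post_distances(
    point_yz, array: PostArrayGeometry, half_width: int = 2
) -> list[tuple[np.ndarray, float]]:
    """All posts in a (2*half_width+1)^2 neighborhood with center distances."""
    i, j = cell_index(point_yz, array)
    oy, oz = array.origin
    y, z = float(point_yz[0]), float(point_yz[1])
    out = []
    for di in range(-half_width, half_width + 2):
        for dj in range(-half_width, half_width + 2):
            center = np.array([oy + (i + di) * array.S_p, oz + (j + dj) * array.S_p])
            out.append((center, math.hypot(y - center[0], z - center[1])))
    return out


def posts_in_range(point_yz, array: PostArrayGeometry, distances) -> set[tuple[float, float]]:
    """Post centers within bead-post interaction range of a yz point."""
    rmax = array.D_p / 2.0 + R_CUT
    return {tuple(np.round(c, 9)) for c, r in distances if r <= rmax}


def geometry_table(series: str = "constant_spacing") -> pd.DataFrame:
    """Published geometry series as a DataFrame.

    ``constant_spacing``: S_p = 12, d_p from 1.9 to 11.9.
    ``constant_passage``: w_p = 2, d_p from 1.9 to 60.9 (S_p = d_p + 2).

    Columns: d_p, S_p, w_p, d_c, F, ratio.
    """
    rows = []
    if series == "constant_spacing":
        for d_p in CONSTANT_SPACING_DIAMETERS:
            p = derived_params(12.0, d_p)
            rows.append({"d_p": d_p, "S_p": 12.0, **p})
    elif series == "constant_passage":
        for d_p in CONSTANT_PASSAGE_DIAMETERS:
            S_p = d_p + 2.0
            p = derived_params(S_p, d_p)
            rows.append({"d_p": d_p, "S_p": S_p, **p})
    else:
        raise ValueError(f"unknown series {series!r}")
    return pd.DataFrame(rows)
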