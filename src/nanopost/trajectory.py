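"""Trajectory I/O: XYZ interchange format and lossless HDF5 archival.

Frames are written as standard XYZ blocks; the comment line carries the
step index and an optional metadata tag (e.g. a geometry/config hash), so
a trajectory file is self-describing.  Coordinates are absolute - the
system is unbounded, so there is no box or periodic wrapping.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

__all__ = ["write_xyz", "read_xyz", "write_hdf5", "read_hdf5", "TrajectoryParseError"]


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; message names the offending line."""


def write_xyz(
    path: str | Path,
    frames: np.ndarray,
    steps=None,
    tag: str = "",
    element: str = "C",
) -> None:
    """Write frames (n_frames, N, 3) as multi-frame XYZ.

    Comment line format: ``step=<int> tag=<tag>``.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n_frames, N, _ = frames.shape
    if steps is None:
        steps = np.arange(n_frames)
    steps = np.asarray(steps)
    if steps.size != n_frames:
        raise ValueError("steps must match the number of frames")
    with open(path, "w") as fh:
        for f in range(n_frames):
            fh.write(f"{N}\n")
            fh.write(f"step={int(steps[f])} tag={tag}\n")
            for i in range(N):
                x, y, z = frames[f, i]
                fh.write(f"{element} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a multi-frame XYZ file; returns (frames, steps)."""
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    steps: list[int] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            N = int(lines[i].strip())
        except ValueError:
            raise TrajectoryParseError(
                f"{path}:{i + 1}: expected atom count, got {lines[i]!r}"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        step = len(frames)
        for token in comment.split():
            if token.startswith("step="):
                try:
                    step = int(token[5:])
                except ValueError:
                    raise TrajectoryParseError(
                        f"{path}:{i + 2}: malformed step field {token!r}"
                    )
        coords = np.empty((N, 3))
        for k in range(N):
            ln = i + 2 + k
            if ln >= len(lines):
                raise TrajectoryParseError(
                    f"{path}:{len(lines)}: truncated frame (expected {N} atoms)"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    f"{path}:{ln + 1}: expected 'element x y z', got {lines[ln]!r}"
                )
            try:
                coords[k] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise TrajectoryParseError(
                    f"{path}:{ln + 1}: non-numeric coordinate in {lines[ln]!r}"
                )
        frames.append(coords)
        steps.append(step)
        i += 2 + N
    if not frames:
        raise TrajectoryParseError(f"{path}: no frames found")
    return np.asarray(frames), np.asarray(steps)


def write_hdf5(
    path: str | Path,
    frames: np.ndarray,
    steps=None,
    attrs: dict | None = None,
) -> None:
    """Full-precision trajectory container (exact round trip)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if steps is None:
        steps = np.arange(frames.shape[0])
    with h5py.File(path, "w") as h5:
        h5.create_dataset("positions", data=frames)
        h5.create_dataset("steps", data=np.asarray(steps))
        for key, val in (attrs or {}).items():
            h5.attrs[key] = val


def read_hdf5(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    with h5py.File(path, "r") as h5:
        frames = h5["positions"][...]
        steps = h5["steps"][...]
        attrs = dict(h5.attrs)
    return frames, steps, attrs
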