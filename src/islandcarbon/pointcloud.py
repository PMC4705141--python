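"""Laser-return point clouds and their delimited text codec.

The on-disk dialect is whitespace-delimited ``x y z return_number`` per
line, optionally gzip-compressed (by ``.gz`` suffix); ``#`` lines are
comments. Coordinates are projected meters.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PointCloud", "PointCloudFormatError", "read_point_cloud", "write_point_cloud"]


class PointCloudFormatError(ValueError):
    pass


@dataclass
class PointCloud:
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    return_number: np.ndarray
    #: optional per-return generator truth label (True = emitted from the ground),
    #: populated by the synthetic scene simulator; never serialized.
    truth_ground: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.return_number = np.asarray(self.return_number, dtype=int)
        n = len(self.x)
        if not (len(self.y) == len(self.z) == len(self.return_number) == n):
            raise ValueError("coordinate arrays must have equal length")
        if n and not (
            np.isfinite(self.x).all() and np.isfinite(self.y).all() and np.isfinite(self.z).all()
        ):
            raise ValueError("point coordinates must be finite")
        if n and (self.return_number < 1).any():
            raise ValueError("return_number must be >= 1")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def first_returns(self) -> "PointCloud":
        return self.subset(self.return_number == 1)

    def subset(self, mask) -> "PointCloud":
        mask = np.asarray(mask)
        tg = None if self.truth_ground is None else self.truth_ground[mask]
        return PointCloud(self.x[mask], self.y[mask], self.z[mask],
                          self.return_number[mask], truth_ground=tg)

    def bounds(self) -> tuple[float, float, float, float]:
        return (self.x.min(), self.y.min(), self.x.max(), self.y.max())


def _open(path, mode):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_point_cloud(cloud: PointCloud, path) -> None:
    with _open(path, "w") as fh:
        fh.write("# x y z return_number\n")
        for xi, yi, zi, ri in zip(cloud.x, cloud.y, cloud.z, cloud.return_number):
            fh.write(f"{xi:.3f} {yi:.3f} {zi:.3f} {ri}\n")


def read_point_cloud(path) -> PointCloud:
    """Parse the delimited dialect; malformed rows raise with their line number."""
    xs, ys, zs, rs = [], [], [], []
    with _open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise PointCloudFormatError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(parts)}"
                )
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
                zs.append(float(parts[2]))
                rs.append(int(parts[3]))
            except ValueError as exc:
                raise PointCloudFormatError(f"{path}: line {lineno}: {exc}") from None
    return PointCloud(np.array(xs), np.array(ys), np.array(zs), np.array(rs))
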