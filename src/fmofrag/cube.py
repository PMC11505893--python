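"""Gaussian cube grids: read, write, and difference electron densities.

Follows the standard cube conventions: two comment lines; natoms + origin;
three axis records (voxel counts and step vectors, bohr); atom records;
then values with the last axis fastest.  Densities are e/bohr^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GRID_MATCH_TOL = 1e-6
DEFAULT_ISOLEVELS = (0.05, 0.01, 0.005)  # e/bohr^3, conventional isovalues


class CubeError(ValueError):
    pass


@dataclass
class DensityGrid:
    origin: np.ndarray            # (3,) bohr
    axes: np.ndarray              # (3,3) voxel step vectors, bohr
    counts: tuple[int, int, int]
    values: np.ndarray            # shape == counts
    atoms: list[tuple[int, float, np.ndarray]] = field(default_factory=list)
    comment: str = "fmofrag density grid"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.counts):
            raise CubeError(f"value array shape {self.values.shape} does "
                            f"not match voxel counts {self.counts}")

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.axes)))

    def integral(self) -> float:
        """Volume integral of the grid (e)."""
        return float(self.values.sum() * self.voxel_volume)

    def same_grid_as(self, other: "DensityGrid",
                     tol: float = GRID_MATCH_TOL) -> bool:
        return (self.counts == other.counts
                and np.allclose(self.origin, other.origin, atol=tol)
                and np.allclose(self.axes, other.axes, atol=tol))


def read_cube(path) -> DensityGrid:
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 6:
        raise CubeError(f"{path}: too short to be a cube file")
    comment = lines[0].strip()
    try:
        head = lines[2].split()
        natoms = int(head[0])
        origin = np.array([float(v) for v in head[1:4]])
        if natoms < 0:
            raise CubeError("cube files with DSET ids (negative atom "
                            "count) are not supported")
        counts = []
        axes = []
        for k in range(3):
            toks = lines[3 + k].split()
            counts.append(int(toks[0]))
            axes.append([float(v) for v in toks[1:4]])
        atoms = []
        for k in range(natoms):
            toks = lines[6 + k].split()
            atoms.append((int(toks[0]), float(toks[1]),
                          np.array([float(v) for v in toks[2:5]])))
        vals: list[float] = []
        for ln in lines[6 + natoms:]:
            vals += [float(v) for v in ln.split()]
    except (ValueError, IndexError) as exc:
        raise CubeError(f"{path}: malformed cube file ({exc})")
    n = counts[0] * counts[1] * counts[2]
    if len(vals) != n:
        raise CubeError(f"{path}: expected {n} voxel values, found "
                        f"{len(vals)}")
    values = np.array(vals).reshape(counts)
    return DensityGrid(origin=origin, axes=np.array(axes),
                       counts=tuple(counts), values=values, atoms=atoms,
                       comment=comment)


def write_cube(grid: DensityGrid, path) -> None:
    lines = [grid.comment, "generated by fmofrag"]
    ox, oy, oz = grid.origin
    lines.append(f"{len(grid.atoms):5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}")
    for k in range(3):
        ax, ay, az = grid.axes[k]
        lines.append(f"{grid.counts[k]:5d}{ax:12.6f}{ay:12.6f}{az:12.6f}")
    for z, q, pos in grid.atoms:
        x, y, zz = pos
        lines.append(f"{z:5d}{q:12.6f}{x:12.6f}{y:12.6f}{zz:12.6f}")
    flat = grid.values.reshape(-1)
    for i in range(0, len(flat), 6):
        lines.append("".join(f"{v:13.5E}" for v in flat[i:i + 6]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass
class CubeDiffSummary:
    max_abs: float
    exceed_counts: dict[float, int]
    integral: float  # of the signed difference, e


def cube_diff(a: DensityGrid, b: DensityGrid,
              isolevels=DEFAULT_ISOLEVELS
              ) -> tuple[DensityGrid, CubeDiffSummary]:
    """Voxelwise a - b on identical grids, with an exceedance summary.

    ``exceed_counts[L]`` is the number of voxels with ``|delta rho| > L``;
    counts are monotonically nonincreasing in the level.
    """
    if not a.same_grid_as(b):
        raise CubeError("grids differ (origin/axes/counts); cannot "
                        "difference")
    delta = a.values - b.values
    grid = DensityGrid(origin=a.origin.copy(), axes=a.axes.copy(),
                       counts=a.counts, values=delta,
                       atoms=list(a.atoms),
                       comment="density difference")
    summary = CubeDiffSummary(
        max_abs=float(np.abs(delta).max()) if delta.size else 0.0,
        exceed_counts={float(L): int((np.abs(delta) > L).sum())
                       for L in isolevels},
        integral=float(delta.sum() * grid.voxel_volume))
    return grid, summary


def gaussian_grid(center, sigma: float, amplitude: float,
                  origin, step: float, counts) -> DensityGrid:
    """Analytic isotropic Gaussian sampled on an axis-aligned grid.

    Convenience for validation: the closed-form integral of the density is
    ``amplitude * (2 pi sigma^2)^(3/2)``.
    """
    counts = tuple(counts)
    origin = np.asarray(origin, dtype=float)
    center = np.asarray(center, dtype=float)
    grids = [origin[k] + step * np.arange(counts[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*grids, indexing="ij")
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    vals = amplitude * np.exp(-r2 / (2.0 * sigma ** 2))
    return DensityGrid(origin=origin, axes=np.eye(3) * step,
                       counts=counts, values=vals,
                       comment="analytic gaussian")
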