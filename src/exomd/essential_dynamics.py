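"""Essential dynamics (covariance PCA) and free-energy surfaces.

The positional covariance matrix is built after removing overall
translation and rotation by least-squares superposition of every frame
onto the average structure.  Its leading eigenvectors are the dominant
collective motions ("principal components"); projections of the
trajectory onto the first two span the essential subspace.

The free-energy surface over two order parameters (by default radius of
gyration and RMSD) is obtained by Boltzmann inversion of the sampled 2D
histogram, dG = -kB*T*ln(P / P_max), so the most-populated bin sits at
dG = 0 and every visited bin is non-negative.  Basins deeper than a
threshold are counted as metastable states.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .domain import Trajectory
from .trajectory import AtomSelection, superpose_to_mean

__all__ = [
    "KB_KJ_PER_MOL_K",
    "EDResult",
    "FESGrid",
    "build_covariance",
    "principal_components",
    "project_trajectory",
    "essential_dynamics_analysis",
    "free_energy_surface",
    "count_minima",
]

# Boltzmann constant in kJ mol^-1 K^-1.
KB_KJ_PER_MOL_K = 0.0083144621


def _fitted_flat(
    traj: Trajectory,
    selection: AtomSelection | None,
    mass_weighted: bool,
    masses: np.ndarray | None,
    cut: float,
    fit: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose, select, optionally mass-weight, flatten to (F, 3n)."""
    keep = traj.times >= cut
    coords = traj.coords[keep]
    if coords.shape[0] < 2:
        raise ValueError("equilibration cut leaves fewer than 2 frames")
    if fit:
        coords, _ = superpose_to_mean(coords, selection)
    idx = selection.indices if selection is not None else np.arange(traj.n_particles)
    sub = coords[:, idx, :]
    if mass_weighted:
        if masses is None:
            raise ValueError("mass_weighted requires masses")
        w = np.sqrt(np.asarray(masses, dtype=float)[idx])
        sub = sub * w[None, :, None]
    flat = sub.reshape(sub.shape[0], -1)
    mean = flat.mean(axis=0)
    return flat, mean


def build_covariance(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    mass_weighted: bool = False,
    masses: np.ndarray | None = None,
    cut: float = 0.0,
    fit: bool = True,
    max_dof: int = 3000,
) -> np.ndarray:
    """Positional covariance matrix C = <(x - <x>)(x - <x>)^T> (3N x 3N, nm^2).

    Each retained frame is least-squares superposed onto the average
    structure first (``fit=False`` disables this for analytic tests).
    ``max_dof`` caps the matrix size to keep memory desk-scale; pass a
    larger value explicitly to override.
    """
    flat, mean = _fitted_flat(traj, selection, mass_weighted, masses, cut, fit)
    if flat.shape[1] > max_dof:
        raise ValueError(
            f"selection yields {flat.shape[1]} degrees of freedom > max_dof={max_dof}; "
            "reduce the selection or raise max_dof"
        )
    centred = flat - mean
    return (centred.T @ centred) / centred.shape[0]


@dataclass
class EDResult:
    """Eigen-decomposition of the positional covariance matrix.

    ``eigenvalues`` holds the full descending spectrum (nm^2);
    ``eigenvectors`` the top-k as columns; ``contributions`` the percentage
    of the total fluctuation (trace) captured by each eigenvalue.
    """

    trace: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (3n, k)
    contributions: np.ndarray  # %, full spectrum
    mean: np.ndarray | None = None  # flattened mean configuration
    projections: np.ndarray | None = field(default=None)  # (F, min(k, 2))


def principal_components(C: np.ndarray, k: int = 10) -> EDResult:
    """Top-k eigenpairs of a symmetric covariance matrix, descending."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance matrix must be square")
    scale = max(float(np.max(np.abs(C))), 1e-300)
    if not np.allclose(C, C.T, atol=1e-8 * scale):
        raise ValueError("covariance matrix must be symmetric")
    eigenvalues, eigenvectors = np.linalg.eigh(C)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = eigenvectors[:, order]
    trace = float(np.trace(C))
    contributions = (
        100.0 * eigenvalues / trace if trace > 0 else np.zeros_like(eigenvalues)
    )
    k = min(k, C.shape[0])
    return EDResult(
        trace=trace,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors[:, :k],
        contributions=contributions,
    )


def project_trajectory(
    traj: Trajectory,
    ed: EDResult,
    selection: AtomSelection | None = None,
    cut: float = 0.0,
    fit: bool = True,
    n_components: int = 2,
) -> np.ndarray:
    """Project each frame onto the leading eigenvectors.

    Frames are superposed and mean-centred exactly as in
    :func:`build_covariance`; the result is an (F, n_components) array of
    nm-scale displacements along the principal components.
    """
    flat, mean = _fitted_flat(traj, selection, False, None, cut, fit)
    centre = ed.mean if ed.mean is not None else mean
    if flat.shape[1] != ed.eigenvectors.shape[0]:
        raise ValueError(
            f"trajectory dof {flat.shape[1]} does not match eigenvector "
            f"dimension {ed.eigenvectors.shape[0]}"
        )
    n_components = min(n_components, ed.eigenvectors.shape[1])
    return (flat - centre) @ ed.eigenvectors[:, :n_components]


def essential_dynamics_analysis(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    k: int = 10,
    cut: float = 0.0,
    mass_weighted: bool = False,
    masses: np.ndarray | None = None,
    fit: bool = True,
) -> EDResult:
    """Covariance build, diagonalization and 2D projection in one pass,
    guaranteeing that projections use the same superposition and mean as
    the covariance itself."""
    flat, mean = _fitted_flat(traj, selection, mass_weighted, masses, cut, fit)
    centred = flat - mean
    C = (centred.T @ centred) / centred.shape[0]
    ed = principal_components(C, k)
    ed.mean = mean
    ed.projections = centred @ ed.eigenvectors[:, : min(2, ed.eigenvectors.shape[1])]
    return ed


@dataclass
class FESGrid:
    """Binned 2D free-energy surface over two order parameters.

    ``delta_g`` is in kJ/mol with NaN in unvisited bins; ``visited`` marks
    bins with at least one sample.  The most-populated bin has dG = 0.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    delta_g: np.ndarray  # (bins_x, bins_y)
    visited: np.ndarray  # bool, same shape
    temperature: float  # K


def free_energy_surface(
    x_series, y_series, temperature: float = 300.0, bins: int = 32
) -> FESGrid:
    """Boltzmann inversion of the 2D occupancy histogram.

    dG(x, y) = -kB*T*ln(P(x, y) / P_max); bins never visited are flagged
    rather than assigned a value.  Bin edges span the data range with a
    tiny padding so extreme points land inside.
    """
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.shape != y.shape:
        raise ValueError("order-parameter series must have equal length")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    pad = 1e-9
    x_edges = np.linspace(x.min() - pad, x.max() + pad, bins + 1)
    y_edges = np.linspace(y.min() - pad, y.max() + pad, bins + 1)
    counts, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    visited = counts > 0
    p = counts / counts.sum()
    delta_g = np.full_like(p, np.nan)
    p_max = p.max()
    with np.errstate(divide="ignore"):
        delta_g[visited] = -KB_KJ_PER_MOL_K * temperature * np.log(p[visited] / p_max)
    return FESGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        delta_g=delta_g,
        visited=visited,
        temperature=temperature,
    )


_NEIGHBOURS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def _escape_barrier(grid: FESGrid, start: tuple[int, int]) -> float:
    """Minimax path height from ``start`` to any visited bin with lower dG,
    moving through visited bins only; inf if none is reachable."""
    dg = grid.delta_g
    nx, ny = dg.shape
    g0 = dg[start]
    best = np.full((nx, ny), np.inf)
    heap = [(g0, start)]
    best[start] = g0
    while heap:
        level, (i, j) = heapq.heappop(heap)
        if level > best[i, j]:
            continue
        if dg[i, j] < g0:
            return level - g0
        for di, dj in _NEIGHBOURS:
            ni, nj = i + di, j + dj
            if 0 <= ni < nx and 0 <= nj < ny and grid.visited[ni, nj]:
                new_level = max(level, dg[ni, nj])
                if new_level < best[ni, nj]:
                    best[ni, nj] = new_level
                    heapq.heappush(heap, (new_level, (ni, nj)))
    return np.inf


def count_minima(grid: FESGrid, depth_threshold: float | None = None) -> int:
    """Number of metastable basins on the surface.

    A basin is a visited bin that is a strict minimum over its visited
    8-neighbourhood and whose lowest escape barrier (minimax path to any
    lower bin, through visited bins) is at least ``depth_threshold``
    (default 1 kB*T at the grid's temperature).  The global minimum has an
    infinite barrier and always counts.
    """
    if depth_threshold is None:
        depth_threshold = KB_KJ_PER_MOL_K * grid.temperature
    dg = grid.delta_g
    nx, ny = dg.shape
    n = 0
    for i in range(nx):
        for j in range(ny):
            if not grid.visited[i, j]:
                continue
            strict = True
            for di, dj in _NEIGHBOURS:
                ni, nj = i + di, j + dj
                if 0 <= ni < nx and 0 <= nj < ny and grid.visited[ni, nj]:
                    if dg[ni, nj] <= dg[i, j]:
                        strict = False
                        break
            if not strict:
                continue
            if _escape_barrier(grid, (i, j)) >= depth_threshold:
                n += 1
    return n
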