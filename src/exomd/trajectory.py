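"""Trajectory observables computed from first principles.

Optimal rigid-body superposition (Kabsch), RMSD time series, per-residue
RMSF about the time-average structure, radius of gyration, Shrake-Rupley
solvent-accessible surface area, and equilibration-aware summaries
(mean +/- sample SD over the frames after an equilibration cut).

All lengths are nm, times ns, areas nm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domain import Structure, Trajectory

__all__ = [
    "AtomSelection",
    "SeriesSummary",
    "select_backbone",
    "select_all",
    "select_names",
    "kabsch_superpose",
    "apply_rigid",
    "rmsd_series",
    "superpose_to_mean",
    "rmsf_per_residue",
    "rg_series",
    "sasa_structure",
    "sasa_series",
    "summarize_series",
    "sphere_points",
    "BACKBONE_NAMES",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


@dataclass(frozen=True)
class AtomSelection:
    """A resolved set of particle indices of one Structure."""

    indices: np.ndarray  # int array into the particle axis

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.size == 0:
            raise ValueError("empty atom selection")

    def __len__(self) -> int:
        return self.indices.size


def select_backbone(structure: Structure) -> AtomSelection:
    """Protein backbone atoms (names N, CA, C, O)."""
    idx = [i for i, n in enumerate(structure.names) if n in BACKBONE_NAMES]
    if not idx:
        raise ValueError("structure has no backbone atoms (N/CA/C/O)")
    return AtomSelection(np.array(idx))


def select_all(structure: Structure) -> AtomSelection:
    return AtomSelection(np.arange(structure.n_particles))


def select_names(structure: Structure, names) -> AtomSelection:
    wanted = set(names)
    idx = [i for i, n in enumerate(structure.names) if n in wanted]
    if not idx:
        raise ValueError(f"no atoms named {sorted(wanted)}")
    return AtomSelection(np.array(idx))


def _resolve(selection: AtomSelection | None, n: int) -> np.ndarray:
    if selection is None:
        return np.arange(n)
    return selection.indices


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: AtomSelection | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Both are (N, 3) coordinate frames in nm.  The fit is computed on the
    selected atoms.  Returns (rotation, translation, rmsd_after_fit) such
    that ``mobile @ rotation.T + translation`` best matches the reference;
    the rotation is proper (det +1, reflections excluded) and the RMSD is
    the global minimum over all rigid motions.

    Raises for fewer than 3 selected atoms or a collinear selection, for
    which the rotation about the line is undetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = _resolve(selection, mobile.shape[0])
    if idx.size < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    x = mobile[idx]
    y = reference[idx]
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    # Collinearity check: second singular value of either centred cloud ~ 0.
    for cloud in (x0, y0):
        s = np.linalg.svd(cloud, compute_uv=False)
        if s[1] <= 1e-10 * max(s[0], 1e-300):
            raise ValueError("selected atoms are collinear; rotation undetermined")
    h = x0.T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = yc - rotation @ xc
    fitted = x @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_rigid(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ rotation.T + translation


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | None = None,
    selection: AtomSelection | None = None,
) -> np.ndarray:
    """Per-frame RMSD (nm) against a fixed reference frame after optimal
    superposition on the selection.  Default reference: frame 0."""
    ref = traj.coords[0] if reference is None else np.asarray(reference, dtype=float)
    return np.array(
        [kabsch_superpose(frame, ref, selection)[2] for frame in traj.coords]
    )


def superpose_to_mean(
    coords: np.ndarray,
    selection: AtomSelection | None = None,
    max_iter: int = 10,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superpose all frames onto their running average structure.

    Returns (fitted_coords, mean_coords).  Convergence is monitored as the
    displacement of the mean between iterations; a handful of rounds
    suffices in practice.
    """
    coords = np.asarray(coords, dtype=float)
    fitted = coords.copy()
    mean = fitted[0]
    for _ in range(max_iter):
        new_fitted = np.empty_like(coords)
        for f, frame in enumerate(coords):
            rot, trans, _ = kabsch_superpose(frame, mean, selection)
            new_fitted[f] = apply_rigid(frame, rot, trans)
        new_mean = new_fitted.mean(axis=0)
        shift = float(np.max(np.abs(new_mean - mean)))
        fitted, mean = new_fitted, new_mean
        if shift < tol:
            break
    return fitted, mean


def _frames_after_cut(traj: Trajectory, cut: float) -> np.ndarray:
    keep = traj.times >= cut
    return traj.coords[keep]


def rmsf_per_residue(
    traj: Trajectory,
    structure: Structure,
    selection: AtomSelection | None = None,
    cut: float = 0.0,
    fit: bool = True,
):
    """Per-residue RMSF (nm) about the time-average structure.

    Frames with time >= ``cut`` (ns) are retained, superposed onto their
    average (unless ``fit`` is False, useful for analytic tests), and the
    per-atom fluctuation sqrt(<|r_i - <r_i>|^2>) is averaged over each
    residue's selected atoms.  Returns a pandas Series indexed by residue.
    """
    import pandas as pd

    coords = _frames_after_cut(traj, cut)
    if coords.shape[0] < 2:
        raise ValueError("equilibration cut leaves fewer than 2 frames")
    if fit:
        coords, mean = superpose_to_mean(coords, selection)
    else:
        mean = coords.mean(axis=0)
    idx = _resolve(selection, traj.n_particles)
    dev = coords[:, idx, :] - mean[idx]
    per_atom = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    residues = structure.residue_indices[idx]
    series = pd.Series(per_atom).groupby(residues).mean()
    series.index.name = "residue"
    series.name = "rmsf_nm"
    return series


def rg_series(
    traj: Trajectory,
    structure: Structure,
    selection: AtomSelection | None = None,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame radius of gyration (nm) of the selected atoms:
    Rg = sqrt(sum m_i |r_i - r_cm|^2 / sum m_i)."""
    idx = _resolve(selection, traj.n_particles)
    masses = structure.masses[idx] if mass_weighted else np.ones(idx.size)
    total = masses.sum()
    if total <= 0:
        raise ValueError("zero total mass in selection")
    coords = traj.coords[:, idx, :]
    com = (coords * masses[None, :, None]).sum(axis=1) / total
    d2 = np.sum((coords - com[:, None, :]) ** 2, axis=2)
    return np.sqrt((d2 * masses[None, :]).sum(axis=1) / total)


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points by the golden-spiral (Fibonacci)
    construction; deterministic, no RNG."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def sasa_structure(
    structure: Structure,
    coords: np.ndarray | None = None,
    probe: float = 0.14,
    n_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area (nm^2).

    For every particle, ``n_points`` quasi-uniform test points are placed
    on a sphere of radius r_i + probe; a point is buried if it falls inside
    any other particle's probe-expanded sphere.  The particle's area is
    4*pi*(r_i+probe)^2 times its exposed fraction.  Returns
    (total, per-particle array).
    """
    if n_points < 32:
        raise ValueError("n_points < 32 is below the accuracy floor")
    radii = structure.radii
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    xyz = structure.coords if coords is None else np.asarray(coords, dtype=float)
    n = xyz.shape[0]
    unit = sphere_points(n_points)
    expanded = radii + probe
    per_particle = np.empty(n)
    # Pairwise distances once; only probe-overlapping neighbours can bury points.
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    for i in range(n):
        neighbours = np.where((dist[i] < expanded[i] + expanded) & (np.arange(n) != i))[0]
        pts = xyz[i] + expanded[i] * unit
        if neighbours.size:
            d2 = np.sum((pts[:, None, :] - xyz[neighbours][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (expanded[neighbours] ** 2)[None, :], axis=1)
            exposed_fraction = 1.0 - buried.mean()
        else:
            exposed_fraction = 1.0
        per_particle[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed_fraction
    return float(per_particle.sum()), per_particle


def sasa_series(
    traj: Trajectory, structure: Structure, probe: float = 0.14, n_points: int = 960
) -> np.ndarray:
    """Total SASA (nm^2) per frame."""
    return np.array(
        [sasa_structure(structure, frame, probe, n_points)[0] for frame in traj.coords]
    )


@dataclass(frozen=True)
class SeriesSummary:
    """Mean and sample SD (n-1) of an observable over post-equilibration frames."""

    mean: float
    sd: float
    n_frames_used: int
    equilibration_cut: float  # ns


def summarize_series(series, frame_time: float, cut: float = 0.0) -> SeriesSummary:
    """Summarize a per-frame series using only frames with time >= cut (ns)."""
    values = np.asarray(series, dtype=float)
    times = np.arange(values.size) * frame_time
    kept = values[times >= cut]
    if kept.size < 2:
        raise ValueError("equilibration cut leaves fewer than 2 frames")
    return SeriesSummary(
        mean=float(kept.mean()),
        sd=float(kept.std(ddof=1)),
        n_frames_used=int(kept.size),
        equilibration_cut=float(cut),
    )
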