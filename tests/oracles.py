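"""Slow, literal reference implementations kept independent of the package.

These re-derive the same quantities by a different route (numerical
minimization, explicit loops, two-pass formulas) so that agreement with
the package is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def rmsd_fixed(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def brute_force_min_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Global minimum RMSD over rigid motions by multi-start numerical
    minimization over Euler angles (translation handled by centroids)."""
    x0c = mobile - mobile.mean(axis=0)
    y0c = reference - reference.mean(axis=0)

    def objective(angles):
        rot = Rotation.from_euler("xyz", angles).as_matrix()
        return rmsd_fixed(x0c @ rot.T, y0c)

    best = np.inf
    rng = np.random.default_rng(12345)
    starts = [np.zeros(3)] + [rng.uniform(-np.pi, np.pi, 3) for _ in range(20)]
    for start in starts:
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return float(best)


def align_vectors_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via scipy's independent Kabsch solver."""
    x0 = mobile - mobile.mean(axis=0)
    y0 = reference - reference.mean(axis=0)
    _, rssd = Rotation.align_vectors(y0, x0)
    return float(rssd / np.sqrt(len(x0)))


def recount_segregation(matrix, pedigree, max_phenocopies, max_unaffected_carriers):
    """Brute-force carrier recount; returns {variant_id: (ac, anc, uc, passes)}."""
    from exomd.domain import Affection, Carrier

    out = {}
    for vid in matrix.variant_ids:
        ac = anc = uc = 0
        for ind in matrix.individual_ids:
            status = matrix.get(ind, vid)
            if status == Carrier.UNTYPED:
                continue
            aff = pedigree[ind].affection
            if aff == Affection.AFFECTED and status == Carrier.PRESENT:
                ac += 1
            if aff == Affection.AFFECTED and status == Carrier.ABSENT:
                anc += 1
            if aff == Affection.UNAFFECTED and status == Carrier.PRESENT:
                uc += 1
        out[vid] = (ac, anc, uc, anc <= max_phenocopies and uc <= max_unaffected_carriers)
    return out


def two_pass_covariance(flat: np.ndarray) -> np.ndarray:
    """Literal two-pass covariance of an (F, d) configuration matrix."""
    f, d = flat.shape
    mean = np.zeros(d)
    for row in flat:
        mean += row
    mean /= f
    cov = np.zeros((d, d))
    for row in flat:
        dev = row - mean
        cov += np.outer(dev, dev)
    return cov / f
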