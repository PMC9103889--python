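"""Independent brute-force oracles used to cross-check the package.

Everything in this file is deliberately naive (per-point loops, all-pairs
distance checks, a quaternion eigenvalue superposition) and shares no code
path with the implementations it validates.
"""

from __future__ import annotations

import numpy as np


def brute_bin_counts(origin, spacing, shape, points):
    """O(N*V): test each point against every voxel's half-open bounds."""
    counts = np.zeros(shape)
    n_oob = 0
    for p in points:
        placed = False
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    lo = np.asarray(origin) + np.array([i, j, k]) * spacing
                    hi = lo + spacing
                    if np.all(p >= lo) and np.all(p < hi):
                        counts[i, j, k] += 1
                        placed = True
        if not placed:
            n_oob += 1
    return counts, n_oob


def brute_shell_mask(origin, spacing, shape, reference_points, cutoff):
    """O(V*P): exhaustive center-to-reference distance check."""
    member = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                center = np.asarray(origin) + (np.array([i, j, k]) + 0.5) * spacing
                for r in reference_points:
                    if np.linalg.norm(center - np.asarray(r)) <= cutoff:
                        member[i, j, k] = True
                        break
    return member


def brute_residues_within(probe_heavy, residue_heavy_sets, cutoff):
    """All-pairs heavy-atom distances; returns indices of passing residues."""
    selected = []
    for idx, res_coords in enumerate(residue_heavy_sets):
        hit = False
        for a in res_coords:
            for b in probe_heavy:
                if np.linalg.norm(np.asarray(a) - np.asarray(b)) <= cutoff:
                    hit = True
                    break
            if hit:
                break
        if hit:
            selected.append(idx)
    return selected


def brute_on_surface(probe_heavy, member, origin, spacing):
    """Per-atom voxel lookup against the membership array."""
    shape = member.shape
    for p in probe_heavy:
        idx = np.floor((np.asarray(p) - np.asarray(origin)) / spacing).astype(int)
        if np.all(idx >= 0) and np.all(idx < np.array(shape)):
            if member[tuple(idx)]:
                return True
    return False


def brute_displacements(centroids, n_lag, box=None):
    """Two-pointer loop over the centroid series with minimum-image wrap."""
    out = []
    for t in range(n_lag, len(centroids)):
        d = np.asarray(centroids[t]) - np.asarray(centroids[t - n_lag])
        if box is not None:
            for ax in range(3):
                d[ax] -= box[ax] * round(d[ax] / box[ax])
        out.append(float(np.linalg.norm(d)))
    return np.array(out)


def horn_superpose(mobile, reference):
    """Quaternion (Horn 1987) closed-form superposition; proper rotation.

    Returns (rotation_matrix, translation, rmsd) mapping mobile onto
    reference.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    cm_m = mob.mean(axis=0)
    cm_r = ref.mean(axis=0)
    a = mob - cm_m
    b = ref - cm_r
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(key)
    q = eigvecs[:, -1]  # w, x, y, z
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    translation = cm_r - rot @ cm_m
    fitted = a @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))
    return rot, translation, rmsd
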