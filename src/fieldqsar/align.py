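"""Rigid common-skeleton superposition onto a template conformer.

Every compound in a field-based QSAR study must sit in one common frame
before the lattice is sampled, so each conformer's shared scaffold is fitted
onto the scaffold of a template compound (the most active one, by
convention) with a proper rigid rotation.  The optimal rotation is found by
the Kabsch SVD construction with a reflection guard: an improper rotation is
never returned, even for near-mirror point sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

__all__ = ["RigidTransform", "AtomCorrespondence", "kabsch_superpose", "align_to_template"]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ x + t with R a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection) is not a rigid pose")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class AtomCorrespondence:
    """Ordered (template_atom_index, target_atom_index) pairs, 0-based."""

    pairs: tuple

    def __init__(self, pairs: Sequence[Tuple[int, int]]):
        pairs = tuple((int(a), int(b)) for a, b in pairs)
        if len(pairs) < 3:
            raise ValueError("need at least 3 atom pairs to define a rigid pose")
        for side in (0, 1):
            idx = [p[side] for p in pairs]
            if len(set(idx)) != len(idx):
                raise ValueError("duplicate atom indices in correspondence")
            if min(idx) < 0:
                raise ValueError("negative atom index in correspondence")
        object.__setattr__(self, "pairs", pairs)

    @classmethod
    def identity(cls, n: int) -> "AtomCorrespondence":
        return cls([(i, i) for i in range(n)])

    def template_indices(self):
        return [p[0] for p in self.pairs]

    def target_indices(self):
        return [p[1] for p in self.pairs]


def _check_point_set(X: np.ndarray, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array")
    if X.shape[0] < 3:
        raise ValueError(f"{name}: need at least 3 points, got {X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name}: non-finite coordinates")
    return X


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> Tuple[RigidTransform, float]:
    """Least-RMSD proper rigid transform taking point set ``Q`` onto ``P``.

    Returns the transform and the residual RMSD (Å).  Degenerate sets —
    coincident or collinear points, which leave a rotation axis undetermined —
    are rejected.
    """
    P = _check_point_set(P, "P")
    Q = _check_point_set(Q, "Q")
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in size: {P.shape[0]} vs {Q.shape[0]}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinear/coincident sets have covariance rank < 2
    for X, name in ((Pc, "P"), (Qc, "Q")):
        s = np.linalg.svd(X, compute_uv=False)
        scale = max(s[0], 1.0)
        if np.sum(s > 1e-9 * scale) < 2:
            raise ValueError(f"{name} is degenerate (coincident or collinear points)")
    H = Qc.T @ Pc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = P.mean(axis=0) - R @ Q.mean(axis=0)
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(Q) - P) ** 2, axis=1))))
    return transform, rmsd


def align_to_template(target, template, correspondence: AtomCorrespondence = None):
    """Superpose ``target``'s skeleton onto ``template``'s and move all atoms.

    Without an explicit correspondence, both structures' own
    ``skeleton_atom_indices`` are paired in order.  Returns a new structure;
    the input is untouched.  The achieved skeleton RMSD is stored on the
    result as ``alignment_rmsd``.
    """
    if correspondence is None:
        ti = template.skeleton_atom_indices
        gi = target.skeleton_atom_indices
        if len(ti) != len(gi):
            raise ValueError(
                f"skeleton size mismatch: template {len(ti)} vs target {len(gi)}"
            )
        correspondence = AtomCorrespondence(list(zip(ti, gi)))
    tmpl_idx = correspondence.template_indices()
    targ_idx = correspondence.target_indices()
    if max(tmpl_idx) >= template.n_atoms:
        raise ValueError("correspondence template index out of range")
    if max(targ_idx) >= target.n_atoms:
        raise ValueError("correspondence target index out of range")
    transform, rmsd = kabsch_superpose(template.coords[tmpl_idx], target.coords[targ_idx])
    aligned = target.with_coords(transform.apply(target.coords))
    aligned.alignment_rmsd = rmsd
    return aligned
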