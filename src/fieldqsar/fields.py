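"""Molecular interaction fields on a rectangular lattice.

Two families of descriptors are computed for aligned conformers:

* CoMFA-type probe energies — a Lennard-Jones 6-12 steric term and a
  Coulomb electrostatic term evaluated by an sp3-carbon probe (vdW radius
  1.52 Å, charge +1 e) at every lattice node, truncated at an energy cutoff
  (default 30 kcal/mol).
* CoMSIA-type similarity indices — Gaussian-attenuated overlap
  ``A(p) = -sum_i w_probe * w_i * exp(-alpha * r_i^2)`` for steric,
  electrostatic, hydrophobic, H-bond donor and acceptor properties, with
  attenuation alpha = 0.3 Å^-2 and no cutoff (the Gaussian decays smoothly).

:func:`assemble_descriptor_matrix` stacks the per-compound fields into the
compounds × columns matrix PLS consumes, masking near-constant columns and
substituting the training-column mean for electrostatic values at sterically
buried nodes (where the hard-core clamp would otherwise leak the arbitrary
cutoff value into the regression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "GridSpec",
    "ProbeSpec",
    "FieldParams",
    "FieldBlock",
    "build_grid",
    "comfa_steric_field",
    "comfa_electrostatic_field",
    "comsia_field",
    "assemble_descriptor_matrix",
    "export_dx",
]

COMSIA_KINDS = ("S", "E", "H", "A", "D")

# Coulomb conversion in kcal·Å/(mol·e²)
COULOMB_KCAL = 332.0636


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned cubic lattice: origin plus shape nodes at fixed spacing."""

    origin: tuple
    spacing: float
    shape: tuple

    def __post_init__(self):
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if len(self.origin) != 3 or len(self.shape) != 3:
            raise ValueError("origin and shape must be 3-vectors")
        if any(n < 2 for n in self.shape):
            raise ValueError("grid must have at least 2 nodes per axis")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) * self.spacing

    def points(self) -> np.ndarray:
        """All lattice nodes, z varying fastest, then y, then x."""
        axes = [
            self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def contains(self, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        lo = np.asarray(self.origin) - tol
        hi = self.upper + tol
        return np.all((pts >= lo) & (pts <= hi), axis=1)


@dataclass(frozen=True)
class ProbeSpec:
    """The probe atom: sp3 carbon of radius 1.52 Å carrying +1 e; unit
    weights for the similarity properties."""

    vdw_radius: float = 1.52
    charge: float = 1.0
    steric_epsilon: float = 0.107  # kcal/mol LJ well depth
    steric_weight: float = 1.0
    electrostatic_weight: float = 1.0
    hydrophobic_weight: float = 1.0
    donor_weight: float = 1.0
    acceptor_weight: float = 1.0

    def __post_init__(self):
        if self.vdw_radius <= 0:
            raise ValueError("probe vdW radius must be positive")


@dataclass(frozen=True)
class FieldParams:
    """Numerical knobs of the field evaluation.

    ``energy_cutoff``: CoMFA truncation, kcal/mol.
    ``attenuation_alpha``: CoMSIA Gaussian exponent, Å^-2.
    ``atom_epsilon``: LJ well depth assumed per atom (combined with the probe
    well depth by the geometric rule).
    ``dielectric_model``: 'distance_dependent' (eps = r, the SYBYL
    convention) or 'constant' (eps = dielectric_constant).
    """

    energy_cutoff: float = 30.0
    attenuation_alpha: float = 0.3
    coulomb_constant: float = COULOMB_KCAL
    atom_epsilon: float = 0.107
    dielectric_model: str = "distance_dependent"
    dielectric_constant: float = 1.0

    def __post_init__(self):
        if self.energy_cutoff <= 0:
            raise ValueError("energy cutoff must be positive")
        if self.attenuation_alpha <= 0:
            raise ValueError("attenuation factor must be positive")
        if self.dielectric_model not in ("distance_dependent", "constant"):
            raise ValueError(f"unknown dielectric model {self.dielectric_model!r}")


def build_grid(structures, spacing: float = 2.0, margin: float = 4.0) -> GridSpec:
    """Smallest lattice of the given spacing whose closed bounds cover every
    atom of every structure plus ``margin`` Å, with the origin snapped down
    to a multiple of the spacing."""
    structures = list(structures)
    if not structures:
        raise ValueError("cannot build a grid from zero structures")
    coords = np.vstack([s.coords for s in structures])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    origin = np.floor(lo / spacing + 1e-9) * spacing
    shape = np.ceil((hi - origin) / spacing - 1e-9).astype(int) + 1
    shape = np.maximum(shape, 2)
    return GridSpec(origin=tuple(origin), spacing=float(spacing), shape=tuple(shape))


def _distances(structure, grid: GridSpec) -> np.ndarray:
    return cdist(grid.points(), structure.coords)


def comfa_steric_field(
    structure,
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    params: FieldParams = FieldParams(),
) -> np.ndarray:
    """Lennard-Jones 6-12 probe energy at every node, clamped to the cutoff.

    ``E(p) = sum_i eps_i [ (R_i/r_i)^12 - 2 (R_i/r_i)^6 ]`` with
    ``R_i = r_vdw,i + r_probe`` and ``eps_i = sqrt(eps_atom * eps_probe)``;
    the minimum of this form is exactly ``-eps_i`` at ``r = R_i``.  A node
    inside an atom (including a node coinciding with it) takes the +cutoff
    clamp value.
    """
    if structure.n_atoms == 0:
        return np.zeros(grid.n_points)
    r = _distances(structure, grid)
    R = structure.vdw_radii + probe.vdw_radius
    eps = np.sqrt(params.atom_epsilon * probe.steric_epsilon)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ratio6 = (R[None, :] / r) ** 6
        e = eps * (ratio6 * ratio6 - 2.0 * ratio6)
        e = np.where(np.isfinite(e), e, np.inf)
    total = e.sum(axis=1)
    return np.clip(total, -params.energy_cutoff, params.energy_cutoff)


def steric_buried_mask(
    structure,
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    params: FieldParams = FieldParams(),
) -> np.ndarray:
    """Nodes where the steric energy sits at the +cutoff clamp."""
    if structure.n_atoms == 0:
        return np.zeros(grid.n_points, dtype=bool)
    e = comfa_steric_field(structure, grid, probe, params)
    return e >= params.energy_cutoff - 1e-12


def comfa_electrostatic_field(
    structure,
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    params: FieldParams = FieldParams(),
) -> np.ndarray:
    """Coulomb probe energy ``sum_i k q_i q_probe / (eps(r) r)`` per node,
    clamped to ±cutoff.  With the distance-dependent dielectric eps(r) = r
    this is the familiar 1/r² form."""
    if structure.n_atoms == 0:
        return np.zeros(grid.n_points)
    if not np.all(np.isfinite(structure.partial_charges)):
        raise ValueError(f"{structure.compound_id}: non-finite partial charges")
    r = _distances(structure, grid)
    q = structure.partial_charges
    with np.errstate(divide="ignore", invalid="ignore"):
        if params.dielectric_model == "distance_dependent":
            e = params.coulomb_constant * probe.charge * q[None, :] / (r * r)
        else:
            e = params.coulomb_constant * probe.charge * q[None, :] / (
                params.dielectric_constant * r
            )
    # r = 0 with q = 0 yields 0/0; an uncharged coincident atom contributes nothing
    e = np.where(np.isnan(e), 0.0, e)
    total = e.sum(axis=1)
    # opposing infinities at one node (coincident +/- charges) clamp to zero
    total = np.where(np.isnan(total), 0.0, total)
    return np.clip(total, -params.energy_cutoff, params.energy_cutoff)


def _comsia_weights(structure, kind: str, probe: ProbeSpec):
    if kind == "S":
        return structure.steric_weights(), probe.steric_weight
    if kind == "E":
        return structure.partial_charges, probe.electrostatic_weight
    if kind == "H":
        return structure.hydrophobic, probe.hydrophobic_weight
    if kind == "D":
        return structure.is_donor.astype(float), probe.donor_weight
    if kind == "A":
        return structure.is_acceptor.astype(float), probe.acceptor_weight
    raise ValueError(f"unknown similarity field kind {kind!r} (expected one of {COMSIA_KINDS})")


def comsia_field(
    structure,
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    params: FieldParams = FieldParams(),
    kind: str = "S",
) -> np.ndarray:
    """Gaussian similarity index ``A(p) = -sum_i w_probe w_i exp(-alpha r_i^2)``.

    No cutoff is applied; the Gaussian keeps every value finite.  For
    unit-positive weights the values are ≤ 0 by construction.
    """
    w_atoms, w_probe = _comsia_weights(structure, kind, probe)
    if structure.n_atoms == 0:
        return np.zeros(grid.n_points)
    r = _distances(structure, grid)
    g = np.exp(-params.attenuation_alpha * r * r)
    return -(w_probe * (g * w_atoms[None, :]).sum(axis=1))


@dataclass
class FieldBlock:
    """Compounds × lattice-nodes × field-kinds descriptor tensor.

    ``kinds`` is an ordered list of ``(family, letter)`` pairs such as
    ``("comfa", "S")``.  The flattened design matrix orders columns with the
    lattice z index fastest, then y, then x, then kind; ``column_mask`` marks
    the columns that survived the minimum-sigma filter.
    """

    grid: GridSpec
    kinds: list
    compound_ids: list
    values: np.ndarray  # (n_compounds, n_kinds, n_points), post-processing
    column_mask: np.ndarray  # (n_kinds * n_points,)
    kind_scale: dict  # block-scaling divisor actually applied per kind
    filtering_sigma: float

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1] * self.values.shape[2]

    def full_matrix(self) -> np.ndarray:
        return self.values.reshape(self.n_compounds, -1)

    def matrix(self) -> np.ndarray:
        """Design matrix restricted to retained columns."""
        return self.full_matrix()[:, self.column_mask]

    def column_meta(self, masked: bool = True) -> pd.DataFrame:
        pts = self.grid.points()
        frames = []
        for family, letter in self.kinds:
            frames.append(
                pd.DataFrame(
                    {
                        "family": family,
                        "kind": letter,
                        "x": pts[:, 0],
                        "y": pts[:, 1],
                        "z": pts[:, 2],
                    }
                )
            )
        meta = pd.concat(frames, ignore_index=True)
        meta["kept"] = self.column_mask
        if masked:
            meta = meta[meta["kept"]].reset_index(drop=True)
        return meta

    def kind_labels(self) -> np.ndarray:
        """Per-column '<family>:<letter>' label, full (unmasked) order."""
        labels = []
        for family, letter in self.kinds:
            labels.extend([f"{family}:{letter}"] * self.grid.n_points)
        return np.asarray(labels)

    def to_csv(self, path) -> None:
        meta = self.column_meta(masked=True)
        X = self.matrix()
        df = pd.DataFrame(X.T, columns=self.compound_ids)
        out = pd.concat([meta[["family", "kind", "x", "y", "z"]], df], axis=1)
        out.to_csv(path, index=False)


def _parse_kinds(comfa: str = "", comsia: str = "") -> list:
    kinds = [("comfa", k) for k in comfa.upper()] + [("comsia", k) for k in comsia.upper()]
    for family, k in kinds:
        if family == "comfa" and k not in ("S", "E"):
            raise ValueError(f"CoMFA kind must be S or E, got {k!r}")
        if family == "comsia" and k not in COMSIA_KINDS:
            raise ValueError(f"CoMSIA kind must be one of {COMSIA_KINDS}, got {k!r}")
    if not kinds:
        raise ValueError("no field kinds requested")
    return kinds


def assemble_descriptor_matrix(
    structures,
    comfa_kinds: str = "SE",
    comsia_kinds: str = "",
    grid: Optional[GridSpec] = None,
    spacing: float = 2.0,
    margin: float = 4.0,
    probe: ProbeSpec = ProbeSpec(),
    params: FieldParams = FieldParams(),
    filtering_sigma: float = 2.0,
    block_scaling: bool = False,
    train_mask: Optional[np.ndarray] = None,
) -> FieldBlock:
    """Compute all requested fields on a common grid and assemble the design
    tensor.

    ``filtering_sigma`` masks columns whose standard deviation across the
    *training* compounds (all compounds when ``train_mask`` is None) falls
    below the threshold; 0 disables filtering.  ``block_scaling`` applies the
    CoMFA-STD convention, dividing each field-kind block by its RMS column
    standard deviation so every kind enters with equal total variance.
    Electrostatic CoMFA values at sterically buried nodes are replaced by the
    training-column mean over unburied compounds.
    """
    structures = list(structures)
    if not structures:
        raise ValueError("no structures given")
    kinds = _parse_kinds(comfa_kinds, comsia_kinds)
    if grid is None:
        grid = build_grid(structures, spacing=spacing, margin=margin)
    else:
        all_coords = np.vstack([s.coords for s in structures])
        if not np.all(grid.contains(all_coords)):
            warnings.warn("some atoms fall outside the supplied grid", stacklevel=2)
    n = len(structures)
    if train_mask is None:
        train_mask = np.ones(n, dtype=bool)
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.shape != (n,):
        raise ValueError("train_mask length must match number of structures")

    npts = grid.n_points
    values = np.zeros((n, len(kinds), npts))
    buried = None
    if ("comfa", "E") in kinds:
        buried = np.zeros((n, npts), dtype=bool)
    for i, s in enumerate(structures):
        for j, (family, letter) in enumerate(kinds):
            if family == "comfa" and letter == "S":
                values[i, j] = comfa_steric_field(s, grid, probe, params)
            elif family == "comfa" and letter == "E":
                values[i, j] = comfa_electrostatic_field(s, grid, probe, params)
            else:
                values[i, j] = comsia_field(s, grid, probe, params, kind=letter)
        if buried is not None:
            buried[i] = steric_buried_mask(s, grid, probe, params)

    # electrostatic burial: replace clamp artefacts with the column mean of
    # the unburied training compounds (zero when every one is buried)
    if buried is not None:
        j = kinds.index(("comfa", "E"))
        col = values[:, j, :]
        ok = (~buried) & train_mask[:, None]
        counts = ok.sum(axis=0)
        sums = np.where(ok, col, 0.0).sum(axis=0)
        col_mean = np.divide(sums, counts, out=np.zeros(npts), where=counts > 0)
        values[:, j, :] = np.where(buried, col_mean[None, :], col)

    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite field values after assembly")

    # minimum-sigma column filter on the training rows
    stds = values[train_mask].std(axis=0, ddof=0)  # (n_kinds, npts)
    if filtering_sigma > 0:
        mask = stds >= filtering_sigma
    else:
        mask = np.ones_like(stds, dtype=bool)

    kind_scale = {}
    if block_scaling:
        for j, key in enumerate(kinds):
            kept = mask[j]
            block_std = np.sqrt(np.mean(stds[j, kept] ** 2)) if kept.any() else 0.0
            scale = block_std if block_std > 0 else 1.0
            values[:, j, :] = values[:, j, :] / scale
            kind_scale[key] = float(scale)
    else:
        kind_scale = {key: 1.0 for key in kinds}

    return FieldBlock(
        grid=grid,
        kinds=kinds,
        compound_ids=[s.compound_id for s in structures],
        values=values,
        column_mask=mask.reshape(-1),
        kind_scale=kind_scale,
        filtering_sigma=filtering_sigma,
    )


def export_dx(grid: GridSpec, point_values: np.ndarray, path) -> None:
    """Write one scalar field (length n_points, z-fastest order) as OpenDX."""
    from gridData import Grid

    vals = np.asarray(point_values, dtype=float).reshape(grid.shape)
    g = Grid(vals, origin=np.asarray(grid.origin), delta=[grid.spacing] * 3)
    g.export(str(path), file_format="dx")
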