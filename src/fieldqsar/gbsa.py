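"""MM/GBSA binding free-energy bookkeeping.

The simulation engines that produce per-complex energy components are out of
scope here; this module only aggregates and audits their output:

    dE_gas  = dE_vdw + dE_ele
    dG_sol  = dG_GB  + dG_SA
    dG_bind = dE_gas + dG_sol - T*dS        (T*dS usually omitted)

and checks that the resulting binding free energies rank the complexes the
same way the measured activities do (more negative dG_bind should pair with
higher pIC50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "EnergyComponents",
    "BindingEnergyRecord",
    "aggregate",
    "read_component_table",
    "rank_agreement",
]

_IDENTITY_TOL = 1e-3

# column aliases accepted in delimited component tables
_ALIASES = {
    "complex_id": ("complex_id", "no", "no.", "id", "complex"),
    "dE_ele": ("de_ele", "dele", "delta_e_ele", "e_ele", "ele"),
    "dE_vdw": ("de_vdw", "devdw", "delta_e_vdw", "e_vdw", "vdw"),
    "dG_gb": ("dg_gb", "dggb", "gb", "g_gb"),
    "dG_sa": ("dg_sa", "dgsa", "sa", "g_sa"),
    "t_dS": ("t_ds", "tds", "tdeltas"),
    "pic50": ("pic50",),
}


@dataclass(frozen=True)
class EnergyComponents:
    """Per-complex energy components, kcal/mol."""

    complex_id: str
    dE_ele: float
    dE_vdw: float
    dG_gb: float
    dG_sa: float
    t_dS: Optional[float] = None
    pic50: Optional[float] = None
    raw_complex: Optional[float] = None
    raw_protein: Optional[float] = None
    raw_ligand: Optional[float] = None

    def __post_init__(self):
        for name in ("dE_ele", "dE_vdw", "dG_gb", "dG_sa"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"{self.complex_id}: missing or non-finite {name}")


@dataclass(frozen=True)
class BindingEnergyRecord:
    """Aggregated terms; all in kcal/mol."""

    complex_id: str
    dE_gas: float
    dG_sol: float
    dG_bind: float
    pic50: Optional[float] = None


def aggregate(ec: EnergyComponents) -> BindingEnergyRecord:
    """Sum the component terms into gas-phase, solvation, and binding energy.

    The entropic term is subtracted when present and taken as zero otherwise.
    If raw per-species totals are supplied, the thermodynamic-cycle identity
    ``raw_complex - raw_protein - raw_ligand == dG_bind`` is enforced to
    1e-3 kcal/mol.
    """
    dE_gas = ec.dE_vdw + ec.dE_ele
    dG_sol = ec.dG_gb + ec.dG_sa
    t_ds = ec.t_dS if ec.t_dS is not None else 0.0
    dG_bind = dE_gas + dG_sol - t_ds
    if all(v is not None for v in (ec.raw_complex, ec.raw_protein, ec.raw_ligand)):
        raw = ec.raw_complex - (ec.raw_protein + ec.raw_ligand)
        if abs(raw - dG_bind) > _IDENTITY_TOL:
            raise ValueError(
                f"{ec.complex_id}: per-species totals give dG_bind {raw:.4f}, "
                f"components give {dG_bind:.4f}"
            )
    return BindingEnergyRecord(
        complex_id=ec.complex_id,
        dE_gas=dE_gas,
        dG_sol=dG_sol,
        dG_bind=dG_bind,
        pic50=ec.pic50,
    )


def _normalise(text: str) -> str:
    return (
        text.replace("−", "-")  # Unicode minus
        .replace("–", "-")
        .strip()
        .lower()
        .replace(" ", "")
    )


def read_component_table(path) -> List[EnergyComponents]:
    """Read a delimited (comma/tab) MM/GBSA component table.

    Header names are matched case-insensitively against common aliases;
    Unicode minus signs in numbers are accepted.  A row with an unparseable
    number raises with its line number.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.empty and len(df.columns) == 0:
        return []
    colmap = {}
    for canonical, names in _ALIASES.items():
        for c in df.columns:
            if _normalise(c) in names:
                colmap[canonical] = c
                break
    required = ("complex_id", "dE_ele", "dE_vdw", "dG_gb", "dG_sa")
    missing = [r for r in required if r not in colmap]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for pos, (_, row) in enumerate(df.iterrows()):
        line_no = pos + 2  # header is line 1

        def num(canonical, optional=False):
            if canonical not in colmap:
                return None
            raw = row[colmap[canonical]]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                return None
            try:
                return float(_normalise(str(raw)))
            except ValueError:
                raise ValueError(
                    f"{path}:{line_no}: cannot parse {canonical} value {raw!r}"
                ) from None

        out.append(
            EnergyComponents(
                complex_id=str(row[colmap["complex_id"]]),
                dE_ele=num("dE_ele"),
                dE_vdw=num("dE_vdw"),
                dG_gb=num("dG_gb"),
                dG_sa=num("dG_sa"),
                t_dS=num("t_dS", optional=True),
                pic50=num("pic50", optional=True),
            )
        )
    return out


def rank_agreement(records: List[BindingEnergyRecord]):
    """Compare the binding-energy ranking with the activity ranking.

    Complexes are ranked by ascending dG_bind (most negative = strongest
    binder first) and by descending pIC50; ties break on complex_id.
    Returns ``(energy_order, activity_order, concordant, spearman_rho)``
    where the orders are lists of complex ids and rho is the Spearman
    correlation between the two rankings.
    """
    recs = [r for r in records if r.pic50 is not None]
    if len(recs) < 3:
        raise ValueError("rank agreement needs at least 3 records with pIC50")
    energy_order = [r.complex_id for r in sorted(recs, key=lambda r: (r.dG_bind, r.complex_id))]
    activity_order = [r.complex_id for r in sorted(recs, key=lambda r: (-r.pic50, r.complex_id))]
    concordant = energy_order == activity_order
    e_rank = {cid: i for i, cid in enumerate(energy_order)}
    a_rank = {cid: i for i, cid in enumerate(activity_order)}
    ids = [r.complex_id for r in recs]
    rho = float(spearmanr([e_rank[c] for c in ids], [a_rank[c] for c in ids]).statistic)
    return energy_order, activity_order, concordant, rho
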