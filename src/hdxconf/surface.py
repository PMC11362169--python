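"""Solvent-accessible surface areas, buried interfaces, and contacts.

SASA is computed with the Shrake–Rupley sphere-sampling algorithm
(biotite's implementation, 1000 sample points per atom by default) using
the ProtOr heavy-atom van-der-Waals radius set; atoms without a ProtOr
radius fall back to 1.80 Å with a warning.  Hydrogens are ignored
throughout (crystal structures lack them).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .structure import ResidueSelection, StructureModel

__all__ = ["sasa", "buried_surface_area", "contact_residues"]

FALLBACK_RADIUS = 1.80  # Å, applied when no ProtOr radius is tabulated
DEFAULT_POINTS = 1000


def _to_atom_array(structure: StructureModel):
    import biotite.structure as bst

    n = len(structure)
    arr = bst.AtomArray(n)
    df = structure.atoms
    arr.coord = structure.coords.astype(np.float32)
    arr.chain_id = df["chain"].to_numpy(str)
    arr.res_id = df["resnum"].to_numpy(int)
    arr.res_name = df["resname"].to_numpy(str)
    arr.atom_name = df["atom"].to_numpy(str)
    arr.element = df["element"].to_numpy(str)
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def _radii(structure: StructureModel) -> np.ndarray:
    from biotite.structure.info import vdw_radius_protor

    radii = np.empty(len(structure))
    missing = []
    for i, row in enumerate(structure.atoms.itertuples(index=False)):
        try:
            r = vdw_radius_protor(row.resname, row.atom)
        except (KeyError, ValueError):
            r = None
        if r is None:
            missing.append((row.resname, row.atom))
            r = FALLBACK_RADIUS
        radii[i] = r
    if missing:
        uniq = sorted(set(missing))[:8]
        warnings.warn(
            f"no ProtOr vdW radius for {len(missing)} atoms (e.g. {uniq}); "
            f"using fallback {FALLBACK_RADIUS} Å", stacklevel=3)
    return radii


def sasa(structure: StructureModel, probe: float = 1.4,
         point_number: int = DEFAULT_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area in Å²."""
    import biotite.structure as bst

    arr = _to_atom_array(structure)
    values = bst.sasa(arr, probe_radius=probe, point_number=point_number,
                      vdw_radii=_radii(structure))
    return np.nan_to_num(values, nan=0.0)


def buried_surface_area(complex_structure: StructureModel,
                        side_a_chains, side_b_chains,
                        probe: float = 1.4,
                        point_number: int = DEFAULT_POINTS):
    """Interface area buried on each side of a two-body complex.

    For each side ``x``, ``area_x = SASA(x alone) − SASA(x in complex)``,
    i.e. the surface of that side's chains occluded by the partner.
    Returns ``(area_a, area_b)`` in Å².  The two chain sets must be
    non-empty and disjoint; chains outside both sets are ignored.
    """
    side_a = set(side_a_chains)
    side_b = set(side_b_chains)
    if not side_a or not side_b:
        raise ValueError("both chain sets must be non-empty")
    if side_a & side_b:
        raise ValueError(f"chain sets overlap: {sorted(side_a & side_b)}")
    present = set(complex_structure.chains)
    for side in (side_a, side_b):
        absent = side - present
        if absent:
            raise ValueError(f"chains not in structure: {sorted(absent)}")

    both = complex_structure.select_chains(side_a | side_b)
    sasa_complex = sasa(both, probe=probe, point_number=point_number)
    in_a = both.atoms["chain"].isin(side_a).to_numpy()

    areas = []
    for mask in (in_a, ~in_a):
        alone = both.subset(mask)
        sasa_alone = sasa(alone, probe=probe, point_number=point_number)
        areas.append(float(sasa_alone.sum() - sasa_complex[mask].sum()))
    return areas[0], areas[1]


def contact_residues(complex_structure: StructureModel,
                     query_chains, target_chains,
                     cutoff: float = 4.0) -> ResidueSelection | None:
    """Residues of ``target_chains`` with any heavy atom within ``cutoff``
    Å of any heavy atom of ``query_chains``.

    Returns a :class:`ResidueSelection` (all atoms, single-residue ranges)
    or None when there are no contacts; empty chain sets give None rather
    than an error.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    query = complex_structure.atoms[complex_structure.atoms["chain"].isin(set(query_chains))]
    target = complex_structure.atoms[complex_structure.atoms["chain"].isin(set(target_chains))]
    if query.empty or target.empty:
        return None
    tree = cKDTree(query[["x", "y", "z"]].to_numpy(float))
    dist, _ = tree.query(target[["x", "y", "z"]].to_numpy(float),
                         distance_upper_bound=cutoff)
    hit = dist <= cutoff
    if not hit.any():
        return None
    residues = target[hit][["chain", "resnum"]]
    keys = sorted(set(map(tuple, residues.to_numpy())))
    ranges = tuple((chain, int(rn), int(rn)) for chain, rn in keys)
    return ResidueSelection(ranges, atoms=None)
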