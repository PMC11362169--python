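"""Rigid-body and backbone geometry of conformational change.

This module quantifies how one transporter conformation differs from
another: per-residue backbone dihedral changes localise hinges, Kabsch
superposition of domain selections yields rigid-body transforms and RMSDs,
the screw (Chasles) decomposition of such a transform exposes the rotation
axis and angle of the mobile domain, helix-axis fits give inter-helix
angles, and site displacement measures how far a set of residues (e.g. a
substrate binding site) travels between conformations after aligning on a
static domain.

Angle conventions: dihedrals and rotation angles are reported in degrees;
dihedrals live on (−180, 180]; wrapped absolute differences live on
[0, 180].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import ResidueSelection, StructureModel

__all__ = [
    "RigidTransform",
    "ScrewAxis",
    "HelixAxis",
    "dihedral_angle",
    "compute_dihedrals",
    "dihedral_difference",
    "wrap_angle",
    "superpose",
    "screw_decompose",
    "screw_compose",
    "helix_axis",
    "inter_helix_angle",
    "site_displacement",
]


def wrap_angle(deg):
    """Wrap angle(s) in degrees onto (−180, 180]."""
    wrapped = np.mod(np.asarray(deg, float) + 180.0, 360.0) - 180.0
    # mod puts -180 at -180; convention places it at +180
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return wrapped if np.ndim(deg) else float(wrapped)


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion angle (degrees) of four points, IUPAC sign convention."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = n1 @ n2
    y = np.cross(n1, n2) @ (b1 / np.linalg.norm(b1))
    return float(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# dihedral series
# ---------------------------------------------------------------------------

def compute_dihedrals(structure: StructureModel,
                      selection: ResidueSelection | None = None) -> pd.DataFrame:
    """Backbone φ/ψ per residue.

    Returns a DataFrame indexed by ``(chain, resnum)`` with float columns
    ``phi`` and ``psi`` in degrees on (−180, 180].  Angles that are
    undefined — chain termini, or a missing backbone atom in the residue or
    its neighbour — are NaN and flagged in the boolean columns
    ``phi_defined`` / ``psi_defined``; they are never zero-filled.
    """
    df = structure.atoms
    bb = df[df["atom"].isin(["N", "CA", "C"])]
    coords: dict[tuple[str, int, str], np.ndarray] = {
        (r.chain, r.resnum, r.atom): np.array([r.x, r.y, r.z])
        for r in bb.itertuples(index=False)
    }
    if selection is not None:
        keys = [k for k in selection.residue_keys()
                if any((k[0], k[1], a) in coords for a in ("N", "CA", "C"))]
        # a selection that resolves to nothing is a user error
        if not keys:
            raise ValueError("dihedral selection matches no residues")
    else:
        keys = list(dict.fromkeys((r.chain, r.resnum) for r in bb.itertuples(index=False)))

    rows = []
    for chain, resnum in keys:
        def get(rn, atom):
            return coords.get((chain, rn, atom))

        n, ca, c = get(resnum, "N"), get(resnum, "CA"), get(resnum, "C")
        c_prev = get(resnum - 1, "C")
        n_next = get(resnum + 1, "N")
        phi = psi = np.nan
        if all(p is not None for p in (c_prev, n, ca, c)):
            phi = dihedral_angle(c_prev, n, ca, c)
        if all(p is not None for p in (n, ca, c, n_next)):
            psi = dihedral_angle(n, ca, c, n_next)
        rows.append((chain, resnum, phi, psi, not np.isnan(phi), not np.isnan(psi)))

    out = pd.DataFrame(rows, columns=["chain", "resnum", "phi", "psi",
                                      "phi_defined", "psi_defined"])
    return out.set_index(["chain", "resnum"])


def dihedral_difference(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Wrapped absolute φ/ψ differences |Δφ|, |Δψ| ∈ [0, 180] per residue.

    Both inputs must come from :func:`compute_dihedrals` and share the same
    residue keys; a mismatch is an error that lists the offending residues.
    Residues where either series is undefined get NaN differences.
    """
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise ValueError(
            "residue keys differ between series; "
            f"only in first: {list(only_a)[:10]}, only in second: {list(only_b)[:10]}"
        )
    b = b.loc[a.index]
    out = pd.DataFrame(index=a.index)
    for ang in ("phi", "psi"):
        delta = np.abs(wrap_angle(a[ang].to_numpy() - b[ang].to_numpy()))
        defined = a[f"{ang}_defined"].to_numpy() & b[f"{ang}_defined"].to_numpy()
        out[f"d{ang}"] = np.where(defined, delta, np.nan)
        out[f"d{ang}_defined"] = defined
    return out


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x ↦ R x + t`` (rotation matrix + translation, Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has det = -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, float).reshape(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @property
    def screw(self) -> "ScrewAxis":
        return screw_decompose(self)


def _paired_coords(mobile: StructureModel, reference: StructureModel,
                   selection: ResidueSelection):
    """Atom pairs matched by (chain, resnum, atom) within the selection."""
    sub_m = mobile.select(selection).atoms
    sub_r = reference.select(selection).atoms
    key = ["chain", "resnum", "atom"]
    merged = sub_r[key + ["x", "y", "z"]].merge(
        sub_m[key + ["x", "y", "z"]], on=key, suffixes=("_ref", "_mob"))
    xr = merged[["x_ref", "y_ref", "z_ref"]].to_numpy(float)
    xm = merged[["x_mob", "y_mob", "z_mob"]].to_numpy(float)
    return xm, xr, merged[key]


def superpose(mobile: StructureModel, reference: StructureModel,
              selection: ResidueSelection):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Atoms are paired by (chain, residue number, atom name) within the
    selection; the optimal rotation is the Kabsch/SVD solution with the
    reflection corrected, so the returned transform always has det +1.

    Returns ``(RigidTransform, rmsd, n_atoms)`` with RMSD in Å evaluated
    after applying the transform to the mobile atoms.
    """
    xm, xr, _ = _paired_coords(mobile, reference, selection)
    if len(xm) < 3:
        raise ValueError(f"need at least 3 paired atoms, got {len(xm)}")
    cm, cr = xm.mean(axis=0), xr.mean(axis=0)
    H = (xm - cm).T @ (xr - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(xm) - xr) ** 2, axis=1))))
    return transform, rmsd, len(xm)


# ---------------------------------------------------------------------------
# screw (Chasles) decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScrewAxis:
    """Screw parameters of a rigid motion.

    ``axis`` is the unit rotation axis (sign chosen so the angle is
    positive), ``angle`` the rotation in degrees in (0, 180], ``pitch`` the
    translation component along the axis in Å, and ``point`` a point on the
    axis (the one nearest the origin).  For angles below ``angle_tol`` the
    motion is pure translation: ``is_pure_translation`` is set and the axis
    fields are None.
    """

    axis: np.ndarray | None
    angle: float
    pitch: float
    point: np.ndarray | None
    is_pure_translation: bool = False


def screw_decompose(t: RigidTransform, angle_tol: float = 1e-6) -> ScrewAxis:
    """Decompose a rigid motion into rotation axis/angle + pitch.

    The axis is the eigendirection of the rotation for eigenvalue 1,
    extracted from the skew part (or, near 180°, from the symmetric part);
    the angle comes from the trace; the axis point solves the fixed-point
    equation ``(I − R) p = t_perp`` in the plane normal to the axis.
    """
    R, tr = t.rotation, t.translation
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cos_theta)))
    if theta <= angle_tol:  # angle_tol in degrees
        return ScrewAxis(None, 0.0, float(np.linalg.norm(tr)), None,
                         is_pure_translation=True)
    skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if np.linalg.norm(skew) > 1e-8:
        axis = skew / np.linalg.norm(skew)
    else:
        # angle ≈ 180°: axis from the eigenvector of (R + I)
        w, v = np.linalg.eigh((R + R.T) / 2.0)
        axis = v[:, np.argmax(w)]
        axis = axis / np.linalg.norm(axis)
    pitch = float(axis @ tr)
    t_perp = tr - pitch * axis
    # least-squares fixed point; (I - R) is rank 2 with nullspace = axis
    point, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    # pin the reported point to the axis location nearest the origin
    point = point - (point @ axis) * axis
    return ScrewAxis(axis, theta, pitch, point)


def screw_compose(axis, angle_deg: float, pitch: float = 0.0,
                  point=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Build the rigid motion with the given screw parameters (inverse of
    :func:`screw_decompose` for angles in (0, 180))."""
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("degenerate (zero) rotation axis")
    axis = axis / n
    point = np.asarray(point, float)
    th = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    t = point - R @ point + pitch * axis
    return RigidTransform(R, t)


# ---------------------------------------------------------------------------
# helix axes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixAxis:
    """Least-squares helix axis: unit ``direction`` (N→C positive),
    ``centroid`` of the fitted Cα, and number of Cα used."""

    direction: np.ndarray
    centroid: np.ndarray
    n_atoms: int


def helix_axis(structure: StructureModel, selection: ResidueSelection) -> HelixAxis:
    """Fit a helix axis as the dominant singular direction of centred Cα.

    The direction sign is fixed by the N→C convention (positive projection
    from the first to the last selected Cα).  At least 5 Cα are required; a
    fit where the dominant direction barely beats the second singular value
    (axially degenerate, e.g. near-collinear with the helix radius) emits a
    warning.
    """
    sel = selection.with_atoms(("CA",))
    sub = structure.select(sel).atoms.sort_values(["chain", "resnum"])
    if len(sub) < 5:
        raise ValueError(f"helix fit needs >= 5 CA atoms, got {len(sub)}")
    xyz = sub[["x", "y", "z"]].to_numpy(float)
    centroid = xyz.mean(axis=0)
    _, s, Vt = np.linalg.svd(xyz - centroid)
    if s[0] < 1.5 * s[1]:
        warnings.warn("helix axis fit is nearly degenerate "
                      f"(singular values {s[0]:.2f} vs {s[1]:.2f})", stacklevel=2)
    direction = Vt[0]
    nc = xyz[-1] - xyz[0]
    if direction @ nc < 0:
        direction = -direction
    return HelixAxis(direction, centroid, len(sub))


def inter_helix_angle(a: HelixAxis, b: HelixAxis):
    """Angle between two helix axes in degrees.

    Returns ``(acute, oriented)``: the acute angle in [0, 90] from the
    absolute dot product, and the oriented angle in [0, 180] using the
    N→C direction convention of both axes.
    """
    dot = float(np.clip(a.direction @ b.direction, -1.0, 1.0))
    oriented = float(np.degrees(np.arccos(dot)))
    acute = float(np.degrees(np.arccos(abs(dot))))
    return acute, oriented


# ---------------------------------------------------------------------------
# site displacement
# ---------------------------------------------------------------------------

def _dimer_twofold_axis(structure: StructureModel) -> np.ndarray:
    """Screw axis of the protomer→protomer transform of a homodimer.

    Pairs the two largest chains by residue number; for a symmetric dimer
    embedded in a membrane this two-fold axis is parallel to the membrane
    normal.
    """
    chains = structure.chains
    if len(chains) < 2:
        raise ValueError(
            "cannot derive an 'auto' normal from a single-chain structure; "
            "supply the membrane normal explicitly")
    sizes = structure.atoms.groupby("chain").size().sort_values(ascending=False)
    ca, cb = sizes.index[0], sizes.index[1]
    a = structure.select_chains([ca])
    b = structure.select_chains([cb])
    # rename chain b to a's id so the (chain, resnum, atom) pairing works
    bt = b.atoms.copy()
    bt["chain"] = ca
    shared = sorted(set(a.atoms["resnum"]) & set(bt["resnum"]))
    sel = ResidueSelection(((ca, min(shared), max(shared)),), atoms=("CA",))
    transform, _, _ = superpose(StructureModel(bt, label=b.label), a, sel)
    screw = screw_decompose(transform)
    if screw.is_pure_translation:
        raise ValueError("protomer-to-protomer transform has no rotation; "
                         "cannot define a two-fold axis")
    return screw.axis


def site_displacement(struct_a: StructureModel, struct_b: StructureModel,
                      align_on: ResidueSelection, site: ResidueSelection,
                      normal="auto"):
    """Displacement of a site between two conformations.

    ``struct_b`` is superposed onto ``struct_a`` using ``align_on`` (the
    static scaffold domain); the displacement of the site's Cα centroid is
    then measured.  ``normal`` may be a 3-vector (e.g. the membrane normal)
    or ``"auto"``, which derives the normal as the two-fold screw axis of
    the protomer→protomer transform of a homodimeric ``struct_a``.

    Returns ``(total, along_normal)`` in Å, with ``along_normal`` the
    absolute component of the displacement along the normal.
    """
    if isinstance(normal, str):
        if normal != "auto":
            raise ValueError(f"unknown normal spec {normal!r}")
        n_vec = _dimer_twofold_axis(struct_a)
    else:
        n_vec = np.asarray(normal, float)
        norm = np.linalg.norm(n_vec)
        if norm == 0:
            raise ValueError("degenerate (zero) normal vector")
        n_vec = n_vec / norm

    transform, _, _ = superpose(struct_b, struct_a, align_on)
    site_ca = site.with_atoms(("CA",))
    ca_a = struct_a.select(site_ca).atoms
    ca_b = struct_b.select(site_ca).atoms
    if ca_a.empty or ca_b.empty:
        raise ValueError("site selection resolves to no CA atoms")
    centroid_a = ca_a[["x", "y", "z"]].to_numpy(float).mean(axis=0)
    centroid_b = transform.apply(ca_b[["x", "y", "z"]].to_numpy(float)).mean(axis=0)
    d = centroid_b - centroid_a
    return float(np.linalg.norm(d)), float(abs(d @ n_vec))
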