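"""Rigid-body superposition, RMSD, distances, and accessible-surface/interface areas.

Superposition is the closed-form Kabsch solution (SVD with the determinant sign
fix, so reflections are never returned). Solvent-accessible surface area uses
Shrake–Rupley sphere-point sampling on a Fibonacci lattice with a 1.4 Å water
probe; interface area between two chain sets is half the buried area,
(SASA(A) + SASA(B) − SASA(A∪B)) / 2, the quantity PISA-style analyses report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, SelectionError
from .structio import StructureModel

#: van der Waals radii (Å) for SASA; standard Shrake–Rupley practice.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_PROBE = 1.4
DEFAULT_SPHERE_POINTS = 960


@dataclass
class Superposition:
    """A proper rigid transform y ≈ R·x + t minimizing RMSD over paired points."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.rotation.T + self.translation

    @property
    def angle_deg(self) -> float:
        return rotation_angle_deg(self.rotation)


@dataclass
class SasaResult:
    per_atom: np.ndarray
    total: float
    probe: float
    n_sphere_points: int


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle in degrees from a 3×3 proper rotation matrix.

    Equivalent to arccos((tr R − 1)/2) but evaluated through the quaternion
    representation, which stays fully conditioned near 0° and 180°.
    """
    from scipy.spatial.transform import Rotation

    return math.degrees(float(Rotation.from_matrix(R).magnitude()))


def rotation_axis(R: np.ndarray) -> np.ndarray:
    """Unit rotation axis of a proper rotation (sign follows the rotation vector)."""
    from scipy.spatial.transform import Rotation

    vec = Rotation.from_matrix(R).as_rotvec()
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        return np.array([0.0, 0.0, 1.0])
    return vec / norm


def superpose_kabsch(fixed: np.ndarray, moving: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``moving`` onto ``fixed`` (Kabsch).

    Both inputs are (n, 3) with n ≥ 3 paired points. Reflections are excluded
    via the standard determinant sign fix. Raises
    :class:`DegenerateGeometryError` for collinear point sets.
    """
    P = np.asarray(fixed, dtype=float)
    Q = np.asarray(moving, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("fixed and moving must be equal-shape (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 point pairs for superposition")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, S, Vt = np.linalg.svd(H)
    if S[0] > 0 and S[1] / S[0] < 1e-9:
        raise DegenerateGeometryError("point sets are (near-)collinear; rotation underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cp - R @ cq
    diff = P - (Q @ R.T + t)
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def pair_ca(model_a: StructureModel, model_b: StructureModel, chain_a: str, chain_b: str,
            mapping_a: dict | None = None, mapping_b: dict | None = None
            ) -> tuple[list, np.ndarray, np.ndarray]:
    """Pair Cα atoms of two chains on shared residue keys.

    Without mappings, residues pair on identical (resseq, icode). With numbering
    maps (author→reference, from :func:`sbpconf.structio.map_numbering`) they
    pair on shared reference positions. Returns (keys, coords_a, coords_b) with
    keys ascending. Raises if fewer than 3 pairs exist.
    """
    def ca_by_key(model, chain_id, mapping):
        out = {}
        for res in model.chain(chain_id).standard_residues():
            if not res.has_atom("CA"):
                continue
            key = mapping.get(res.key) if mapping is not None else res.key
            if key is not None:
                out[key] = res.atom("CA").xyz
        return out

    ca_a = ca_by_key(model_a, chain_a, mapping_a)
    ca_b = ca_by_key(model_b, chain_b, mapping_b)
    if not ca_a or not ca_b:
        raise SelectionError("chain(s) contain no Cα atoms")
    shared = sorted(set(ca_a) & set(ca_b), key=lambda k: (k if isinstance(k, tuple) else (k, "")))
    if len(shared) < 3:
        raise DegenerateGeometryError(
            f"only {len(shared)} shared Cα pairs; superposition underdetermined"
        )
    xa = np.array([ca_a[k] for k in shared])
    xb = np.array([ca_b[k] for k in shared])
    return shared, xa, xb


def rmsd_after_superposition(model_a: StructureModel, model_b: StructureModel,
                             chain_a: str, chain_b: str,
                             mapping_a: dict | None = None,
                             mapping_b: dict | None = None) -> float:
    """Cα RMSD (Å) after least-squares superposition; all pairs, no outlier rejection."""
    _, xa, xb = pair_ca(model_a, model_b, chain_a, chain_b, mapping_a, mapping_b)
    return superpose_kabsch(xa, xb).rmsd


def atom_distance(model: StructureModel,
                  sel_a: tuple[str, int, str],
                  sel_b: tuple[str, int, str]) -> float:
    """Euclidean distance (Å) between two atoms given as (chain, resseq, atom name)."""
    def locate(sel):
        chain_id, resseq, name = sel
        try:
            return model.chain(chain_id).residue(resseq).atom(name)
        except SelectionError as exc:
            raise SelectionError(f"selection {sel!r}: {exc}") from exc

    a = locate(sel_a)
    b = locate(sel_b)
    return float(np.linalg.norm(a.xyz - b.xyz))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _sasa_atoms(model: StructureModel, chains) -> list:
    atoms = []
    for c in model.chains:
        if chains is not None and c.id not in chains:
            continue
        for res in c.residues:
            if res.is_water:
                continue
            for a in res.atoms:
                if a.is_hydrogen:
                    continue
                atoms.append(a)
    if not atoms:
        raise SelectionError("no heavy atoms selected for SASA")
    return atoms


def shrake_rupley_sasa(model: StructureModel, chains=None, probe: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_SPHERE_POINTS) -> SasaResult:
    """Per-atom solvent-accessible surface area (Å²) by sphere-point sampling.

    Waters and hydrogens are excluded. Unknown elements (no vdW radius entry)
    raise an error naming the element.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be at least 100")
    atoms = _sasa_atoms(model, chains)
    coords = np.array([a.xyz for a in atoms])
    radii = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        try:
            radii[i] = VDW_RADII[a.element]
        except KeyError:
            raise SelectionError(
                f"no van der Waals radius for element {a.element!r} (atom {a.name})"
            ) from None
    sphere = _fibonacci_sphere(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    max_ext = ext.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + ext[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext) if j != i]
        if neigh:
            nb = coords[neigh]
            nr = ext[neigh]
            d2 = ((pts[:, None, :] - nb[None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 >= (nr ** 2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * ext[i] ** 2
    return SasaResult(per_atom=areas, total=float(areas.sum()), probe=probe,
                      n_sphere_points=n_points)


def interface_area(model: StructureModel, chains_a, chains_b,
                   probe: float = DEFAULT_PROBE,
                   n_points: int = DEFAULT_SPHERE_POINTS) -> float:
    """Buried interface area (Å²) between two disjoint chain sets: (ΔSASA)/2."""
    chains_a = set(chains_a)
    chains_b = set(chains_b)
    if chains_a & chains_b:
        raise ValueError("chain sets must be disjoint")
    sa = shrake_rupley_sasa(model, chains_a, probe, n_points).total
    sb = shrake_rupley_sasa(model, chains_b, probe, n_points).total
    sab = shrake_rupley_sasa(model, chains_a | chains_b, probe, n_points).total
    return (sa + sb - sab) / 2.0
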