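"""Shared helpers and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np

from sbpconf import structio

ONE_TO_THREE = {v: k for k, v in structio.THREE_TO_ONE.items()}


def atom_line(serial: int, name: str, resname: str, chain: str, resseq: int,
              x: float, y: float, z: float, occ: float = 1.0, element: str = "C",
              altloc: str = " ", record: str = "ATOM") -> str:
    """One fixed-column PDB ATOM/HETATM line."""
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {nm:<4s}{altloc:1s}{resname:>3s} "
            f"{chain}{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2s}")


def ca_chain_pdb(sequence: str, chain: str = "A", start: int = 1,
                 spacing: float = 3.8) -> str:
    """Cα-only PDB text for a one-letter sequence on a gentle (non-collinear) helix."""
    lines = [
        atom_line(i, "CA", ONE_TO_THREE[aa], chain, start + i - 1,
                  spacing * i, 1.5 * math.sin(0.6 * i), 1.5 * math.cos(0.6 * i))
        for i, aa in enumerate(sequence, start=1)
    ]
    return "\n".join(lines)


def sphere_form_factor(q: np.ndarray, radius: float) -> np.ndarray:
    """Analytic normalized intensity of a uniform sphere: I(q)/I(0)."""
    x = np.asarray(q) * radius
    return (3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3) ** 2


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Analytic pair-distance distribution of a uniform sphere (unnormalized)."""
    x = np.asarray(r) / (2.0 * radius)
    p = r ** 2 * (1.0 - 1.5 * x + 0.5 * x ** 3)
    return np.where(np.asarray(r) <= 2.0 * radius, p, 0.0)


def sphere_curve(radius: float = 30.0, qmin: float = 0.006, qmax: float = 0.5,
                 n: int = 300, sigma=None) -> structio.ScatteringCurve:
    q = np.linspace(qmin, qmax, n)
    I = sphere_form_factor(q, radius)
    return structio.ScatteringCurve(q=q, I=I, sigma=sigma)


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_align_score(seq_a: str, seq_b: str, matrix, gap_open: float,
                            gap_extend: float) -> float:
    """Optimal affine-gap global alignment score by exhaustive path enumeration.

    Exponential; only usable for sequences of length <= 8. Gap states are
    tracked so that opening costs gap_open + gap_extend-per-residue in the
    same convention as the aligner under test (open = first gapped column).
    """
    best = -math.inf

    def recurse(i: int, j: int, score: float, prev: str) -> None:
        nonlocal best
        if i == len(seq_a) and j == len(seq_b):
            best = max(best, score)
            return
        if i < len(seq_a) and j < len(seq_b):
            recurse(i + 1, j + 1, score + matrix[seq_a[i], seq_b[j]], "m")
        if i < len(seq_a):
            cost = gap_extend if prev == "a" else gap_open
            recurse(i + 1, j, score - cost, "a")
        if j < len(seq_b):
            cost = gap_extend if prev == "b" else gap_open
            recurse(i, j + 1, score - cost, "b")

    recurse(0, 0, 0.0, "m")
    return best


def bisect_fraction_bound(p_total: float, l_total: float, kd: float) -> float:
    """Fraction bound by bisection on free ligand (mass-action oracle)."""
    if l_total == 0:
        return 0.0

    def complex_conc(l_free: float) -> float:
        return p_total * l_free / (kd + l_free)

    lo, hi = 0.0, l_total
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if complex_conc(mid) + mid > l_total:
            hi = mid
        else:
            lo = mid
    return complex_conc((lo + hi) / 2.0) / p_total


def grid_refine_min_rmsd(fixed: np.ndarray, moving: np.ndarray) -> float:
    """Minimum RMSD over all proper rotations+translations by grid + refine.

    Independent of the Kabsch path: coarse search over rotation vectors, then
    Nelder–Mead polish. Centroids are matched first (optimal translation).
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    P = fixed - fixed.mean(axis=0)
    Q = moving - moving.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(((P - Q @ R.T) ** 2).sum() / len(P)))

    best = math.inf
    best_v = np.zeros(3)
    for ax in itertools.product(np.linspace(-math.pi, math.pi, 9), repeat=3):
        v = np.array(ax)
        val = rmsd_of(v)
        if val < best:
            best, best_v = val, v
    res = minimize(rmsd_of, best_v, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return float(res.fun)


def random_rigid_transform(rng: np.random.Generator):
    """A random proper rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t
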