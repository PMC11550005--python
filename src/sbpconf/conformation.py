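"""Open/closed conformational descriptors for two-lobe substrate-binding proteins.

A handful of scalar order parameters track lobe closure:

* **latch distance** — Cα–Cα distance of the surface residue pair that stacks
  when the lobes close (R50–N150 in HiSiaP-based numbering for SiaP);
* **kink angle** — the vertex angle of the long hinge helix, measured between
  the Cα vectors vertex→arm1 and vertex→arm2 (defaults Q263–E225–E228, vertex
  E225); closure kinks the helix to ~125°, open states straighten it;
* **named atom contacts** — e.g. the E186 OE2 – H209 NE2 triad interaction.

Between two conformers the lobe motion is modeled as a two-rigid-body
partition (an iterative stand-in for DynDom): superpose globally, split
residues by displacement, refit each cluster with Kabsch, reassign each
residue to the cluster predicting it best, iterate to a fixed point. The
inter-domain rotation angle follows from the rotation matrix that maps the
second domain once the first is aligned, θ = arccos((tr R − 1)/2).

All residue selections are given in reference numbering and resolved through
an optional author→reference numbering map from ``structio.map_numbering``;
with no map, selections are taken as author numbering directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, SelectionError, SingleRigidBodyError
from .geometry import Superposition, pair_ca, rotation_axis, superpose_kabsch
from .structio import StructureModel, invert_numbering

#: Default latch pair, kink triplet (vertex second) and contact list, in
#: HiSiaP-based reference numbering.
DEFAULT_LATCH = ((50, "CA"), (150, "CA"))
DEFAULT_KINK = (263, 225, 228)  # arm, vertex, arm
DEFAULT_CONTACTS = {"E186:OE2-H209:NE2": ((186, "OE2"), (209, "NE2"))}


@dataclass
class DescriptorSpec:
    """Residue/atom selections defining the scalar descriptors."""

    latch_pair: tuple = DEFAULT_LATCH
    kink_triplet: tuple = DEFAULT_KINK
    contacts: dict = field(default_factory=lambda: dict(DEFAULT_CONTACTS))

    def __post_init__(self) -> None:
        if len(set(self.kink_triplet)) != 3:
            raise ValueError("kink triplet residues must be distinct")


@dataclass
class DomainPartition:
    """Two rigid-body residue sets plus a hinge (bending) remainder."""

    domain1: list
    domain2: list
    hinge: list
    quality: tuple[float, float]

    @property
    def sizes(self) -> tuple[int, int]:
        return (len(self.domain1), len(self.domain2))


@dataclass
class RotationResult:
    """Inter-domain rotation: angle (deg, [0,180]), unit axis, screw translation (Å)."""

    angle: float
    axis: np.ndarray
    translation: float


@dataclass
class DescriptorSeries:
    """Per-frame descriptor values for a trajectory/ensemble."""

    time: np.ndarray
    latch: np.ndarray
    kink: np.ndarray
    contacts: dict[str, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.latch)

    def to_frame(self):
        import pandas as pd

        data = {"time": self.time, "latch_A": self.latch, "kink_deg": self.kink}
        for name, vals in self.contacts.items():
            data[name] = vals
        return pd.DataFrame(data)


def _resolve_atom(model: StructureModel, chain_id: str, resseq: int, atom_name: str,
                  inv_map: dict | None):
    """Resolve (reference resseq, atom name) to an atom, via the inverse numbering map."""
    chain = model.chain(chain_id)
    if inv_map is not None:
        key = inv_map.get(resseq)
        if key is None:
            raise SelectionError(f"reference residue {resseq} is unmapped in chain {chain_id}")
        res = chain.residue(*key)
    else:
        res = chain.residue(resseq)
    return res.atom(atom_name)


def _inv(mapping: dict | None) -> dict | None:
    return invert_numbering(mapping) if mapping is not None else None


def latch_distance(model: StructureModel, spec: DescriptorSpec | None = None,
                   chain: str | None = None, mapping: dict | None = None) -> float:
    """Cα–Cα latch distance (Å) of the spec's latch pair."""
    spec = spec or DescriptorSpec()
    chain = chain or model.chains[0].id
    inv = _inv(mapping)
    (r1, a1), (r2, a2) = spec.latch_pair
    x1 = _resolve_atom(model, chain, r1, a1, inv).xyz
    x2 = _resolve_atom(model, chain, r2, a2, inv).xyz
    return float(np.linalg.norm(x1 - x2))


def kink_angle(model: StructureModel, spec: DescriptorSpec | None = None,
               chain: str | None = None, mapping: dict | None = None) -> float:
    """Hinge-helix kink angle (degrees in [0, 180]) at the triplet's vertex."""
    spec = spec or DescriptorSpec()
    chain = chain or model.chains[0].id
    inv = _inv(mapping)
    arm1, vertex, arm2 = spec.kink_triplet
    xv = _resolve_atom(model, chain, vertex, "CA", inv).xyz
    x1 = _resolve_atom(model, chain, arm1, "CA", inv).xyz
    x2 = _resolve_atom(model, chain, arm2, "CA", inv).xyz
    v1 = x1 - xv
    v2 = x2 - xv
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise DegenerateGeometryError("kink triplet contains coincident points")
    c = float(np.dot(v1, v2) / (n1 * n2))
    return float(np.degrees(np.arccos(min(1.0, max(-1.0, c)))))


def contact_distances(model: StructureModel, spec: DescriptorSpec | None = None,
                      chain: str | None = None, mapping: dict | None = None) -> dict[str, float]:
    """Distances (Å) for every named atom-pair contact in the spec."""
    spec = spec or DescriptorSpec()
    chain = chain or model.chains[0].id
    inv = _inv(mapping)
    out = {}
    for name, ((ra, aa), (rb, ab)) in spec.contacts.items():
        xa = _resolve_atom(model, chain, ra, aa, inv).xyz
        xb = _resolve_atom(model, chain, rb, ab, inv).xyz
        out[name] = float(np.linalg.norm(xa - xb))
    return out


# ---------------------------------------------------------------------------
# Two-rigid-body partition and inter-domain rotation


def partition_domains(conformer_a: StructureModel, conformer_b: StructureModel,
                      chain_a: str | None = None, chain_b: str | None = None,
                      min_domain: int = 20, hinge_threshold: float = 2.0,
                      mapping_a: dict | None = None, mapping_b: dict | None = None,
                      max_iter: int = 50, rigid_tol: float = 0.25,
                      min_rotation: float = 2.0) -> DomainPartition:
    """Segment shared residues of a conformer pair into two rigid bodies + hinge.

    Residues whose best per-domain deviation exceeds ``hinge_threshold`` (Å)
    after convergence are assigned to the hinge set. Raises
    :class:`SingleRigidBodyError` when the pair is related by one global rigid
    motion — detected either up front (all residuals below ``rigid_tol`` Å
    after global superposition) or after convergence (the two domain fits
    differ by less than ``min_rotation`` degrees, the noise regime in which a
    two-body description carries no information) — or when no two domains of
    ``min_domain`` residues emerge.
    """
    chain_a = chain_a or conformer_a.chains[0].id
    chain_b = chain_b or conformer_b.chains[0].id
    keys, xa, xb = pair_ca(conformer_a, conformer_b, chain_a, chain_b, mapping_a, mapping_b)
    n = len(keys)
    if n < 2 * min_domain:
        raise DegenerateGeometryError(
            f"{n} shared residues < 2*min_domain ({2 * min_domain})"
        )
    sup = superpose_kabsch(xa, xb)
    disp = np.linalg.norm(xa - sup.apply(xb), axis=1)
    if disp.max() < rigid_tol:
        raise SingleRigidBodyError(
            "conformers are related by a single rigid motion "
            f"(max residual {disp.max():.3f} Å); no domain partition exists"
        )
    # 1D two-means on displacement for the initial split.
    labels = _two_means_1d(disp)
    resid = np.zeros((n, 2))
    fits = [None, None]
    for _ in range(max_iter):
        for d in (0, 1):
            members = labels == d
            if members.sum() < 3:
                raise SingleRigidBodyError("a displacement cluster collapsed; single rigid body?")
            fits[d] = superpose_kabsch(xa[members], xb[members])
            resid[:, d] = np.linalg.norm(xa - fits[d].apply(xb), axis=1)
        new_labels = np.argmin(resid, axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    from .geometry import rotation_angle_deg

    inter = rotation_angle_deg(fits[0].rotation @ fits[1].rotation.T)
    if inter < min_rotation:
        raise SingleRigidBodyError(
            f"domain fits differ by only {inter:.2f} deg (< {min_rotation} deg); "
            "motion is indistinguishable from a single rigid body"
        )
    best = resid.min(axis=1)
    hinge_mask = best > hinge_threshold
    d1_mask = (labels == 0) & ~hinge_mask
    d2_mask = (labels == 1) & ~hinge_mask
    if d1_mask.sum() < min_domain or d2_mask.sum() < min_domain:
        raise SingleRigidBodyError(
            f"no two domains of >= {min_domain} residues found "
            f"({int(d1_mask.sum())}/{int(d2_mask.sum())}); likely a single rigid body"
        )
    # Deterministic labeling: domain1 contains the lowest-numbered residue.
    first_in_1 = min(np.nonzero(d1_mask)[0][0], np.nonzero(d2_mask)[0][0]) in np.nonzero(d1_mask)[0]
    if not first_in_1:
        d1_mask, d2_mask = d2_mask, d1_mask
    q1 = float(np.sqrt((resid[d1_mask].min(axis=1) ** 2).mean()))
    q2 = float(np.sqrt((resid[d2_mask].min(axis=1) ** 2).mean()))
    return DomainPartition(
        domain1=[keys[i] for i in np.nonzero(d1_mask)[0]],
        domain2=[keys[i] for i in np.nonzero(d2_mask)[0]],
        hinge=[keys[i] for i in np.nonzero(hinge_mask)[0]],
        quality=(q1, q2),
    )


def _two_means_1d(values: np.ndarray, iters: int = 25) -> np.ndarray:
    c = np.array([values.min(), values.max()])
    labels = np.zeros(len(values), dtype=int)
    for _ in range(iters):
        labels = (np.abs(values[:, None] - c[None, :])).argmin(axis=1)
        for d in (0, 1):
            if (labels == d).any():
                c[d] = values[labels == d].mean()
    return labels


def domain_rotation(conformer_a: StructureModel, conformer_b: StructureModel,
                    partition: DomainPartition,
                    chain_a: str | None = None, chain_b: str | None = None,
                    mapping_a: dict | None = None, mapping_b: dict | None = None
                    ) -> RotationResult:
    """Rotation of domain2 between conformers after superposing on domain1.

    Returns the rotation angle θ = arccos((tr R − 1)/2) in degrees, the unit
    rotation axis, and the screw translation component along that axis.
    """
    chain_a = chain_a or conformer_a.chains[0].id
    chain_b = chain_b or conformer_b.chains[0].id
    keys, xa, xb = pair_ca(conformer_a, conformer_b, chain_a, chain_b, mapping_a, mapping_b)
    index = {k: i for i, k in enumerate(keys)}
    idx1 = [index[k] for k in partition.domain1 if k in index]
    idx2 = [index[k] for k in partition.domain2 if k in index]
    if len(idx1) < 3 or len(idx2) < 3:
        raise DegenerateGeometryError("partition domains not resolvable on this pair")
    sup1 = superpose_kabsch(xa[idx1], xb[idx1])
    yb2 = sup1.apply(xb[idx2])
    sup2: Superposition = superpose_kabsch(xa[idx2], yb2)
    axis = rotation_axis(sup2.rotation)
    t_along = float(np.dot(sup2.translation, axis))
    return RotationResult(angle=sup2.angle_deg, axis=axis, translation=t_along)


# ---------------------------------------------------------------------------
# Trajectory series, densities, state classification


def descriptor_series(frames, spec: DescriptorSpec | None = None,
                      chain: str | None = None, mapping: dict | None = None,
                      times=None) -> DescriptorSeries:
    """Latch/kink/contact values per frame, in frame order."""
    spec = spec or DescriptorSpec()
    frames = list(frames)
    latch = np.empty(len(frames))
    kink = np.empty(len(frames))
    contacts: dict[str, np.ndarray] = {name: np.empty(len(frames)) for name in spec.contacts}
    for i, frame in enumerate(frames):
        try:
            latch[i] = latch_distance(frame, spec, chain, mapping)
            kink[i] = kink_angle(frame, spec, chain, mapping)
            for name, val in contact_distances(frame, spec, chain, mapping).items():
                contacts[name][i] = val
        except SelectionError as exc:
            raise SelectionError(f"frame {i + 1}: {exc}") from exc
    t = np.asarray(times, dtype=float) if times is not None else np.arange(len(frames), dtype=float)
    return DescriptorSeries(time=t, latch=latch, kink=kink, contacts=contacts)


def probability_density(values, method: str = "kde", bandwidth: float | None = None,
                        n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Probability density of a descriptor series (integrates to 1 on its grid).

    ``kde`` uses a Gaussian kernel with Silverman bandwidth by default;
    ``histogram`` uses Freedman–Diaconis bins. Identical values under kde fall
    back to a delta-like narrow histogram with a warning.
    """
    from scipy.stats import gaussian_kde

    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need at least 2 finite values")
    if method not in ("kde", "histogram"):
        raise ValueError("method must be 'kde' or 'histogram'")
    if method == "kde":
        if np.ptp(x) == 0:
            warnings.warn("all values identical; falling back to a narrow histogram")
            method = "histogram"
        else:
            kde = gaussian_kde(x, bw_method=bandwidth if bandwidth is not None else "silverman")
            h = kde.factor * x.std(ddof=1)
            grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, n_grid)
            dens = kde(grid)
            dens = dens / np.trapezoid(dens, grid)
            return grid, dens
    if np.ptp(x) == 0:
        center = x[0]
        eps = max(abs(center) * 1e-6, 1e-6)
        grid = np.array([center - eps, center, center + eps])
        dens = np.array([0.0, 1.0 / eps, 0.0])
        return grid, dens
    counts, edges = np.histogram(x, bins="fd", density=True)
    grid = (edges[:-1] + edges[1:]) / 2.0
    return grid, counts


def classify_state(series, closed_ref: float, open_ref: float,
                   margin: float = 1.0):
    """Label each frame closed/intermediate/open by its latch distance.

    Frames with latch ≤ closed_ref + margin are closed; ≥ open_ref − margin
    open; otherwise intermediate. Returns (labels, fractions); the occupancy
    fractions sum to 1 exactly.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if closed_ref >= open_ref:
        raise ValueError("closed_ref must be < open_ref")
    if closed_ref + margin >= open_ref - margin:
        raise ValueError("classification bands overlap; reduce margin")
    values = series.latch if isinstance(series, DescriptorSeries) else np.asarray(series, dtype=float)
    labels = np.where(values <= closed_ref + margin, "closed",
                      np.where(values >= open_ref - margin, "open", "intermediate"))
    n = len(values)
    fractions = {state: float(np.sum(labels == state)) / n
                 for state in ("closed", "intermediate", "open")}
    return labels, fractions
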