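"""Synthetic inputs with known ground truth for every stage of the pipeline.

The structural toy is a two-lobe Cα-only pseudo-protein: two uniform-ball
point clouds joined by a short connector, with lobe 2 rigidly rotated about a
fixed hinge axis through the connector by a controllable hinge angle
(0° = fully closed reference). Marker residues mimic the descriptors of real
substrate-binding proteins: a latch pair (one residue per lobe whose Cα gap
grows monotonically with the hinge angle) and a kink triplet on the connector
whose vertex angle is exactly 180° − hinge angle. Because lobes are uniform
balls, closed-form Rg and Dmax oracles remain available for the scattering
stack.

Ensembles draw per-frame hinge angles from a constant, an Ornstein–Uhlenbeck
process, or a two-state Markov chain; scattering curves, titrations, and melt
curves add calibrated noise to the corresponding forward models. Every
generator is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binding import MeltCurve, TitrationTable, _boltzmann, fraction_bound
from .errors import SbpconfError
from .saxs import debye_intensity
from .structio import AtomRecord, ChainModel, Residue, ScatteringCurve, StructureModel

#: Study-design MST ladder: 16 two-fold dilutions from 100 µM (min 0.00305 µM).
MST_LADDER_M = 100e-6 * 0.5 ** np.arange(16)
MST_PROTEIN_M = 75e-9
MST_SIGNAL_BASE = 1000.0
MST_SIGNAL_AMPLITUDE = 200.0

#: DSF defaults: 20–95 °C window, ligand range 0.25 µM – 1 mM.
DSF_T_GRID = np.arange(20.0, 95.0 + 0.25, 0.5)
DSF_LIGAND_M = np.array([0.0, 0.25e-6, 1e-6, 4e-6, 16e-6, 62.5e-6, 250e-6, 1e-3])


@dataclass
class TwoLobeSpec:
    """Geometry of the two-lobe clamshell toy (hinge angle in degrees, 0 = closed).

    Two uniform-ball lobes sit at the ends of struts radiating from a hinge
    pivot; the closed state has the lobes just touching, and increasing the
    hinge angle swings lobe 2 away from lobe 1, so latch gap, radius of
    gyration and maximum extent all grow with opening — the geometry a
    substrate-binding protein's Venus-flytrap motion presents to solution
    scattering.
    """

    atoms_per_lobe: int = 60
    lobe_radius: float = 10.0
    hinge_angle: float = 0.0
    seed: int = 0
    closed_half_angle: float = 35.0
    connector_length: float = 6.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hinge_angle <= 90.0):
            raise ValueError("hinge angle must be within [0, 90] degrees")
        if self.atoms_per_lobe < 30:
            raise ValueError("atoms_per_lobe must be >= 30")

    @property
    def strut_length(self) -> float:
        # Closed lobes separated by 1 A of clearance.
        return (2.0 * self.lobe_radius + 1.0) / (
            2.0 * math.sin(math.radians(self.closed_half_angle)))


@dataclass
class TwoLobeTruth:
    """Ground truth emitted alongside a generated two-lobe structure."""

    hinge_angle: float
    lobe1_resseqs: list[int]
    lobe2_resseqs: list[int]
    hinge_resseqs: list[int]
    latch_pair: tuple[int, int]
    kink_triplet: tuple[int, int, int]
    latch_gap: float
    kink_angle: float
    axis: np.ndarray
    pivot: np.ndarray

    def descriptor_spec(self):
        from .conformation import DescriptorSpec

        arm1, vertex, arm2 = self.kink_triplet
        return DescriptorSpec(
            latch_pair=((self.latch_pair[0], "CA"), (self.latch_pair[1], "CA")),
            kink_triplet=(arm1, vertex, arm2),
            contacts={},
        )


@dataclass
class OUProcess:
    """Mean-reverting hinge-angle dynamics (degrees; relaxation in frames)."""

    mean: float
    relaxation: float = 10.0
    sd: float = 3.0


@dataclass
class TwoStateDynamics:
    """Markov switching between two hinge angles with stationary occupancies."""

    angles: tuple[float, float]
    occupancies: tuple[float, float]
    switch_prob: float = 1.0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.occupancies) - 1.0) > 1e-9:
            raise ValueError("occupancies must sum to 1")


@dataclass
class ConstantDynamics:
    angle: float


@dataclass
class EnsembleSpec:
    n_frames: int
    dynamics: object = field(default_factory=lambda: ConstantDynamics(20.0))
    seed: int = 0


def make_sphere_cloud(n_atoms: int, radius: float, seed: int = 0) -> StructureModel:
    """Uniformly sampled solid sphere of unit pseudo-atoms (closed-form oracles).

    A ball of radius R has Rg = sqrt(3/5)·R, Dmax = 2R and the analytic form
    factor [3(sin qR − qR cos qR)/(qR)³]², which makes this the reference
    object for the scattering stack.
    """
    rng = np.random.default_rng(seed)
    coords = _lobe_cloud(rng, n_atoms, radius)
    chain = ChainModel(id="A")
    for i, xyz in enumerate(coords, start=1):
        res = Residue(resname="GLY", resseq=i, icode="")
        res.atoms.append(AtomRecord(
            serial=i, name="CA", element="C", altloc="", resname="GLY",
            chain="A", resseq=i, icode="", xyz=np.array(xyz, dtype=float),
            occupancy=1.0, bfactor=0.0, is_het=False,
        ))
        chain.residues.append(res)
    return StructureModel(id=f"sphere_r{radius:g}_n{n_atoms}", chains=[chain],
                          source="synthetic")


def _hinge_rotation(theta_deg: float) -> np.ndarray:
    """Rotation about the z hinge axis by theta, swinging lobe 2 away from lobe 1.

    With strut angles measured from +y toward +x this maps a direction at
    angle phi to phi + theta, i.e. a clockwise rotation about +z.
    """
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def _lobe_cloud(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return radius * u * v


def _strut_dir(phi_deg: float) -> np.ndarray:
    """Unit vector at angle phi from +y toward +x (lobe-1 side is negative phi)."""
    t = math.radians(phi_deg)
    return np.array([math.sin(t), math.cos(t), 0.0])


def _two_lobe_sites(spec: TwoLobeSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Reference (closed) coordinates split into lobe1-rigid and lobe2-rigid blocks.

    Lobe 1 hangs off the strut at −closed_half_angle from +y, lobe 2 at
    +closed_half_angle; opening rotates the lobe-2 block about +z through the
    pivot (origin). Residue order: lobe1 cloud, latch1, kink arm1, kink
    vertex, kink arm2, latch2, lobe2 cloud.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.atoms_per_lobe
    R = spec.lobe_radius
    d = spec.strut_length
    u1 = _strut_dir(-spec.closed_half_angle)
    u2 = _strut_dir(+spec.closed_half_angle)
    lobe1 = _lobe_cloud(rng, n, R) + d * u1
    lobe2 = _lobe_cloud(rng, n, R) + d * u2
    latch1 = (d + R) * u1
    latch2 = (d + R) * u2
    arm1 = spec.connector_length * u1
    vertex = np.zeros(3)
    arm2 = spec.connector_length * u2
    fixed = np.vstack([lobe1, latch1[None, :], arm1[None, :], vertex[None, :]])
    mobile = np.vstack([arm2[None, :], latch2[None, :], lobe2])
    meta = {
        "n_fixed": len(fixed),
        "n_mobile": len(mobile),
        "latch1_res": n + 1,          # 1-based resseq of latch marker 1
        "arm1_res": n + 2,
        "vertex_res": n + 3,
        "arm2_res": n + 4,
        "latch2_res": n + 5,
        "lobe1_resseqs": list(range(1, n + 3)),          # cloud + latch1 + arm1
        "hinge_resseqs": [n + 3],                        # pivot vertex
        "lobe2_resseqs": list(range(n + 4, 2 * n + 6)),  # arm2 + latch2 + cloud
    }
    return fixed, mobile, meta


def _assemble(fixed: np.ndarray, mobile: np.ndarray, theta: float,
              meta: dict, model_id: str) -> tuple[StructureModel, float]:
    rot = _hinge_rotation(theta)
    mobile_rot = mobile @ rot.T
    coords = np.vstack([fixed, mobile_rot])
    chain = ChainModel(id="A")
    for i, xyz in enumerate(coords, start=1):
        res = Residue(resname="GLY", resseq=i, icode="")
        res.atoms.append(AtomRecord(
            serial=i, name="CA", element="C", altloc="", resname="GLY",
            chain="A", resseq=i, icode="", xyz=np.array(xyz, dtype=float),
            occupancy=1.0, bfactor=0.0, is_het=False,
        ))
        chain.residues.append(res)
    model = StructureModel(id=model_id, chains=[chain], source="synthetic")
    i1 = meta["latch1_res"] - 1
    i2 = meta["latch2_res"] - 1
    gap = float(np.linalg.norm(coords[i1] - coords[i2]))
    a1 = coords[meta["arm1_res"] - 1] - coords[meta["vertex_res"] - 1]
    a2 = coords[meta["arm2_res"] - 1] - coords[meta["vertex_res"] - 1]
    kink = math.degrees(math.acos(
        float(np.clip(a1 @ a2 / (np.linalg.norm(a1) * np.linalg.norm(a2)), -1, 1))))
    return model, gap, kink


def make_two_lobe(spec: TwoLobeSpec) -> tuple[StructureModel, TwoLobeTruth]:
    """Generate a two-lobe Cα-only structure at the spec's hinge angle.

    Deterministic for a fixed seed; the same seed at two hinge angles yields a
    pair related exactly by the hinge rotation on the mobile block. Raises when
    the requested angle brings the lobes into steric overlap.
    """
    fixed, mobile, meta = _two_lobe_sites(spec)
    model, gap, kink = _assemble(fixed, mobile, spec.hinge_angle, meta,
                                 f"two_lobe_h{spec.hinge_angle:g}_s{spec.seed}")
    coords = model.coords()
    lobe1 = coords[: spec.atoms_per_lobe]
    lobe2 = coords[-spec.atoms_per_lobe:]
    from scipy.spatial.distance import cdist

    if cdist(lobe1, lobe2).min() < 0.5:
        raise SbpconfError(f"lobes overlap at hinge angle {spec.hinge_angle}")
    truth = TwoLobeTruth(
        hinge_angle=spec.hinge_angle,
        lobe1_resseqs=meta["lobe1_resseqs"],
        lobe2_resseqs=meta["lobe2_resseqs"],
        hinge_resseqs=meta["hinge_resseqs"],
        latch_pair=(meta["latch1_res"], meta["latch2_res"]),
        kink_triplet=(meta["arm1_res"], meta["vertex_res"], meta["arm2_res"]),
        latch_gap=gap,
        kink_angle=kink,
        axis=np.array([0.0, 0.0, -1.0]),
        pivot=np.zeros(3),
    )
    return model, truth


def _draw_angles(dyn, n_frames: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(dyn, ConstantDynamics):
        return np.full(n_frames, float(dyn.angle)), None
    if isinstance(dyn, OUProcess):
        phi = math.exp(-1.0 / dyn.relaxation)
        innov_sd = dyn.sd * math.sqrt(1.0 - phi * phi)
        angles = np.empty(n_frames)
        angles[0] = rng.normal(dyn.mean, dyn.sd)
        for t in range(1, n_frames):
            angles[t] = dyn.mean + phi * (angles[t - 1] - dyn.mean) + rng.normal(0.0, innov_sd)
        return np.clip(angles, 0.0, 90.0), None
    if isinstance(dyn, TwoStateDynamics):
        p0, p1 = dyn.occupancies
        states = np.empty(n_frames, dtype=int)
        states[0] = int(rng.uniform() < p1)
        for t in range(1, n_frames):
            if states[t - 1] == 0:
                states[t] = int(rng.uniform() < dyn.switch_prob * p1)
            else:
                states[t] = 0 if rng.uniform() < dyn.switch_prob * p0 else 1
        angles = np.array([dyn.angles[s] for s in states], dtype=float)
        if dyn.jitter_sd > 0:
            angles = np.clip(angles + rng.normal(0.0, dyn.jitter_sd, n_frames), 0.0, 90.0)
        return angles, states
    raise TypeError(f"unknown dynamics {type(dyn).__name__}")


def make_ensemble(spec_struct: TwoLobeSpec, spec_dyn: EnsembleSpec):
    """Generate a conformer ensemble plus a truth table of per-frame angles.

    Returns (frames, truth) where ``truth`` is a DataFrame with columns frame,
    hinge_angle, latch_gap (plus state for two-state dynamics).
    """
    import pandas as pd

    fixed, mobile, meta = _two_lobe_sites(spec_struct)
    rng = np.random.default_rng(spec_dyn.seed)
    angles, states = _draw_angles(spec_dyn.dynamics, spec_dyn.n_frames, rng)
    frames = []
    gaps = []
    for i, theta in enumerate(angles, start=1):
        model, gap, _ = _assemble(fixed, mobile, float(theta), meta, f"frame#{i}")
        frames.append(model)
        gaps.append(gap)
    truth = pd.DataFrame({"frame": np.arange(1, spec_dyn.n_frames + 1),
                          "hinge_angle": angles, "latch_gap": gaps})
    if states is not None:
        truth["state"] = np.where(states == 0, "closed", "open")
    return frames, truth


def simulate_scattering_curve(model: StructureModel, q=None, counts_scale: float = 1e4,
                              seed: int = 0, form_factor_mode: str = "point"
                              ) -> ScatteringCurve:
    """Noisy scattering curve from a model: Poisson-like heteroscedastic noise.

    σ(q) = sqrt(I(q)/counts_scale); reported I = true I + N(0, σ). As
    counts_scale → ∞ the curve approaches the noiseless Debye prediction.
    """
    if counts_scale <= 0:
        raise ValueError("counts_scale must be positive")
    if q is None:
        q = np.linspace(0.006, 0.5, 200)
    truth = debye_intensity(model, q, form_factor_mode)
    sigma = np.sqrt(np.maximum(truth.I, 1e-12) / counts_scale)
    rng = np.random.default_rng(seed)
    noisy = truth.I + rng.normal(0.0, sigma)
    return ScatteringCurve(q=truth.q, I=noisy, sigma=sigma)


def simulate_titration(p_total: float = MST_PROTEIN_M, kd: float = 430e-9,
                       concentrations=None, noise_frac: float = 0.05,
                       n_replicates: int = 1, seed: int = 0) -> list[TitrationTable]:
    """Simulate MST-style titrations: affine signal of fraction bound + noise.

    signal = 1000 + 200·FB + N(0, noise_frac·200). Default ladder is the
    16-step two-fold dilution from 100 µM (min 0.00305 µM).
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    L = np.asarray(concentrations, dtype=float) if concentrations is not None else MST_LADDER_M.copy()
    rng = np.random.default_rng(seed)
    tables = []
    for rep in range(n_replicates):
        fb = fraction_bound(p_total, L, kd)
        signal = MST_SIGNAL_BASE + MST_SIGNAL_AMPLITUDE * fb
        if noise_frac > 0:
            signal = signal + rng.normal(0.0, noise_frac * MST_SIGNAL_AMPLITUDE, len(L))
        tables.append(TitrationTable(ligand_total=L, signal=signal,
                                     protein_total=p_total, replicate=rep))
    return tables


def simulate_melt_curve(tm: float, k: float = 1.5,
                        baselines: tuple[float, float, float, float] = (100.0, 0.2, 600.0, -0.5),
                        t_grid=None, noise_sd: float = 0.0, seed: int = 0) -> MeltCurve:
    """Simulate a DSF melt curve: Boltzmann sigmoid + Gaussian noise.

    ``baselines`` are (pre-intercept, pre-slope, post-intercept, post-slope).
    Raises when Tm lies outside the temperature grid.
    """
    T = np.asarray(t_grid, dtype=float) if t_grid is not None else DSF_T_GRID.copy()
    if not (T[0] < tm < T[-1]):
        raise ValueError(f"Tm {tm} outside temperature grid [{T[0]}, {T[-1]}]")
    b_pre, m_pre, b_post, m_post = baselines
    F = _boltzmann(T, b_pre, m_pre, b_post, m_post, tm, k)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, noise_sd, len(T))
    return MeltCurve(temperature=T, fluorescence=F)


def simulate_thermal_shift(k_app: float = 54.6e-6, tm0: float = 50.7,
                           dtm_max: float = 7.0, concentrations=None,
                           noise_sd: float = 0.0, seed: int = 0):
    """Simulate a Tm-vs-ligand thermal-shift series (hyperbolic apparent-K model)."""
    L = np.asarray(concentrations, dtype=float) if concentrations is not None else DSF_LIGAND_M.copy()
    tm = tm0 + dtm_max * L / (L + k_app)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        tm = tm + rng.normal(0.0, noise_sd, len(L))
    return L, tm
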