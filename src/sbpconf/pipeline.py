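"""End-to-end orchestration: conformer landscape reports and solution-state fits.

``analyze_conformers`` joins the per-structure descriptors (latch, kink,
contacts), the pairwise Cα RMSD matrix, and the domain rotation of every
structure against a designated reference. ``fit_solution_state`` runs the
scattering stack (Guinier, P(r)/Dmax, Porod volume, χ² conformer ranking) for
one experimental curve against candidate structures. Reports are plain
DataFrames plus a provenance block, written as deterministic TSVs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conformation import (DescriptorSpec, contact_distances, domain_rotation,
                           kink_angle, latch_distance, partition_domains)
from .errors import SbpconfError, SingleRigidBodyError
from .geometry import rmsd_after_superposition
from .saxs import (ScatteringCurve, estimate_dmax, guinier_fit, porod_volume,
                   pr_transform, rank_models)
from .structio import StructureModel

CHI2_INADEQUACY_FLAG = 3.0


@dataclass
class ConformerReport:
    """Joined outputs of a conformational-landscape analysis."""

    descriptors: pd.DataFrame
    rmsd_matrix: pd.DataFrame
    rotations: pd.DataFrame
    solution: dict | None = None
    provenance: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.descriptors.to_csv(out / "descriptors.tsv", sep="\t", index=False)
        self.rmsd_matrix.to_csv(out / "rmsd_matrix.tsv", sep="\t")
        self.rotations.to_csv(out / "rotations.tsv", sep="\t", index=False)
        lines = [f"sbpconf {__version__} conformer report"]
        for k, v in sorted(self.provenance.items()):
            lines.append(f"{k} = {v}")
        if self.solution is not None:
            lines.append("")
            lines.append("[solution scattering]")
            for k, v in self.solution.items():
                if isinstance(v, pd.DataFrame):
                    v.to_csv(out / f"solution_{k}.tsv", sep="\t", index=False)
                    lines.append(f"{k}: written to solution_{k}.tsv")
                else:
                    lines.append(f"{k} = {v}")
        for note in self.notes:
            lines.append(f"note: {note}")
        (out / "summary.txt").write_text("\n".join(lines) + "\n")


def _model_checksum(model: StructureModel) -> str:
    h = hashlib.sha256()
    for a in model.atoms():
        h.update(a.xyz.tobytes())
    return h.hexdigest()[:12]


def analyze_conformers(structures, reference: str | int = 0,
                       spec: DescriptorSpec | None = None,
                       chains=None, mappings=None,
                       min_domain: int = 20) -> ConformerReport:
    """Descriptor table, RMSD matrix, and rotation-vs-reference for ≥ 2 conformers.

    ``structures`` is a list of StructureModel; ``reference`` an index or model
    id; ``chains``/``mappings`` optional per-structure lists. Failures of the
    domain partition (e.g. identical conformers) are recorded as notes and a
    0°/NaN row rather than aborting the report.
    """
    structures = list(structures)
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    spec = spec or DescriptorSpec()
    n = len(structures)
    chains = chains or [m.chains[0].id for m in structures]
    mappings = mappings or [None] * n
    labels = [m.id for m in structures]
    if isinstance(reference, str):
        ref_idx = labels.index(reference)
    else:
        ref_idx = int(reference)
    notes: list[str] = []

    rows = []
    for m, chain, mapping in zip(structures, chains, mappings):
        row = {"label": m.id}
        try:
            row["latch_A"] = latch_distance(m, spec, chain, mapping)
        except SbpconfError as exc:
            row["latch_A"] = np.nan
            notes.append(f"{m.id}: latch failed ({exc})")
        try:
            row["kink_deg"] = kink_angle(m, spec, chain, mapping)
        except SbpconfError as exc:
            row["kink_deg"] = np.nan
            notes.append(f"{m.id}: kink failed ({exc})")
        try:
            for name, val in contact_distances(m, spec, chain, mapping).items():
                row[name] = val
        except SbpconfError as exc:
            notes.append(f"{m.id}: contacts failed ({exc})")
        rows.append(row)
    descriptors = pd.DataFrame(rows)

    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                val = rmsd_after_superposition(structures[i], structures[j],
                                               chains[i], chains[j],
                                               mappings[i], mappings[j])
            except SbpconfError as exc:
                val = np.nan
                notes.append(f"rmsd {labels[i]} vs {labels[j]} failed ({exc})")
            rmsd[i, j] = rmsd[j, i] = val
    rmsd_matrix = pd.DataFrame(rmsd, index=labels, columns=labels)

    rot_rows = []
    ref = structures[ref_idx]
    for i, m in enumerate(structures):
        if i == ref_idx:
            rot_rows.append({"label": m.id, "angle_deg": 0.0,
                             "n_domain1": np.nan, "n_domain2": np.nan})
            continue
        try:
            part = partition_domains(ref, m, chains[ref_idx], chains[i],
                                     min_domain=min_domain,
                                     mapping_a=mappings[ref_idx], mapping_b=mappings[i])
            rot = domain_rotation(ref, m, part, chains[ref_idx], chains[i],
                                  mappings[ref_idx], mappings[i])
            rot_rows.append({"label": m.id, "angle_deg": rot.angle,
                             "n_domain1": part.sizes[0], "n_domain2": part.sizes[1]})
        except SingleRigidBodyError as exc:
            rot_rows.append({"label": m.id, "angle_deg": 0.0,
                             "n_domain1": np.nan, "n_domain2": np.nan})
            notes.append(f"{m.id} vs reference: single rigid body ({exc})")
        except SbpconfError as exc:
            rot_rows.append({"label": m.id, "angle_deg": np.nan,
                             "n_domain1": np.nan, "n_domain2": np.nan})
            notes.append(f"{m.id} vs reference: rotation failed ({exc})")
    rotations = pd.DataFrame(rot_rows)

    provenance = {
        "reference": labels[ref_idx],
        "n_structures": n,
        "latch_pair": spec.latch_pair,
        "kink_triplet": spec.kink_triplet,
        "checksums": ",".join(f"{l}:{_model_checksum(m)}" for l, m in zip(labels, structures)),
        "version": __version__,
    }
    return ConformerReport(descriptors=descriptors, rmsd_matrix=rmsd_matrix,
                           rotations=rotations, provenance=provenance, notes=notes)


def fit_solution_state(curve: ScatteringCurve, structures, names=None,
                       form_factor_mode: str = "point") -> dict:
    """Solution-scattering characterization of one curve vs candidate conformers.

    Returns a dict with Guinier parameters, Dmax and P(r) moments, Porod
    volume, the χ² ranking table, and a model-inadequacy flag when even the
    best χ² exceeds 3 (a hint that the true solution ensemble lies outside the
    candidate set, e.g. wider-open conformers than any crystal form).
    """
    out: dict = {"notes": []}
    try:
        g = guinier_fit(curve)
        out["guinier_rg_A"] = g.rg
        out["guinier_i0"] = g.i0
        out["guinier_n_points"] = g.n_points
    except SbpconfError as exc:
        out["notes"].append(f"Guinier failed: {exc}")
        g = None
    if g is not None:
        try:
            dmax = estimate_dmax(curve)
            dist = pr_transform(curve, dmax)
            out["dmax_A"] = dmax
            out["pr_rg_A"] = dist.rg
            out["pr_i0"] = dist.i0
        except SbpconfError as exc:
            out["notes"].append(f"P(r) failed: {exc}")
        try:
            out["porod_volume_A3"] = porod_volume(curve, g)
        except SbpconfError as exc:
            out["notes"].append(f"Porod failed: {exc}")
    structures = list(structures)
    if structures:
        if len(structures) >= 2:
            table = rank_models(curve, structures, names=names,
                                form_factor_mode=form_factor_mode)
            out["ranking"] = table
            out["best_model"] = table.iloc[0]["model"]
            out["best_chi2"] = float(table.iloc[0]["chi2"])
            if out["best_chi2"] > CHI2_INADEQUACY_FLAG:
                out["model_inadequate"] = True
                out["notes"].append(
                    "best chi2 exceeds 3: candidate set may not contain the "
                    "solution ensemble (consider more-open models)")
            else:
                out["model_inadequate"] = False
    return out
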