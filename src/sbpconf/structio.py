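"""Structure and curve I/O plus the coordinate data model used by every other module.

Coordinates come from fixed-column PDB text (``ATOM``/``HETATM``/``MODEL``/
``ENDMDL``/``TER``). The model is deliberately simple: a :class:`StructureModel`
holds ordered chains of ordered residues of :class:`AtomRecord`, in file order,
keyed by author numbering. Author residue numbers are never renumbered; mapping
onto a reference numbering (e.g. the HiSiaP numbering used for residue labels
such as R50 or E186) is explicit, via :func:`map_numbering`.

Alternate locations are resolved at read time: the highest-occupancy copy of
each atom wins, ties broken by the lexicographically smallest altloc character.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import FormatError, ParseError, SelectionError

logger = logging.getLogger("sbpconf.structio")

#: 3-letter -> 1-letter codes for the 20 standard amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

WATER_RESNAMES = {"HOH", "WAT", "DOD"}


@dataclass
class AtomRecord:
    """One atom parsed from a PDB ``ATOM``/``HETATM`` record (coordinates in Å)."""

    serial: int
    name: str
    element: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    xyz: np.ndarray
    occupancy: float
    bfactor: float
    is_het: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    """An ordered group of atoms sharing (chain, resseq, icode)."""

    resname: str
    resseq: int
    icode: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def is_het(self) -> bool:
        return all(a.is_het for a in self.atoms)

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    @property
    def key(self) -> tuple[int, str]:
        return (self.resseq, self.icode)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise SelectionError(
            f"atom {name!r} not found in residue {self.resname} {self.resseq}{self.icode}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class ChainModel:
    """An ordered collection of residues with a single chain identifier."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, resseq: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.resseq == resseq and r.icode == icode:
                return r
        raise SelectionError(f"residue {resseq}{icode} not found in chain {self.id}")

    def sequence(self) -> str:
        """One-letter sequence of standard (non-het) amino-acid residues, file order."""
        return "".join(
            THREE_TO_ONE[r.resname]
            for r in self.residues
            if not r.is_het and r.resname in THREE_TO_ONE
        )

    def standard_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_het and r.resname in THREE_TO_ONE]


@dataclass
class StructureModel:
    """Hierarchical atom/residue/chain coordinate set (Å units)."""

    id: str
    chains: list[ChainModel] = field(default_factory=list)
    source: str = ""

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise SelectionError(f"chain {chain_id!r} not found in structure {self.id!r}")

    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def atoms(self, heavy_only: bool = False, skip_water: bool = False) -> Iterator[AtomRecord]:
        for c in self.chains:
            for r in c.residues:
                if skip_water and r.is_water:
                    continue
                for a in r.atoms:
                    if heavy_only and a.is_hydrogen:
                        continue
                    yield a

    def coords(self, heavy_only: bool = True, skip_water: bool = True) -> np.ndarray:
        xyz = [a.xyz for a in self.atoms(heavy_only=heavy_only, skip_water=skip_water)]
        if not xyz:
            raise SelectionError(f"structure {self.id!r} has no matching atoms")
        return np.asarray(xyz, dtype=float)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


@dataclass
class ScatteringCurve:
    """A small-angle scattering profile: (q, I, sigma) with q in Å⁻¹, strictly increasing."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.shape != self.I.shape:
            raise FormatError("q and I must have equal length")
        if self.sigma is not None and self.sigma.shape != self.q.shape:
            raise FormatError("sigma must match q length")
        if len(self.q) and np.any(np.diff(self.q) <= 0):
            raise FormatError("q must be strictly increasing")
        if np.any(self.q <= 0):
            raise FormatError("q must be positive")
        if self.sigma is not None and np.any(self.sigma <= 0):
            raise FormatError("sigma must be positive where present")

    def __len__(self) -> int:
        return len(self.q)


# ---------------------------------------------------------------------------
# PDB parsing


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    """Parse one fixed-column ATOM/HETATM record (PDB v3.3 columns)."""
    if len(line) < 54:
        raise ParseError(f"line {lineno}: ATOM/HETATM record shorter than 54 columns")
    padded = line.ljust(80)
    try:
        serial = int(padded[6:11])
    except ValueError:
        # Overflowed serial fields (*****) occur in very large files; tolerate.
        serial = 0
    name = padded[12:16].strip()
    if not name:
        raise ParseError(f"line {lineno}: empty atom name")
    altloc = padded[16].strip()
    resname = padded[17:20].strip()
    chain = padded[21].strip() or " "
    icode = padded[26].strip()
    try:
        resseq = int(padded[22:26])
        xyz = np.array(
            [float(padded[30:38]), float(padded[38:46]), float(padded[46:54])],
            dtype=float,
        )
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed fixed-width numeric field ({exc})") from exc
    try:
        occupancy = float(padded[54:60]) if padded[54:60].strip() else 1.0
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed occupancy field") from exc
    try:
        bfactor = float(padded[60:66]) if padded[60:66].strip() else 0.0
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed B-factor field") from exc
    element = padded[76:78].strip().upper()
    if not element:
        # Fall back to the leading letter(s) of the atom name.
        element = "".join(ch for ch in name if ch.isalpha())[:1].upper()
    if not np.all(np.isfinite(xyz)):
        raise ParseError(f"line {lineno}: non-finite coordinates")
    if not (0.0 <= occupancy <= 1.0):
        occupancy = min(max(occupancy, 0.0), 1.0)
    return AtomRecord(
        serial=serial, name=name, element=element, altloc=altloc,
        resname=resname, chain=chain, resseq=resseq, icode=icode,
        xyz=xyz, occupancy=occupancy, bfactor=bfactor,
    )


def _resolve_altlocs(atoms: list[AtomRecord], policy: str) -> list[AtomRecord]:
    """Collapse alternate locations of the same named atom to one copy.

    ``occupancy`` (default): keep the highest occupancy, ties broken by the
    lexicographically smallest altloc. ``first``: keep the first copy seen.
    """
    if policy not in ("occupancy", "first"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    out: dict[str, AtomRecord] = {}
    for a in atoms:
        prev = out.get(a.name)
        if prev is None:
            out[a.name] = a
        elif policy == "occupancy":
            if (a.occupancy, _altloc_rank(a.altloc)) > (prev.occupancy, _altloc_rank(prev.altloc)):
                out[a.name] = a
        # policy == "first": keep prev
    return list(out.values())


def _altloc_rank(altloc: str) -> float:
    # Higher rank wins alongside occupancy; smaller letter preferred on ties.
    return -ord(altloc) if altloc else 0.0


def _build_model(records: list[AtomRecord], model_id: str, source: str,
                 altloc_policy: str) -> StructureModel:
    chains: list[ChainModel] = []
    cur_chain: ChainModel | None = None
    cur_res: Residue | None = None
    raw: list[tuple[Residue, list[AtomRecord]]] = []
    for rec in records:
        if cur_chain is None or rec.chain != cur_chain.id:
            cur_chain = ChainModel(id=rec.chain)
            chains.append(cur_chain)
            cur_res = None
        if (cur_res is None or rec.resseq != cur_res.resseq
                or rec.icode != cur_res.icode or rec.resname != cur_res.resname):
            cur_res = Residue(resname=rec.resname, resseq=rec.resseq, icode=rec.icode)
            cur_chain.residues.append(cur_res)
            raw.append((cur_res, []))
        raw[-1][1].append(rec)
    for res, atoms in raw:
        res.atoms = _resolve_altlocs(atoms, altloc_policy)
    return StructureModel(id=model_id, chains=chains, source=source)


def _read_text(path_or_text: str | Path) -> tuple[str, str]:
    """Return (text, source label). Accepts a path or literal PDB text."""
    text = str(path_or_text)
    if "\n" not in text and Path(text).exists():
        return Path(text).read_text(), text
    return text, "<string>"


def _split_frames(lines: list[str]) -> list[tuple[str, list[tuple[int, str]]]]:
    """Split PDB lines into (frame id, [(lineno, line)]) blocks on MODEL/ENDMDL."""
    frames: list[tuple[str, list[tuple[int, str]]]] = []
    current: list[tuple[int, str]] = []
    current_id: str | None = None
    seen_model = False
    for i, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            seen_model = True
            if current:
                frames.append((current_id or str(len(frames) + 1), current))
            current = []
            current_id = line[6:].strip() or str(len(frames) + 1)
        elif rec == "ENDMDL":
            frames.append((current_id or str(len(frames) + 1), current))
            current = []
            current_id = None
        elif rec in ("ATOM", "HETATM"):
            current.append((i, line))
    if current:
        frames.append((current_id or str(len(frames) + 1), current))
    if not seen_model and len(frames) > 1:  # pragma: no cover - defensive
        frames = [(fid, blk) for fid, blk in frames]
    return [f for f in frames if f[1]]


def read_pdb(path_or_text: str | Path, altloc_policy: str = "occupancy") -> StructureModel:
    """Read a PDB file (or literal text); first MODEL only; hets and waters retained.

    Raises :class:`ParseError` (naming the line number) on malformed fixed-width
    records and on empty input.
    """
    text, source = _read_text(path_or_text)
    frames = _split_frames(text.splitlines())
    if not frames:
        raise ParseError("no ATOM or HETATM records found")
    frame_id, block = frames[0]
    records = []
    for lineno, line in block:
        rec = _parse_atom_line(line, lineno)
        rec.is_het = line[:6].strip() == "HETATM"
        records.append(rec)
    model_id = Path(source).stem if source != "<string>" else "model"
    return _build_model(records, model_id, source, altloc_policy)


def read_ensemble(path_or_text: str | Path, altloc_policy: str = "occupancy") -> list[StructureModel]:
    """Read a multi-model PDB as a list of frames, one StructureModel each.

    All frames must share an atom count; the first offending frame is named in
    the error. Frame index is preserved in each model's id.
    """
    text, source = _read_text(path_or_text)
    frames = _split_frames(text.splitlines())
    if not frames:
        raise ParseError("no ATOM or HETATM records found")
    base = Path(source).stem if source != "<string>" else "ensemble"
    models: list[StructureModel] = []
    n0: int | None = None
    for idx, (frame_id, block) in enumerate(frames, start=1):
        records = []
        for lineno, line in block:
            rec = _parse_atom_line(line, lineno)
            rec.is_het = line[:6].strip() == "HETATM"
            records.append(rec)
        if n0 is None:
            n0 = len(records)
        elif len(records) != n0:
            raise ParseError(
                f"frame {idx} (MODEL {frame_id}) has {len(records)} atoms, expected {n0}"
            )
        models.append(_build_model(records, f"{base}#{idx}", source, altloc_policy))
    return models


def write_pdb(models: StructureModel | Sequence[StructureModel], path: str | Path) -> None:
    """Write one model (single-model PDB) or several (MODEL/ENDMDL blocks)."""
    if isinstance(models, StructureModel):
        models = [models]
    lines: list[str] = []
    multi = len(models) > 1
    for i, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:>4d}")
        serial = 1
        for chain in model.chains:
            for res in chain.residues:
                for a in res.atoms:
                    rec = "HETATM" if a.is_het else "ATOM  "
                    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                    lines.append(
                        f"{rec}{serial:>5d} {name:<4.4s}{a.altloc or ' ':1.1s}"
                        f"{a.resname:>3.3s} {a.chain:1.1s}{a.resseq:>4d}{a.icode or ' ':1.1s}   "
                        f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2.2s}"
                    )
                    serial += 1
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Scattering curves


def read_scattering_curve(path_or_text: str | Path) -> ScatteringCurve:
    """Read a 3-column (q, I[, sigma]) text curve; '#' comments; commas allowed.

    Rows with non-positive q or non-finite intensity are dropped (count logged).
    """
    text = str(path_or_text)
    if "\n" not in text and Path(text).exists():
        text = Path(text).read_text()
    q_list, i_list, s_list = [], [], []
    n_sigma = 0
    n_rows = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        parts = stripped.replace(",", " ").split()
        if len(parts) < 2:
            raise FormatError(f"line {lineno}: expected at least 2 columns (q, I)")
        try:
            vals = [float(p) for p in parts[:3]]
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric value ({exc})") from exc
        n_rows += 1
        q_list.append(vals[0])
        i_list.append(vals[1])
        if len(vals) >= 3:
            s_list.append(vals[2])
            n_sigma += 1
        else:
            s_list.append(math.nan)
    if n_rows == 0:
        raise FormatError("empty curve file")
    q = np.array(q_list)
    I = np.array(i_list)
    s = np.array(s_list)
    keep = (q > 0) & np.isfinite(I)
    dropped = int(np.sum(~keep))
    if dropped:
        logger.info("read_scattering_curve: dropped %d invalid rows", dropped)
    q, I, s = q[keep], I[keep], s[keep]
    sigma = s if n_sigma == n_rows and np.all(np.isfinite(s)) and np.all(s > 0) else None
    return ScatteringCurve(q=q, I=I, sigma=sigma)


def write_scattering_curve(curve: ScatteringCurve, path: str | Path,
                           header: str = "q I sigma") -> None:
    cols = [curve.q, curve.I]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    arr = np.column_stack(cols)
    np.savetxt(path, arr, fmt="%.8g", header=header)


# ---------------------------------------------------------------------------
# Descriptor tables

DESCRIPTOR_COLUMNS = ["label", "descriptor", "value", "units"]


def write_table(rows, path: str | Path) -> None:
    """Write a descriptor table (label, descriptor, value, units) as TSV, input order."""
    import pandas as pd

    df = pd.DataFrame(rows, columns=DESCRIPTOR_COLUMNS) if not hasattr(rows, "to_csv") else rows
    if list(df.columns) != DESCRIPTOR_COLUMNS:
        raise FormatError(f"descriptor table must have columns {DESCRIPTOR_COLUMNS}")
    dup = df.duplicated(subset=["label", "descriptor"])
    if dup.any():
        raise FormatError("one value per (label, descriptor) pair is required")
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sequences and numbering maps


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record, line-wrapped) FASTA file as [(id, sequence)]."""
    from Bio import SeqIO

    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def map_numbering(model: StructureModel, chain_id: str, reference_seq: str) -> dict[tuple[int, str], int]:
    """Map author residue numbering of one chain onto a reference sequence.

    The chain's one-letter sequence is globally aligned to ``reference_seq``
    (Needleman–Wunsch, see :mod:`sbpconf.seqcalc`); each aligned residue maps to
    its 1-based reference position. Unaligned residues are absent from the map.
    """
    from . import seqcalc

    if not reference_seq:
        raise ValueError("reference sequence must be non-empty")
    chain = model.chain(chain_id)
    residues = chain.standard_residues()
    if not residues:
        raise SelectionError(f"chain {chain_id} has no standard amino-acid residues")
    seq = "".join(THREE_TO_ONE[r.resname] for r in residues)
    aln = seqcalc.global_align(seq, reference_seq)
    mapping: dict[tuple[int, str], int] = {}
    i = j = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-" and cb != "-":
            mapping[residues[i].key] = j + 1
        if ca != "-":
            i += 1
        if cb != "-":
            j += 1
    return mapping


def invert_numbering(mapping: dict[tuple[int, str], int]) -> dict[int, tuple[int, str]]:
    """Invert an author→reference map to reference→author (for selection lookup)."""
    return {v: k for k, v in mapping.items()}
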