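"""Structure and reflection I/O for toy orthogonal P1 crystals.

The structural hierarchy is chain -> secondary-structure element ->
residue -> atom.  Secondary-structure assignment is input metadata: it is
carried in the PDB segment identifier column (columns 73-76), supplied as a
sidecar mapping, or defaulted to one element per chain.  It is never
computed from geometry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "StructureModel",
    "ReflectionRecord",
    "ReflectionSet",
    "read_structure",
    "write_structure",
    "read_reflections",
    "write_reflections",
    "b_profile",
]


class ModelIOError(ValueError):
    """Raised for malformed structure or reflection input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the model.

    ``ss_id`` names the secondary-structure element the atom belongs to;
    ``b_iso`` is the isotropic atomic displacement parameter in A^2.
    """

    atom_id: int
    name: str
    element: str
    chain_id: str
    ss_id: str
    res_id: int
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ModelIOError(f"atom {self.atom_id}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ModelIOError(f"atom {self.atom_id}: occupancy {self.occupancy} outside [0, 1]")
        if self.b_iso < 0:
            raise ModelIOError(f"atom {self.atom_id}: negative b_iso {self.b_iso}")


class StructureModel:
    """Ordered atom list plus hierarchy in an orthogonal P1 cell.

    Parameters
    ----------
    atoms:
        Atom records in file order.
    cell:
        Three orthogonal edge lengths in Angstrom.

    The hierarchy mapping ``chain_id -> ss_id -> res_id -> [atom indices]``
    is derived from the atom records and partitions the atoms exactly once
    by construction; :meth:`validate` re-asserts this.
    """

    def __init__(self, atoms: list[AtomRecord], cell: tuple[float, float, float]):
        self.atoms = list(atoms)
        self.cell = tuple(float(c) for c in cell)
        if len(self.cell) != 3 or any(c <= 0 for c in self.cell):
            raise ModelIOError(f"cell edges must be three positive lengths, got {cell}")
        self._rebuild_hierarchy()

    def _rebuild_hierarchy(self) -> None:
        hierarchy: dict[str, dict[str, dict[int, list[int]]]] = {}
        seen: set[int] = set()
        for idx, atom in enumerate(self.atoms):
            if atom.atom_id in seen:
                raise ModelIOError(f"duplicate atom_id {atom.atom_id}")
            seen.add(atom.atom_id)
            hierarchy.setdefault(atom.chain_id, {}).setdefault(atom.ss_id, {}).setdefault(
                atom.res_id, []
            ).append(idx)
        self.hierarchy = hierarchy

    # -- array views ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def b_iso(self) -> np.ndarray:
        return np.array([a.b_iso for a in self.atoms], dtype=float)

    @property
    def occupancies(self) -> np.ndarray:
        return np.array([a.occupancy for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def atom_ids(self) -> np.ndarray:
        return np.array([a.atom_id for a in self.atoms], dtype=int)

    def with_positions(self, positions: np.ndarray) -> "StructureModel":
        """Copy of the model with replaced coordinates (same order)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (self.n_atoms, 3):
            raise ModelIOError(f"positions shape {positions.shape} != ({self.n_atoms}, 3)")
        atoms = [replace(a, position=positions[i].copy()) for i, a in enumerate(self.atoms)]
        return StructureModel(atoms, self.cell)

    def with_b_iso(self, b_iso: np.ndarray) -> "StructureModel":
        b_iso = np.asarray(b_iso, dtype=float)
        if b_iso.shape != (self.n_atoms,):
            raise ModelIOError(f"b_iso shape {b_iso.shape} != ({self.n_atoms},)")
        atoms = [replace(a, b_iso=float(b)) for a, b in zip(self.atoms, b_iso)]
        return StructureModel(atoms, self.cell)

    # -- selections ----------------------------------------------------

    def select(self, predicate) -> np.ndarray:
        """Indices of atoms for which ``predicate(AtomRecord)`` is true."""
        return np.array([i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int)

    def chain_ids(self) -> list[str]:
        return list(self.hierarchy.keys())

    def groups(self, level: str) -> dict[tuple, list[int]]:
        """Atom-index groups at ``level`` in {'chain', 'secondary_structure', 'residue'}.

        Keys are hierarchy paths (chain,), (chain, ss) or (chain, ss, res).
        """
        out: dict[tuple, list[int]] = {}
        for ch, ss_map in self.hierarchy.items():
            for ss, res_map in ss_map.items():
                for res, idxs in res_map.items():
                    if level == "chain":
                        key: tuple = (ch,)
                    elif level == "secondary_structure":
                        key = (ch, ss)
                    elif level == "residue":
                        key = (ch, ss, res)
                    else:
                        raise ValueError(f"unknown level {level!r}")
                    out.setdefault(key, []).extend(idxs)
        return out

    def validate(self) -> None:
        """Assert the hierarchy partitions all atoms exactly once."""
        counted = sum(
            len(idxs)
            for ss_map in self.hierarchy.values()
            for res_map in ss_map.values()
            for idxs in res_map.values()
        )
        flat: list[int] = []
        for ss_map in self.hierarchy.values():
            for res_map in ss_map.values():
                for idxs in res_map.values():
                    flat.extend(idxs)
        if counted != self.n_atoms or len(set(flat)) != self.n_atoms:
            raise ModelIOError("hierarchy does not partition atoms exactly once")

    def __repr__(self) -> str:
        return (
            f"StructureModel({self.n_atoms} atoms, {len(self.hierarchy)} chains, "
            f"cell={self.cell})"
        )


@dataclass(frozen=True)
class ReflectionRecord:
    hkl: tuple[int, int, int]
    f_obs: float
    sigma: float
    free_flag: bool

    def __post_init__(self) -> None:
        if self.f_obs < 0:
            raise ModelIOError(f"negative f_obs for {self.hkl}")
        if self.sigma <= 0:
            raise ModelIOError(f"non-positive sigma for {self.hkl}")


@dataclass
class ReflectionSet:
    """Observed amplitudes with a cross-validation (free) split."""

    records: list[ReflectionRecord]
    d_min: float | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[int, int, int]] = set()
        for rec in self.records:
            if rec.hkl in seen:
                raise ModelIOError(f"duplicate reflection index {rec.hkl}")
            seen.add(rec.hkl)

    @property
    def n_reflections(self) -> int:
        return len(self.records)

    @property
    def hkl(self) -> np.ndarray:
        return np.array([r.hkl for r in self.records], dtype=int)

    @property
    def f_obs(self) -> np.ndarray:
        return np.array([r.f_obs for r in self.records], dtype=float)

    @property
    def sigma(self) -> np.ndarray:
        return np.array([r.sigma for r in self.records], dtype=float)

    @property
    def free_mask(self) -> np.ndarray:
        return np.array([r.free_flag for r in self.records], dtype=bool)

    @property
    def work_mask(self) -> np.ndarray:
        return ~self.free_mask

    def resolution(self, cell: tuple[float, float, float]) -> np.ndarray:
        """d-spacing per reflection for an orthogonal cell, Angstrom."""
        hkl = self.hkl.astype(float)
        inv_d2 = (hkl / np.asarray(cell, dtype=float)) ** 2
        s = np.sqrt(inv_d2.sum(axis=1))
        with np.errstate(divide="ignore"):
            return np.where(s > 0, 1.0 / np.maximum(s, 1e-300), np.inf)


# ---------------------------------------------------------------------------
# PDB-subset I/O (via gemmi)
# ---------------------------------------------------------------------------

_DEFAULT_CELL = (50.0, 50.0, 50.0)


def read_structure(
    text: str,
    ss_map: dict[str, list[tuple[int, int, str]]] | None = None,
    default_cell: tuple[float, float, float] | None = _DEFAULT_CELL,
) -> StructureModel:
    """Parse a minimal fixed-width PDB string into a :class:`StructureModel`.

    Secondary-structure assignment, in order of precedence: the PDB segment
    column written by :func:`write_structure`; the ``ss_map`` sidecar
    ``{chain_id: [(res_start, res_end, ss_id), ...]}``; one element per
    chain.  Only the first MODEL of a multi-model file is read.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line.rstrip()) < 54:
            raise ModelIOError(f"malformed ATOM line at line {lineno}: {line!r}")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ModelIOError(f"PDB parse error: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise ModelIOError("no ATOM records found")

    if st.cell.a > 0 and st.cell.is_crystal():
        cell = (st.cell.a, st.cell.b, st.cell.c)
    elif default_cell is not None:
        cell = default_cell
    else:
        raise ModelIOError("no CRYST1 cell and no default cell configured")

    def lookup_ss(chain_id: str, res_id: int, segment: str) -> str:
        if segment:
            return segment
        if ss_map and chain_id in ss_map:
            for lo, hi, ss in ss_map[chain_id]:
                if lo <= res_id <= hi:
                    return ss
        return chain_id  # one SS element per chain

    atoms: list[AtomRecord] = []
    serial = 0
    for chain in st[0]:
        for res in chain:
            for at in res:
                serial += 1
                atoms.append(
                    AtomRecord(
                        atom_id=at.serial if at.serial > 0 else serial,
                        name=at.name,
                        element=at.element.name,
                        chain_id=chain.name,
                        ss_id=lookup_ss(chain.name, res.seqid.num, res.segment),
                        res_id=res.seqid.num,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        b_iso=at.b_iso,
                    )
                )
    model = StructureModel(atoms, cell)
    model.validate()
    return model


def _to_gemmi(models: list[StructureModel]) -> gemmi.Structure:
    first = models[0]
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*first.cell, 90.0, 90.0, 90.0)
    st.spacegroup_hm = "P 1"
    for i, model in enumerate(models, start=1):
        gm = gemmi.Model(str(i))
        chain = None
        residue = None
        res_key = None
        for atom in model.atoms:
            if abs(atom.position).max() >= 10000:
                raise ModelIOError(
                    f"atom {atom.atom_id}: coordinate overflows fixed-width PDB field"
                )
            if chain is None or chain.name != atom.chain_id:
                gm.add_chain(gemmi.Chain(atom.chain_id))
                chain = gm[len(gm) - 1]
                res_key = None
            key = (atom.res_id, atom.ss_id)
            if key != res_key:
                residue = gemmi.Residue()
                residue.name = "GLY"
                residue.seqid = gemmi.SeqId(atom.res_id, " ")
                residue.segment = atom.ss_id[:4]
                chain.add_residue(residue)
                residue = chain[len(chain) - 1]
                res_key = key
            at = gemmi.Atom()
            at.serial = atom.atom_id
            at.name = atom.name
            at.element = gemmi.Element(atom.element)
            at.pos = gemmi.Position(*atom.position)
            at.occ = atom.occupancy
            at.b_iso = atom.b_iso
            residue.add_atom(at)
        st.add_model(gm)
    return st


def write_structure(model: StructureModel | list[StructureModel]) -> str:
    """Render one model (or an ensemble as MODEL/ENDMDL blocks) as PDB text.

    B factors go to the fixed-format B column with 2 decimals; the
    secondary-structure element id goes to the segment column.
    """
    models = model if isinstance(model, list) else [model]
    if not models:
        raise ModelIOError("empty ensemble")
    st = _to_gemmi(models)
    opts = gemmi.PdbWriteOptions()
    opts.seqres_records = False
    opts.ter_records = False
    opts.numbered_ter = False
    return st.make_pdb_string(opts)


def read_ensemble(text: str, **kwargs) -> list[StructureModel]:
    """Read all MODEL blocks of a multi-model PDB string."""
    st = gemmi.read_pdb_string(text)
    out = []
    for gm in st:
        buf = io.StringIO()
        single = gemmi.Structure()
        single.cell = st.cell
        single.spacegroup_hm = st.spacegroup_hm
        single.add_model(gm)
        out.append(read_structure(single.make_pdb_string(), **kwargs))
    return out


# ---------------------------------------------------------------------------
# Reflection-table I/O
# ---------------------------------------------------------------------------

_REFL_COLUMNS = ["h", "k", "l", "fobs", "sigma", "free"]


def read_reflections(text: str, d_min: float | None = None) -> ReflectionSet:
    """Parse a delimited reflection table with header ``h k l fobs sigma free``.

    Both whitespace- and comma-delimited dialects are accepted; the free
    flag column is parsed as boolean (0/1 or true/false).
    """
    sep = "," if "," in text.splitlines()[0] else r"\s+"
    df = pd.read_csv(io.StringIO(text), sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REFL_COLUMNS if c not in df.columns]
    if missing:
        raise ModelIOError(f"reflection table missing columns: {missing}")
    records = [
        ReflectionRecord(
            hkl=(int(row.h), int(row.k), int(row.l)),
            f_obs=float(row.fobs),
            sigma=float(row.sigma),
            free_flag=bool(int(row.free)) if str(row.free).isdigit() else str(row.free).lower() in ("true", "t", "yes"),
        )
        for row in df.itertuples(index=False)
    ]
    return ReflectionSet(records, d_min=d_min)


def write_reflections(refl: ReflectionSet) -> str:
    """Render a :class:`ReflectionSet` as a whitespace-delimited table."""
    lines = ["h k l fobs sigma free"]
    for r in refl.records:
        lines.append(
            f"{r.hkl[0]} {r.hkl[1]} {r.hkl[2]} {r.f_obs:.6g} {r.sigma:.6g} {int(r.free_flag)}"
        )
    return "\n".join(lines) + "\n"


def b_profile(model: StructureModel, selection=None) -> list[tuple[int, float]]:
    """Ordered ``(atom_id, b_iso)`` pairs for atoms matching ``selection``.

    ``selection`` is a predicate on :class:`AtomRecord`; ``None`` selects
    every atom.  Raises on an empty selection.
    """
    if selection is None:
        idxs = range(model.n_atoms)
    else:
        idxs = model.select(selection)
        if len(idxs) == 0:
            raise ModelIOError("selection matches no atoms")
    return [(model.atoms[i].atom_id, model.atoms[i].b_iso) for i in idxs]
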