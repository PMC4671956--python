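"""PDB v3.3 fixed-column reading/writing and the coordinate data model.

The hierarchy is Ensemble -> StructureModel -> Residue -> Atom; MODEL/ENDMDL
blocks of a multi-model file map to successive StructureModel entries, so a
trajectory exported as a multi-model PDB becomes an Ensemble of frames.

Only the ATOM/HETATM/MODEL/ENDMDL records matter here; everything else
(SEQRES, symmetry, secondary structure) is ignored by design. Alternate
locations are resolved at parse time per the chosen policy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AltLocPolicy",
    "PDBParseError",
    "PDBFormatError",
    "EmptyInputError",
    "LookupFailure",
    "Atom",
    "Residue",
    "StructureModel",
    "Ensemble",
    "EnsembleKind",
    "read_pdb",
    "read_pdb_file",
    "write_pdb",
    "get_atom",
    "get_residue",
    "list_waters",
]

WATER_NAMES = frozenset({"HOH", "WAT"})


class AltLocPolicy(str, enum.Enum):
    HIGHEST_OCCUPANCY = "highest_occupancy"
    FIRST = "first"


class PDBParseError(ValueError):
    """Malformed PDB record; the message names the offending line number."""


class PDBFormatError(ValueError):
    """A value cannot be represented in fixed-column PDB output."""


class EmptyInputError(ValueError):
    """Input contained no usable content."""


class LookupFailure(KeyError):
    """A (chain, residue, atom) query did not resolve."""


class EnsembleKind(str, enum.Enum):
    CRYSTAL_SET = "crystal_set"
    TRAJECTORY = "trajectory"


@dataclass(slots=True)
class Atom:
    serial: int
    name: str
    element: str
    alt_loc: str
    coords: np.ndarray  # 3-vector, Angstrom
    occupancy: float
    b_factor: float
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise ValueError(f"atom {self.name}: negative B factor {self.b_factor}")


@dataclass(slots=True)
class Residue:
    chain_id: str
    res_seq: int
    res_name: str
    i_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.i_code)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise LookupFailure(
            f"atom {name!r} not found in {self.res_name} "
            f"{self.chain_id}{self.res_seq}{self.i_code}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES


@dataclass(slots=True)
class StructureModel:
    model_no: int
    residues: dict[tuple[str, int, str], Residue] = field(default_factory=dict)
    source_label: str = ""

    def add_residue(self, residue: Residue) -> None:
        if residue.key in self.residues:
            raise ValueError(f"duplicate residue key {residue.key}")
        self.residues[residue.key] = residue

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for res in self.residues.values():
            seen.setdefault(res.chain_id, None)
        return list(seen)

    def iter_atoms(self):
        for res in self.residues.values():
            for atom in res.atoms:
                yield res, atom


@dataclass(slots=True)
class Ensemble:
    models: list[StructureModel]
    kind: EnsembleKind = EnsembleKind.CRYSTAL_SET

    def __post_init__(self) -> None:
        if not self.models:
            raise EmptyInputError("an Ensemble requires at least one model")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


# ---------------------------------------------------------------------------
# parsing

def _parse_float(line: str, lo: int, hi: int, what: str, lineno: int) -> float:
    text = line[lo:hi].strip()
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed {what} field {text!r}") from None


def _parse_int(line: str, lo: int, hi: int, what: str, lineno: int) -> int:
    text = line[lo:hi].strip()
    try:
        return int(text)
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed {what} field {text!r}") from None


def read_pdb(
    text: str,
    alt_loc_policy: AltLocPolicy | str = AltLocPolicy.HIGHEST_OCCUPANCY,
    source_label: str = "",
    kind: EnsembleKind | str = EnsembleKind.CRYSTAL_SET,
) -> Ensemble:
    """Parse PDB-format text into an Ensemble.

    MODEL/ENDMDL blocks become successive models; a file without MODEL
    records yields a single model. Fields are read from the PDB v3.3 fixed
    columns (coordinates 31-54, occupancy 55-60, B factor 61-66, element
    77-78). Alternate locations are resolved per ``alt_loc_policy``:
    ``highest_occupancy`` keeps the highest-occupancy record (ties broken by
    alphabetical alt-loc id), ``first`` keeps the first record seen.
    """
    policy = AltLocPolicy(alt_loc_policy)
    kind = EnsembleKind(kind)

    models: list[StructureModel] = []
    current: StructureModel | None = None
    explicit_models = False
    n_atoms = 0

    def _ensure_model() -> StructureModel:
        nonlocal current
        if current is None:
            current = StructureModel(model_no=len(models) + 1, source_label=source_label)
        return current

    # per-model alt-loc candidates: (res key, atom name) -> list of Atom
    candidates: dict[tuple, list[Atom]] = {}
    res_meta: dict[tuple, tuple[str, str, int, str]] = {}
    order: list[tuple] = []

    def _flush_model() -> None:
        nonlocal current, candidates, res_meta, order
        if current is None:
            return
        for full_key in order:
            res_key = full_key[:3]
            res_name = res_meta[full_key]
            atoms = candidates[full_key]
            if policy is AltLocPolicy.FIRST:
                chosen = atoms[0]
            else:
                chosen = min(atoms, key=lambda a: (-a.occupancy, a.alt_loc))
            residue = current.residues.get(res_key)
            if residue is None:
                residue = Residue(
                    chain_id=res_key[0], res_seq=res_key[1], i_code=res_key[2],
                    res_name=res_name,
                )
                current.residues[res_key] = residue
            residue.atoms.append(chosen)
        models.append(current)
        current = None
        candidates, res_meta, order = {}, {}, []

    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6]
        if record.startswith("MODEL"):
            _flush_model()
            explicit_models = True
            current = StructureModel(
                model_no=_parse_int(line, 10, 14, "model number", lineno)
                if line[10:14].strip() else len(models) + 1,
                source_label=source_label,
            )
        elif record.startswith("ENDMDL"):
            _flush_model()
        elif record in ("ATOM  ", "HETATM"):
            model = _ensure_model()
            name = line[12:16].strip()
            alt_loc = line[16:17].strip()
            res_name = line[17:20].strip()
            chain_id = line[21:22].strip()
            res_seq = _parse_int(line, 22, 26, "residue number", lineno)
            i_code = line[26:27].strip()
            x = _parse_float(line, 30, 38, "x coordinate", lineno)
            y = _parse_float(line, 38, 46, "y coordinate", lineno)
            z = _parse_float(line, 46, 54, "z coordinate", lineno)
            occ = _parse_float(line, 54, 60, "occupancy", lineno) if line[54:60].strip() else 1.0
            b = _parse_float(line, 60, 66, "B factor", lineno) if line[60:66].strip() else 0.0
            element = line[76:78].strip() or _guess_element(name)
            atom = Atom(
                serial=_parse_int(line, 6, 11, "serial", lineno),
                name=name, element=element, alt_loc=alt_loc,
                coords=np.array([x, y, z]), occupancy=occ, b_factor=b,
                is_hetero=(record == "HETATM"),
            )
            full_key = (chain_id, res_seq, i_code, name)
            if full_key not in candidates:
                candidates[full_key] = []
                res_meta[full_key] = res_name
                order.append(full_key)
            candidates[full_key].append(atom)
            n_atoms += 1
        # all other records ignored
    _flush_model()

    if n_atoms == 0:
        raise EmptyInputError("no ATOM or HETATM records found")
    if explicit_models:
        models = [m for m in models if m.residues]
    return Ensemble(models=models, kind=kind)


def read_pdb_file(path, **kwargs) -> Ensemble:
    with open(path) as handle:
        text = handle.read()
    kwargs.setdefault("source_label", str(path))
    return read_pdb(text, **kwargs)


def _guess_element(atom_name: str) -> str:
    """Fallback element inference from the atom name (two-letter halogens first)."""
    stripped = atom_name.strip().upper()
    for two in ("CL", "BR"):
        if stripped.startswith(two):
            return two.capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch
    return ""


# ---------------------------------------------------------------------------
# writing

def _format_atom_name(name: str) -> str:
    if len(name) > 4:
        raise PDBFormatError(f"atom name {name!r} longer than 4 characters")
    # one/two-char names conventionally start in column 14 unless 4 chars wide
    if len(name) < 4 and len(name.rstrip("0123456789")) <= 2 and not name[:2].upper() in (
        "CL", "BR", "FE", "ZN", "MG", "NA",
    ):
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(ensemble: Ensemble) -> str:
    """Serialize to fixed-column PDB text.

    Coordinates keep 3 decimals and B factors 2, so
    ``read_pdb(write_pdb(e))`` reproduces them at that precision and
    reproduces names/numbering exactly. Multi-model ensembles get one
    MODEL/ENDMDL block per model.
    """
    lines: list[str] = []
    multi = len(ensemble.models) > 1
    for model in ensemble.models:
        if multi:
            lines.append(f"MODEL     {model.model_no:>4d}")
        serial = 0
        for res in model.residues.values():
            for atom in res.atoms:
                serial += 1
                record = "HETATM" if atom.is_hetero else "ATOM  "
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial:>5d} {_format_atom_name(atom.name)}"
                    f"{atom.alt_loc or ' ':1s}{res.res_name:>3s} {res.chain_id:1s}"
                    f"{res.res_seq:>4d}{res.i_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                    f"{'':10s}{atom.element:>2s}"
                )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# queries

def get_residue(model: StructureModel, chain_id: str, res_seq: int, i_code: str = "") -> Residue:
    res = model.residues.get((chain_id, res_seq, i_code))
    if res is None:
        raise LookupFailure(f"residue ({chain_id!r}, {res_seq}, {i_code!r}) not found")
    return res


def get_atom(model: StructureModel, chain_id: str, res_seq: int, atom_name: str) -> Atom:
    """Return the unique atom matching (chain, residue number, atom name)."""
    res = model.residues.get((chain_id, res_seq, ""))
    if res is None:
        # tolerate insertion codes when the plain key misses
        matches = [r for key, r in model.residues.items() if key[0] == chain_id and key[1] == res_seq]
        if not matches:
            raise LookupFailure(f"no residue for query ({chain_id!r}, {res_seq}, {atom_name!r})")
        res = matches[0]
    try:
        return res.atom(atom_name)
    except LookupFailure:
        raise LookupFailure(
            f"no atom for query ({chain_id!r}, {res_seq}, {atom_name!r})"
        ) from None


def list_waters(model: StructureModel, chain_id: str) -> list[Residue]:
    """All HOH/WAT residues of a chain, ordered by residue number."""
    waters = [
        res for res in model.residues.values()
        if res.chain_id == chain_id and res.is_water
    ]
    return sorted(waters, key=lambda r: (r.res_seq, r.i_code))
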