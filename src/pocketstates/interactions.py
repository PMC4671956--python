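"""Halogen bonds, hydrogen bonds, and the structural-water network.

Halogen bonds are detected by σ-hole geometry: for a bound halogen X with
carbon C, an acceptor A forms a halogen bond when the X···A distance is
within the cutoff (Bondi van der Waals radius sum by default) and the
C-X···A angle is large enough for A to face the electropositive σ-hole cap
on the extension of the C-X axis. Hydrogen bonds use a heavy-atom distance
criterion only — crystal structures at these resolutions carry no hydrogens,
so no angular term is applied.

The Y220C pocket holds two conserved low-B structural waters: W1 bridges the
backbone carbonyls of Val147 and Asp228 at the subsite-I entrance; W2 sits
centrally, hydrogen-bonded to the Leu145 carbonyl and to Thr230 (either the
side-chain hydroxyl OG1 or the main-chain nitrogen, depending on the chain).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .geometry import angle, distance
from .structio import EmptyInputError, LookupFailure, StructureModel, get_atom, list_waters

__all__ = [
    "BONDI_RADII",
    "XBDistMode",
    "TopologyError",
    "InteractionRecord",
    "WaterSiteRecord",
    "detect_halogen_bonds",
    "detect_hbonds",
    "water_network",
    "water_b_stats",
]

#: Bondi (1964) van der Waals radii, Angstrom
BONDI_RADII = {"O": 1.52, "N": 1.55, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98}

HALOGENS = ("Cl", "Br", "I")
ACCEPTOR_ELEMENTS = ("O", "N", "S")

#: default hydrogen-bond heavy-atom cutoff, Angstrom. The source figures draw
#: hydrogen bonds without stating a numeric cutoff; 3.5 A is a conventional
#: heavy-atom bound and is flagged as an assumption in reports.
DEFAULT_HB_DIST = 3.5

#: default sigma-hole angle threshold, degrees (permissive conventional bound;
#: near-ideal geometry is ~175)
DEFAULT_XB_ANGLE = 140.0

_COVALENT_EXCLUSION = 1.8  # closer pairs are treated as covalently bonded
_CX_BOND_MAX = 2.3  # carbon-halogen covalent search radius


class XBDistMode(str, enum.Enum):
    VDW_SUM = "vdw_sum"
    FIXED = "fixed"


class TopologyError(ValueError):
    """Connectivity needed for a detector is missing or inconsistent."""


AtomId = tuple[str, int, str, str]  # (chain, res_seq, res_name, atom_name)


@dataclass(frozen=True, slots=True)
class InteractionRecord:
    kind: str  # "halogen_bond" | "hydrogen_bond"
    donor_atom: AtomId
    acceptor_atom: AtomId
    distance: float
    angle: float | None = None  # sigma-hole angle for halogen bonds
    water_mediated: bool = False


@dataclass(frozen=True, slots=True)
class WaterSiteRecord:
    water_id: tuple[str, int]
    b_factor: float
    partners: tuple[AtomId, ...]
    bridge_label: str | None = None


def _atom_id(res, atom) -> AtomId:
    return (res.chain_id, res.res_seq, res.res_name, atom.name)


def detect_halogen_bonds(
    model: StructureModel,
    max_dist_mode: XBDistMode | str = XBDistMode.VDW_SUM,
    min_sigma_hole_angle: float = DEFAULT_XB_ANGLE,
    fixed_max_dist: float = 3.5,
) -> list[InteractionRecord]:
    """All halogen bonds X···A with σ-hole angle C-X···A above threshold.

    Halogens (Cl, Br, I) are sought on hetero residues; the bonded carbon is
    the nearest carbon of the same residue within 2.3 Å (absence is a
    topology error). Acceptors are O/N/S heavy atoms of other residues
    (protein or water). The distance cutoff is the Bondi vdW-radius sum of
    the pair for ``vdw_sum`` mode, or ``fixed_max_dist`` for ``fixed``.
    Records are sorted by distance.
    """
    mode = XBDistMode(max_dist_mode)
    records: list[InteractionRecord] = []
    for res, atom in model.iter_atoms():
        if not atom.is_hetero or res.is_water:
            continue
        if atom.element not in HALOGENS:
            continue
        carbons = [a for a in res.atoms if a.element == "C"]
        bonded = None
        best = _CX_BOND_MAX
        for c in carbons:
            d = distance(c.coords, atom.coords)
            if d <= best:
                bonded, best = c, d
        if bonded is None:
            raise TopologyError(
                f"halogen {atom.name} in {res.res_name} {res.chain_id}{res.res_seq} "
                f"has no bonded carbon within {_CX_BOND_MAX} A"
            )
        for ores, oatom in model.iter_atoms():
            if ores is res:
                continue
            if oatom.element not in ACCEPTOR_ELEMENTS:
                continue
            d = distance(atom.coords, oatom.coords)
            if mode is XBDistMode.VDW_SUM:
                cutoff = BONDI_RADII[atom.element] + BONDI_RADII.get(oatom.element, 1.55)
            else:
                cutoff = fixed_max_dist
            if d > cutoff:
                continue
            theta = angle(bonded.coords, atom.coords, oatom.coords)
            if theta < min_sigma_hole_angle:
                continue
            records.append(InteractionRecord(
                kind="halogen_bond",
                donor_atom=_atom_id(res, atom),
                acceptor_atom=_atom_id(ores, oatom),
                distance=d, angle=theta,
            ))
    return sorted(records, key=lambda r: r.distance)


def detect_hbonds(
    model: StructureModel,
    donors: list[tuple] | None = None,
    acceptors: list[tuple] | None = None,
    max_dist: float = DEFAULT_HB_DIST,
) -> list[InteractionRecord]:
    """Heavy-atom hydrogen-bond candidates between donor and acceptor sets.

    ``donors``/``acceptors`` are sequences of (Residue, Atom) pairs; when
    None, all N/O/S heavy atoms of the model are used. A pair is reported
    when its distance is within ``max_dist``, excluding same-residue pairs
    and covalently adjacent pairs (< 1.8 Å). Each unordered pair appears
    once; records are sorted by distance.
    """
    def default_sel():
        return [(res, a) for res, a in model.iter_atoms() if a.element in ACCEPTOR_ELEMENTS]

    dsel = default_sel() if donors is None else list(donors)
    asel = default_sel() if acceptors is None else list(acceptors)

    records: list[InteractionRecord] = []
    seen: set[frozenset] = set()
    for dres, datom in dsel:
        for ares, aatom in asel:
            if dres is ares:
                continue
            did, aid = _atom_id(dres, datom), _atom_id(ares, aatom)
            pair = frozenset((did, aid))
            if pair in seen:
                continue
            d = distance(datom.coords, aatom.coords)
            if d < _COVALENT_EXCLUSION or d > max_dist:
                continue
            seen.add(pair)
            records.append(InteractionRecord(
                kind="hydrogen_bond", donor_atom=did, acceptor_atom=aid,
                distance=d,
                water_mediated=dres.is_water or ares.is_water,
            ))
    return sorted(records, key=lambda r: r.distance)


#: default bridge partners, p53 canonical numbering
W1_PARTNERS = (((147, "O"),), ((228, "O"),))
W2_PARTNERS = (((145, "O"),), ((230, "OG1"), (230, "N")))


def water_network(
    model: StructureModel,
    chain_id: str,
    w1_partners=W1_PARTNERS,
    w2_partners=W2_PARTNERS,
    max_dist: float = DEFAULT_HB_DIST,
) -> list[WaterSiteRecord]:
    """Per-water hydrogen-bond partners plus W1/W2 bridge tags.

    Each partner spec is a pair of "slots"; each slot lists alternative
    (res_seq, atom_name) atoms of ``chain_id`` and is satisfied when the
    water oxygen lies within ``max_dist`` of any listed atom (W2's Thr230
    slot accepts OG1 or N). A water satisfying both slots of a spec is
    bridge-tagged; at most one water per tag wins — smallest summed distance
    to the two slots, ties to the lower residue number.
    """
    def resolve(slots):
        resolved = []
        missing = []
        for slot in slots:
            atoms = []
            for res_seq, name in slot:
                try:
                    atoms.append(((chain_id, res_seq, name),
                                  get_atom(model, chain_id, res_seq, name)))
                except LookupFailure:
                    missing.append(f"{chain_id}/{res_seq}/{name}")
            if not atoms:
                raise LookupFailure(f"bridge partner atoms missing: {missing}")
            resolved.append(atoms)
        return resolved

    w1 = resolve(w1_partners)
    w2 = resolve(w2_partners)

    protein_atoms = [
        (res, a) for res, a in model.iter_atoms()
        if res.chain_id == chain_id and not res.is_water and a.element in ACCEPTOR_ELEMENTS
    ]

    waters = list_waters(model, chain_id)
    partners_of: dict[tuple, tuple] = {}
    records: dict[tuple, WaterSiteRecord] = {}
    best: dict[str, tuple[float, int]] = {}

    def slot_distance(oxygen, slots) -> float | None:
        """Summed water-to-slot distance, or None when any slot is unsatisfied."""
        total = 0.0
        for atoms in slots:
            ds = [distance(oxygen.coords, a.coords) for _, a in atoms]
            dmin = min(ds)
            if dmin > max_dist:
                return None
            total += dmin
        return total

    tagged: dict[str, tuple] = {}
    for water in waters:
        oxygens = [a for a in water.atoms if a.element == "O"]
        if not oxygens:
            continue
        oxy = oxygens[0]
        partners = tuple(
            _atom_id(res, a) for res, a in protein_atoms
            if distance(oxy.coords, a.coords) <= max_dist
        )
        partners_of[water.key] = partners
        for tag, slots in (("W1", w1), ("W2", w2)):
            total = slot_distance(oxy, slots)
            if total is None:
                continue
            cand = (total, water.res_seq)
            if tag not in best or cand < best[tag]:
                best[tag] = cand
                tagged[tag] = water.key

    out = []
    for water in waters:
        oxygens = [a for a in water.atoms if a.element == "O"]
        if not oxygens:
            continue
        label = None
        for tag, key in tagged.items():
            if key == water.key:
                label = tag if label is None else label + "," + tag
        out.append(WaterSiteRecord(
            water_id=(water.chain_id, water.res_seq),
            b_factor=oxygens[0].b_factor,
            partners=partners_of[water.key],
            bridge_label=label,
        ))
    return out


def water_b_stats(model: StructureModel, chain_id: str) -> dict:
    """Min/max/mean B factor over the water oxygens of a chain.

    Returns raw statistics plus integer-rounded min/max (the convention used
    when quoting crystallographic water B-factor ranges).
    """
    bs = []
    for water in list_waters(model, chain_id):
        oxygens = [a for a in water.atoms if a.element == "O"]
        if oxygens:
            bs.append(oxygens[0].b_factor)
    if not bs:
        raise EmptyInputError(f"no waters in chain {chain_id!r}")
    arr = np.asarray(bs)
    return {
        "n": len(bs),
        "min_b": float(arr.min()),
        "max_b": float(arr.max()),
        "mean_b": float(arr.mean()),
        "min_b_int": round(float(arr.min())),
        "max_b_int": round(float(arr.max())),
    }
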