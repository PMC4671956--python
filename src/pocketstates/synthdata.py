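"""Synthetic structures and trajectories for the Y220C pocket pipeline.

Everything the analysis stages consume can be generated here as valid PDB
content: an ideal cysteine fragment at a commanded χ1, a pseudo-atom pocket
fixture realizing commanded width/gate/water/halogen-probe geometry, and a
three-state Markov χ1 trajectory whose stationary distribution is commanded
exactly. The fixtures carry only the atoms the measurements need — they are
deliberately not physically complete proteins, and the trajectory models
state-frequency statistics, not molecular-dynamics kinetics.

The default stationary distribution (0.38, 0.48, 0.14) over (g−, t, g+)
matches the rotamer-cluster populations observed in the 900-ns simulations
of the ligand-free Y220C pocket.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformation import CHI1_WELLS
from .geometry import place_atom
from .structio import (
    Atom,
    EmptyInputError,
    Ensemble,
    EnsembleKind,
    Residue,
    StructureModel,
)

__all__ = [
    "TrajectoryConfig",
    "PocketFixtureConfig",
    "WaterSpec",
    "HalogenProbeSpec",
    "ConstructionError",
    "DEFAULT_STATIONARY",
    "gen_cys_fragment",
    "gen_pocket_fixture",
    "gen_chi1_trajectory",
    "gen_structure_set",
]

#: default stationary distribution over (g-, trans, g+)
DEFAULT_STATIONARY = (0.38, 0.48, 0.14)

#: rotamer well centers in state order (g-, trans, g+), degrees
WELL_CENTERS = (CHI1_WELLS["g_minus"], CHI1_WELLS["trans"], CHI1_WELLS["g_plus"])

# ideal internal coordinates for the cysteine fragment (standard amino-acid
# geometry; correctness is defined by measurement round-trip, not force-field
# fidelity)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_O = 1.231
BOND_CA_CB = 1.530
BOND_CB_SG = 1.810
ANGLE_N_CA_CB = 110.5
ANGLE_CA_CB_SG = 114.4
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_O = 120.5


class ConstructionError(ValueError):
    """A commanded fixture geometry cannot be realized."""


@dataclass(frozen=True, slots=True)
class TrajectoryConfig:
    """Markov χ1 trajectory: n frames, stationary π over (g−, t, g+)."""

    n_frames: int
    stationary: tuple[float, float, float] = DEFAULT_STATIONARY
    stay_prob: float = 0.0
    noise_sd: float = 15.0  # degrees, wrapped-normal spread about well centers
    seed: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.stationary, dtype=float)
        if pi.shape != (3,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("stationary must be 3 probabilities summing to 1")
        if not 0.0 <= self.stay_prob < 1.0:
            raise ValueError("stay_prob must lie in [0, 1)")
        if not 0.0 <= self.noise_sd < 60.0:
            raise ValueError("noise_sd must lie in [0, 60) so wells stay in their bins")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def transition_matrix(self) -> np.ndarray:
        """T(i -> j) = s·[i = j] + (1 − s)·π_j; stationary distribution is exactly π."""
        pi = np.asarray(self.stationary, dtype=float)
        return self.stay_prob * np.eye(3) + (1.0 - self.stay_prob) * np.tile(pi, (3, 1))


@dataclass(frozen=True, slots=True)
class WaterSpec:
    """One water: bridge tag ('W1', 'W2' or 'free'), O-partner distance, B factor."""

    tag: str
    distance: float
    b_factor: float


@dataclass(frozen=True, slots=True)
class HalogenProbeSpec:
    """Two-atom C-X probe aimed at the Leu145 backbone oxygen."""

    element: str = "Br"
    distance: float = 3.0  # X···O, Angstrom
    sigma_hole_angle: float = 174.0  # C-X···O, degrees
    cx_bond: float = 1.90


@dataclass(frozen=True, slots=True)
class PocketFixtureConfig:
    width: float = 7.5  # Thr150 CA - Pro222 CA, Angstrom
    gate: float = 5.0  # Pro151 CD - Pro223 CD
    chi1: float = -60.0
    waters: tuple[WaterSpec, ...] = ()
    halogen_probe: HalogenProbeSpec | None = None
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.gate <= 0:
            raise ValueError("width and gate must be positive")
        if not -180.0 < self.chi1 <= 180.0:
            raise ValueError("chi1 outside (-180, 180]")


def _atom(serial, name, element, coords, b=20.0, occ=1.0, hetero=False) -> Atom:
    return Atom(serial=serial, name=name, element=element, alt_loc="",
                coords=np.asarray(coords, dtype=float), occupancy=occ,
                b_factor=b, is_hetero=hetero)


def gen_cys_fragment(chi1: float, chain_id: str = "A", res_seq: int = 220,
                     origin=(0.0, 0.0, 0.0)) -> StructureModel:
    """Cys residue (N, CA, C, O, CB, SG) built so that measured χ1 == input.

    The backbone is placed in a canonical local frame, the Sγ by
    internal-to-Cartesian construction with ideal bond lengths/angles, and
    the whole fragment translated to ``origin``.
    """
    if not -180.0 < chi1 <= 180.0:
        raise ValueError(f"chi1 {chi1} outside (-180, 180]")
    n = np.zeros(3)
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    # CB in the xy-plane at the ideal N-CA-CB angle
    theta = np.radians(ANGLE_N_CA_CB)
    cb = ca + BOND_CA_CB * np.array([-np.cos(theta), np.sin(theta), 0.0])
    sg = place_atom(n, ca, cb, BOND_CB_SG, ANGLE_CA_CB_SG, chi1)
    # backbone C placed off the N-CA-CB plane, O off C
    c = place_atom(cb, n, ca, BOND_CA_C, ANGLE_N_CA_C, 122.5)
    o = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, 180.0)

    shift = np.asarray(origin, dtype=float)
    res = Residue(chain_id=chain_id, res_seq=res_seq, res_name="CYS")
    for i, (name, element, xyz) in enumerate(
        [("N", "N", n), ("CA", "C", ca), ("C", "C", c),
         ("O", "O", o), ("CB", "C", cb), ("SG", "S", sg)], start=1
    ):
        res.atoms.append(_atom(i, name, element, xyz + shift))
    model = StructureModel(model_no=1, source_label="synthetic")
    model.add_residue(res)
    return model


def _bridge_position(p: np.ndarray, q: np.ndarray, d: float, out_dir: np.ndarray) -> np.ndarray:
    """Point at distance d from both p and q, offset along out_dir from the midpoint."""
    mid = 0.5 * (p + q)
    half = 0.5 * np.linalg.norm(q - p)
    if d < half:
        raise ConstructionError(
            f"water distance {d} A infeasible for partners {2 * half:.2f} A apart"
        )
    h = np.sqrt(d * d - half * half)
    axis = (q - p) / (2 * half) if half > 0 else np.array([1.0, 0.0, 0.0])
    # component of out_dir perpendicular to the partner axis
    perp = out_dir - np.dot(out_dir, axis) * axis
    norm = np.linalg.norm(perp)
    if norm < 1e-9:
        raise ConstructionError("degenerate bridge offset direction")
    return mid + h * perp / norm


def gen_pocket_fixture(config: PocketFixtureConfig) -> StructureModel:
    """Pseudo-atom Y220C pocket realizing every commanded scalar exactly.

    Emits the metric/interaction anchor atoms (Thr150 CA, Pro151 CD,
    Leu145 O, Val147 O, Pro222 CA, Pro223 CD, Asp228 O, Thr230 OG1/N), a
    Cys220 fragment at the commanded χ1, bridge waters at commanded
    distances from their partner sets, and an optional C-X halogen probe
    with exact X···O(Leu145) distance and C-X···O σ-hole angle.
    """
    ch = config.chain_id
    model = StructureModel(model_no=1, source_label="synthetic")

    # anchor pseudo-atoms; layout chosen so all commanded distances decouple
    thr150_ca = np.array([0.0, 0.0, 0.0])
    pro222_ca = np.array([config.width, 0.0, 0.0])
    pro151_cd = np.array([0.0, 5.0, 0.0])
    pro223_cd = np.array([config.gate, 5.0, 0.0])
    leu145_o = np.array([3.0, -6.0, 0.0])
    val147_o = np.array([2.0, -3.0, 4.0])
    asp228_o = np.array([4.8, -3.0, 4.0])
    thr230_og1 = np.array([6.5, -6.0, 1.0])
    thr230_n = np.array([7.8, -6.5, 0.2])

    serial = 1

    def add(res_seq, res_name, atoms):
        nonlocal serial
        res = Residue(chain_id=ch, res_seq=res_seq, res_name=res_name)
        for name, element, xyz, *rest in atoms:
            b = rest[0] if rest else 20.0
            hetero = rest[1] if len(rest) > 1 else False
            res.atoms.append(_atom(serial, name, element, xyz, b=b, hetero=hetero))
            serial += 1
        model.add_residue(res)

    add(145, "LEU", [("O", "O", leu145_o)])
    add(147, "VAL", [("O", "O", val147_o)])
    add(150, "THR", [("CA", "C", thr150_ca)])
    add(151, "PRO", [("CD", "C", pro151_cd)])
    add(222, "PRO", [("CA", "C", pro222_ca)])
    add(223, "PRO", [("CD", "C", pro223_cd)])
    add(228, "ASP", [("O", "O", asp228_o)])
    add(230, "THR", [("OG1", "O", thr230_og1), ("N", "N", thr230_n)])

    # Cys220 fragment translated clear of the anchors (translation preserves chi1)
    cys = gen_cys_fragment(config.chi1, chain_id=ch, res_seq=220,
                           origin=(config.width / 2.0, -2.0, -5.0))
    for res in cys.residues.values():
        for a in res.atoms:
            a.serial = serial
            serial += 1
        model.add_residue(res)

    # bridge waters
    water_seq = 501
    for spec in config.waters:
        if spec.tag == "W1":
            pos = _bridge_position(val147_o, asp228_o, spec.distance,
                                   np.array([0.0, -0.3, 1.0]))
        elif spec.tag == "W2":
            pos = _bridge_position(leu145_o, thr230_og1, spec.distance,
                                   np.array([0.0, -1.0, 0.3]))
        elif spec.tag == "free":
            pos = np.array([-8.0 - spec.distance, 10.0, 8.0])
        else:
            raise ConstructionError(f"unknown water tag {spec.tag!r}")
        add(water_seq, "HOH", [("O", "O", pos, spec.b_factor, True)])
        water_seq += 1

    # halogen probe: X on a ray from Leu145 O, C making the sigma-hole angle at X
    if config.halogen_probe is not None:
        probe = config.halogen_probe
        v = np.array([0.0, -1.0, 0.0])  # O -> X direction
        x_pos = leu145_o + probe.distance * v
        e = np.array([1.0, 0.0, 0.0])  # perpendicular to v
        phi = np.radians(probe.sigma_hole_angle)
        # direction from X making angle sigma_hole with (O - X) = -v
        w = np.cos(phi) * (-v) + np.sin(phi) * e
        c_pos = x_pos + probe.cx_bond * w
        add(901, "LIG", [("C1", "C", c_pos, 20.0, True),
                         (probe.element.upper(), probe.element.capitalize(),
                          x_pos, 20.0, True)])

    return model


@dataclass(frozen=True, slots=True)
class TrajectoryResult:
    chi1: np.ndarray  # degrees, (-180, 180]
    states: np.ndarray  # hidden state index per frame: 0=g-, 1=t, 2=g+
    ensemble: Ensemble | None  # cysteine-fragment frames, None if not built


def _wrap_angle(deg: np.ndarray) -> np.ndarray:
    """Wrap into (-180, 180]."""
    wrapped = np.mod(deg + 180.0, 360.0) - 180.0
    wrapped[wrapped == -180.0] = 180.0
    return wrapped


def gen_chi1_trajectory(config: TrajectoryConfig, build_frames: bool = True) -> TrajectoryResult:
    """Sample a three-state Markov χ1 trajectory.

    The hidden state sequence follows T(i→j) = s·[i=j] + (1−s)·π_j with the
    first state drawn from π, so the chain is stationary from frame 0 and
    its stationary distribution equals π for any stay probability s. Emitted
    χ1 = well center of the state plus wrapped-normal noise. With
    ``build_frames`` the frames are realized as cysteine-fragment models in
    a trajectory Ensemble; classification only needs the χ1 series, so large
    runs may skip frame construction.
    """
    rng = np.random.default_rng(config.seed)
    pi = np.asarray(config.stationary, dtype=float)
    n = config.n_frames
    s = config.stay_prob

    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(3, p=pi)
    if s == 0.0:
        if n > 1:
            states[1:] = rng.choice(3, size=n - 1, p=pi)
    else:
        stay = rng.random(n - 1) < s
        redraw = rng.choice(3, size=n - 1, p=pi)
        for t in range(1, n):
            states[t] = states[t - 1] if stay[t - 1] else redraw[t - 1]

    centers = np.asarray(WELL_CENTERS)
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
    chi1 = _wrap_angle(centers[states] + noise)

    ensemble = None
    if build_frames:
        models = []
        for i, x in enumerate(chi1):
            frame = gen_cys_fragment(float(x))
            frame.model_no = i + 1
            frame.source_label = "synthetic"
            models.append(frame)
        ensemble = Ensemble(models=models, kind=EnsembleKind.TRAJECTORY)
    return TrajectoryResult(chi1=chi1, states=states, ensemble=ensemble)


def gen_structure_set(widths, gate: float = 5.0, chi1: float = 180.0) -> Ensemble:
    """One pocket fixture per commanded width, as a crystal-set ensemble."""
    widths = list(widths)
    if not widths:
        raise EmptyInputError("gen_structure_set requires at least one width")
    models = []
    for i, w in enumerate(widths):
        model = gen_pocket_fixture(PocketFixtureConfig(width=float(w), gate=gate, chi1=chi1))
        model.model_no = i + 1
        model.source_label = f"synthetic-w{w:g}"
        models.append(model)
    return Ensemble(models=models, kind=EnsembleKind.CRYSTAL_SET)
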