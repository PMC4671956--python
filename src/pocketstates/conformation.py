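"""Cys220 rotamer analysis: χ1 angles, state calls, populations, clustering.

The gate residue of the Y220C subsite-III pocket is Cys220: its χ1 dihedral
(N-Cα-Cβ-Sγ) switches between the three staggered rotamers gauche(−) (well
at −60°), trans (±180°) and gauche(+) (+60°). The gauche(−) rotamer opens
the transient hydrophobic subpocket (subsite III); trans closes it;
gauche(+) is never seen crystallographically and carries no pocket-state
assignment.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .geometry import dihedral
from .structio import EmptyInputError, StructureModel, get_atom

__all__ = [
    "RotamerState",
    "Subsite3State",
    "Chi1Record",
    "PopulationSummary",
    "ClusterSummary",
    "CHI1_WELLS",
    "chi1_of",
    "classify_rotamer",
    "subsite3_state",
    "population_stats",
    "cluster_frames",
]

logger = logging.getLogger(__name__)

#: rotamer well centers, degrees
CHI1_WELLS = {"g_minus": -60.0, "trans": 180.0, "g_plus": 60.0}


class RotamerState(str, enum.Enum):
    G_MINUS = "g_minus"
    TRANS = "trans"
    G_PLUS = "g_plus"


class Subsite3State(str, enum.Enum):
    OPEN = "open"
    CLOSED = "closed"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True, slots=True)
class Chi1Record:
    frame_index: int
    chi1: float  # degrees, (-180, 180]
    rotamer: RotamerState
    subsite3: Subsite3State

    @classmethod
    def from_chi1(cls, frame_index: int, chi1: float) -> "Chi1Record":
        rot = classify_rotamer(chi1)
        return cls(frame_index=frame_index, chi1=chi1, rotamer=rot,
                   subsite3=subsite3_state(rot))


@dataclass(frozen=True, slots=True)
class PopulationSummary:
    n_frames: int
    pct_g_minus: float
    pct_trans: float
    pct_g_plus: float

    def as_dict(self) -> dict[str, float]:
        return {"g_minus": self.pct_g_minus, "trans": self.pct_trans,
                "g_plus": self.pct_g_plus}


@dataclass(frozen=True, slots=True)
class ClusterSummary:
    k: int
    labels: np.ndarray  # per-frame cluster id
    representatives: tuple[int, ...]  # per-cluster medoid frame index
    feature_names: tuple[str, ...]


def chi1_of(
    model: StructureModel,
    chain_id: str,
    res_seq: int,
    atom_names: Sequence[str] = ("N", "CA", "CB", "SG"),
) -> float:
    """χ1 dihedral (degrees) over the named atom quartet of one residue.

    Default quartet is the cysteine N-Cα-Cβ-Sγ; pass e.g. (..., "OG1") for a
    threonine. Raises a lookup error when any atom is absent.
    """
    coords = [get_atom(model, chain_id, res_seq, name).coords for name in atom_names]
    return dihedral(*coords)


def classify_rotamer(chi1: float) -> RotamerState:
    """Bin a χ1 angle into g−/t/g+.

    Half-open bins with edges at the midpoints between the staggered wells:
    g− = [−120, 0), g+ = [0, 120), trans = [120, 180] ∪ (−180, −120).
    """
    if not -180.0 < chi1 <= 180.0 or not np.isfinite(chi1):
        raise ValueError(f"chi1 {chi1} outside (-180, 180]")
    if -120.0 <= chi1 < 0.0:
        return RotamerState.G_MINUS
    if 0.0 <= chi1 < 120.0:
        return RotamerState.G_PLUS
    return RotamerState.TRANS


def subsite3_state(rotamer: RotamerState) -> Subsite3State:
    """Pocket-state call implied by the Cys220 rotamer.

    gauche(−) opens subsite III, trans closes it; gauche(+) is unassigned
    (never observed in a crystal structure, no state defined for it).
    """
    return {
        RotamerState.G_MINUS: Subsite3State.OPEN,
        RotamerState.TRANS: Subsite3State.CLOSED,
        RotamerState.G_PLUS: Subsite3State.UNASSIGNED,
    }[RotamerState(rotamer)]


def population_stats(records: Sequence[Chi1Record]) -> PopulationSummary:
    """Percentage of frames in each rotamer state; percentages sum to 100."""
    n = len(records)
    if n == 0:
        raise EmptyInputError("population_stats requires at least one frame")
    counts = {state: 0 for state in RotamerState}
    for rec in records:
        counts[RotamerState(rec.rotamer)] += 1
    return PopulationSummary(
        n_frames=n,
        pct_g_minus=100.0 * counts[RotamerState.G_MINUS] / n,
        pct_trans=100.0 * counts[RotamerState.TRANS] / n,
        pct_g_plus=100.0 * counts[RotamerState.G_PLUS] / n,
    )


def classify_series(chi1_series: Sequence[float]) -> list[Chi1Record]:
    """Chi1Record per frame of a χ1 time series."""
    return [Chi1Record.from_chi1(i, float(x)) for i, x in enumerate(chi1_series)]


def cluster_frames(features: np.ndarray, k: int, seed: int,
                   feature_names: Sequence[str] | None = None) -> ClusterSummary:
    """Seeded k-means clustering of per-frame pocket features.

    Features are standardized internally (zero mean, unit variance per
    column); zero-variance columns are dropped with a warning. Angular
    features must be supplied already encoded as (cos, sin) pairs — see
    :func:`trajectory_features`. The per-cluster representative is the
    medoid: the member frame nearest its cluster center.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a frame x feature matrix")
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, n_frames={n}]")
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"f{j}" for j in range(X.shape[1]))

    std = X.std(axis=0)
    keep = std > 1e-12
    if not np.all(keep):
        dropped = [names[j] for j in np.nonzero(~keep)[0]]
        logger.warning("dropping zero-variance features: %s", dropped)
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    Xs = X[:, keep]
    if Xs.shape[1] == 0:
        # all features constant: everything is one point; assign cluster 0..k-1
        labels = np.zeros(n, dtype=int)
        labels[:k] = np.arange(k)
        reps = tuple(int(np.nonzero(labels == c)[0][0]) for c in range(k))
        return ClusterSummary(k=k, labels=labels, representatives=reps,
                              feature_names=tuple(np.array(names)[keep]))
    Xs = (Xs - Xs.mean(axis=0)) / Xs.std(axis=0)

    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=500,
                tol=1e-8, random_state=seed)
    labels = km.fit_predict(Xs)
    reps = []
    for c in range(k):
        members = np.nonzero(labels == c)[0]
        d2 = np.sum((Xs[members] - km.cluster_centers_[c]) ** 2, axis=1)
        reps.append(int(members[np.argmin(d2)]))
    return ClusterSummary(k=k, labels=labels, representatives=tuple(reps),
                          feature_names=tuple(np.array(names)[keep]))


def trajectory_features(chi1_series: Sequence[float],
                        widths: Sequence[float] | None = None,
                        gates: Sequence[float] | None = None) -> tuple[np.ndarray, tuple[str, ...]]:
    """Build the default clustering feature matrix.

    χ1 is encoded circularly as (cos χ1, sin χ1); pocket width
    (Thr150Cα-Pro222Cα) and proline gate (Pro151Cδ-Pro223Cδ) columns are
    appended when available.
    """
    chi = np.radians(np.asarray(chi1_series, dtype=float))
    cols = [np.cos(chi), np.sin(chi)]
    names = ["cos_chi1", "sin_chi1"]
    if widths is not None:
        cols.append(np.asarray(widths, dtype=float))
        names.append("pocket_width")
    if gates is not None:
        cols.append(np.asarray(gates, dtype=float))
        names.append("proline_gate")
    return np.column_stack(cols), tuple(names)
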