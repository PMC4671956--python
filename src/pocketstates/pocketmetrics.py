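"""Named pocket-geometry metrics and their ensemble/trajectory summaries.

Two distances characterize the width of the Y220C surface crevice: the
Thr150 Cα - Pro222 Cα separation at the rim (the "pocket width", spanning
the rigid S3/S4 loop and the mobile S7/S8 loop) and the Pro151 Cδ -
Pro223 Cδ separation (the "proline gate", which closes when the S3/S4 loop
collapses into the pocket). Metric definitions are data, so the machinery
generalizes to other residue pairs or pockets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import distance
from .structio import Ensemble, EmptyInputError, LookupFailure, StructureModel, get_atom

__all__ = [
    "MetricDefinition",
    "PocketWidthRecord",
    "EnsembleSummary",
    "POCKET_WIDTH",
    "PROLINE_GATE",
    "DEFAULT_METRICS",
    "evaluate_metric",
    "pocket_width",
    "proline_gate",
    "ensemble_metric_summary",
    "trajectory_timeseries",
]


@dataclass(frozen=True, slots=True)
class MetricDefinition:
    """An inter-atomic distance metric named for reporting."""

    name: str
    atom_a: tuple[int, str]  # (res_seq, atom_name)
    atom_b: tuple[int, str]

    def __post_init__(self) -> None:
        if self.atom_a == self.atom_b:
            raise ValueError("metric atoms must be distinct")


POCKET_WIDTH = MetricDefinition("pocket_width", (150, "CA"), (222, "CA"))
PROLINE_GATE = MetricDefinition("proline_gate", (151, "CD"), (223, "CD"))
DEFAULT_METRICS = (POCKET_WIDTH, PROLINE_GATE)


@dataclass(frozen=True, slots=True)
class PocketWidthRecord:
    model_label: str
    chain_id: str
    metric_name: str
    value: float  # Angstrom

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"metric value must be positive, got {self.value}")


@dataclass(frozen=True, slots=True)
class EnsembleSummary:
    metric_name: str
    n: int
    min: float
    max: float
    mean: float
    records: tuple[PocketWidthRecord, ...] = field(default=())
    failures: tuple[str, ...] = field(default=())


def evaluate_metric(model: StructureModel, chain_id: str, metric: MetricDefinition) -> float:
    a = get_atom(model, chain_id, metric.atom_a[0], metric.atom_a[1])
    b = get_atom(model, chain_id, metric.atom_b[0], metric.atom_b[1])
    return distance(a.coords, b.coords)


def pocket_width(model: StructureModel, chain_id: str) -> float:
    """Thr150 Cα - Pro222 Cα distance (Å); report to 1 decimal in summaries."""
    return evaluate_metric(model, chain_id, POCKET_WIDTH)


def proline_gate(model: StructureModel, chain_id: str) -> float:
    """Pro151 Cδ - Pro223 Cδ distance (Å)."""
    return evaluate_metric(model, chain_id, PROLINE_GATE)


def ensemble_metric_summary(
    ensemble: Ensemble,
    metric: MetricDefinition,
    chains: list[str] | None = None,
) -> EnsembleSummary:
    """Per-model metric values plus min/max/mean over an ensemble.

    Every (model, chain) observation counts separately (per-chain
    accounting). ``chains=None`` evaluates every chain of every model;
    unresolvable pairs are collected and reported in the error, never
    silently dropped.
    """
    records: list[PocketWidthRecord] = []
    failures: list[str] = []
    for i, model in enumerate(ensemble.models):
        label = model.source_label or f"model{model.model_no}"
        model_chains = chains if chains is not None else model.chains()
        for chain in model_chains:
            try:
                value = evaluate_metric(model, chain, metric)
            except LookupFailure as exc:
                failures.append(f"{label}/{chain}: {exc}")
                continue
            records.append(PocketWidthRecord(
                model_label=f"{label}#{i}" if label else f"#{i}",
                chain_id=chain, metric_name=metric.name, value=value,
            ))
    if not records:
        raise EmptyInputError(
            f"metric {metric.name!r} resolved in zero (model, chain) pairs; "
            f"failures: {failures}"
        )
    records.sort(key=lambda r: (r.model_label, r.chain_id))
    values = np.array([r.value for r in records])
    return EnsembleSummary(
        metric_name=metric.name, n=len(records),
        min=float(values.min()), max=float(values.max()), mean=float(values.mean()),
        records=tuple(records), failures=tuple(failures),
    )


def trajectory_timeseries(
    ensemble: Ensemble,
    metrics: list[MetricDefinition],
    chain_id: str,
    reference: EnsembleSummary | dict[str, EnsembleSummary] | None = None,
) -> pd.DataFrame:
    """Frame-by-frame metric table for a trajectory ensemble.

    One row per frame (column ``frame``), one column per metric. When a
    crystal-reference summary is supplied, its min/max bounds are attached
    as ``df.attrs["reference_bounds"]`` (metric -> (min, max)) so plots can
    draw the crystallographically observed range. Frames missing a metric
    atom raise a topology error naming the first offending frame.
    """
    rows = []
    for i, model in enumerate(ensemble.models):
        row = {"frame": i}
        for metric in metrics:
            try:
                row[metric.name] = evaluate_metric(model, chain_id, metric)
            except LookupFailure as exc:
                from .interactions import TopologyError
                raise TopologyError(f"frame {i}: {exc}") from exc
        rows.append(row)
    df = pd.DataFrame(rows, columns=["frame"] + [m.name for m in metrics])
    bounds: dict[str, tuple[float, float]] = {}
    if reference is not None:
        refs = reference if isinstance(reference, dict) else {reference.metric_name: reference}
        for name, summ in refs.items():
            bounds[name] = (summ.min, summ.max)
    df.attrs["reference_bounds"] = bounds
    return df
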