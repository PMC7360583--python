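"""Morphometric measurements of the vectorial network model.

Per image (tube formation, ETFA): mean mesh size MMS, total mesh area
TMA, total segment length TSL, junction count JN and total length TL
(branches + segments).  Per bead (fibrin bead assay, FBA): TSL/S, JN/S,
TL/S and the anchorage-junction count AJN/S, one record per detected
sphere so that every microbead acts as an independent replicate.  All
lengths and areas are in pixels unless a pixels-per-micron calibration is
supplied, in which case values are converted at output time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph import NetworkGraph

__all__ = [
    "MeasurementRecord",
    "BatchSummary",
    "measure_etfa",
    "measure_fba",
    "summarize_batch",
    "records_to_frame",
]

ETFA_COLUMNS = ["image_id", "MMS", "TMA", "TSL", "JN", "TL", "no_meshes"]
FBA_COLUMNS = ["image_id", "sphere_id", "TSL_S", "JN_S", "TL_S", "AJN_S",
               "AJN_JN_S"]


@dataclass(frozen=True)
class MeasurementRecord:
    """Measurements for one image (ETFA) or one sphere (FBA)."""

    image_id: str = ""
    sphere_id: int | None = None
    MMS: float = 0.0
    TMA: float = 0.0
    TSL: float = 0.0
    JN: int = 0
    TL: float = 0.0
    AJN: int = 0
    no_meshes: bool = False
    flags: tuple[str, ...] = ()

    @property
    def AJN_plus_JN(self) -> float:
        return self.AJN + self.JN

    def calibrated(self, pixels_per_micron: float | None) -> "MeasurementRecord":
        """Convert lengths to microns and areas to square microns."""
        if not pixels_per_micron:
            return self
        f = 1.0 / pixels_per_micron
        return MeasurementRecord(
            image_id=self.image_id, sphere_id=self.sphere_id,
            MMS=self.MMS * f * f, TMA=self.TMA * f * f,
            TSL=self.TSL * f, JN=self.JN, TL=self.TL * f,
            AJN=self.AJN, no_meshes=self.no_meshes, flags=self.flags)


@dataclass(frozen=True)
class BatchSummary:
    group: str
    parameter: str
    mean: float
    sem: float
    n: int
    flags: tuple[str, ...] = ()


def _sum_lengths(g: NetworkGraph, kinds: set[str]) -> float:
    return float(sum(e.length for e in g.edges.values() if e.kind in kinds))


def measure_etfa(g: NetworkGraph, image_id: str = "") -> MeasurementRecord:
    """Whole-image measurements for a tube-formation network."""
    areas = [m.area for m in g.meshes]
    tma = float(sum(areas))
    mms = tma / len(areas) if areas else 0.0
    return MeasurementRecord(
        image_id=image_id,
        MMS=mms,
        TMA=tma,
        TSL=_sum_lengths(g, {"segment"}),
        JN=len(g.junctions),
        TL=_sum_lengths(g, {"segment", "branch"}),
        no_meshes=not areas,
    )


def _sphere_of_component(g: NetworkGraph, component) -> tuple[int | None, list[str]]:
    """Associate a connected object group with a bead.

    An anchorage junction pins the group to its circle; a group touching
    two circles is assigned to the nearest circle center and flagged.
    """
    flags: list[str] = []
    anchored = sorted({g.junctions[ref].circle_index
                       for kind, ref in component
                       if kind == "junction" and ref in g.junctions
                       and g.junctions[ref].is_anchorage
                       and g.junctions[ref].circle_index is not None})
    if len(anchored) > 1:
        flags.append("multi_sphere")
    if anchored:
        return anchored[0] if len(anchored) == 1 else _nearest(g, component), flags
    if g.circles:
        return _nearest(g, component), flags
    return None, flags


def _nearest(g: NetworkGraph, component) -> int:
    pts = []
    for kind, ref in component:
        if kind == "junction" and ref in g.junctions:
            pts.append(g.junctions[ref].centroid)
        elif kind == "extremity" and ref in g.extremities:
            x = g.extremities[ref]
            pts.append((float(x.y), float(x.x)))
    cy = float(np.mean([p[0] for p in pts]))
    cx = float(np.mean([p[1] for p in pts]))
    dists = [math.hypot(cy - c.cy, cx - c.cx) for c in g.circles]
    return int(np.argmin(dists))


def measure_fba(g: NetworkGraph, image_id: str = "") -> list[MeasurementRecord]:
    """Per-sphere measurements for a fibrin-bead network.

    Each connected group of junctions/edges is assigned to its anchoring
    bead; beads with no sprouts still produce an all-zero record, since
    each microbead is a little local experiment of its own.
    """
    if not g.circles:
        raise ValueError("FBA measurement needs at least one detected circle")
    nxg = g.to_networkx()
    per_sphere: dict[int, dict] = {
        i: {"TSL": 0.0, "TL": 0.0, "JN": 0, "AJN": 0, "flags": set()}
        for i in range(len(g.circles))}
    for component in nx.connected_components(nxg):
        sphere, flags = _sphere_of_component(g, component)
        if sphere is None:
            continue
        acc = per_sphere[sphere]
        acc["flags"].update(flags)
        edge_ids = {k for u, v, k in nxg.subgraph(component).edges(keys=True)}
        for eid in edge_ids:
            e = g.edges[eid]
            if e.kind == "segment":
                acc["TSL"] += e.length
                acc["TL"] += e.length
            elif e.kind == "branch":
                acc["TL"] += e.length
        for kind, ref in component:
            if kind == "junction" and ref in g.junctions:
                if g.junctions[ref].is_anchorage:
                    acc["AJN"] += 1
                else:
                    acc["JN"] += 1
    return [
        MeasurementRecord(image_id=image_id, sphere_id=i,
                          TSL=acc["TSL"], JN=acc["JN"], TL=acc["TL"],
                          AJN=acc["AJN"], flags=tuple(sorted(acc["flags"])))
        for i, acc in sorted(per_sphere.items())
    ]


def records_to_frame(records: list[MeasurementRecord],
                     mode: str) -> pd.DataFrame:
    """Tabulate records with the standard abbreviation column names."""
    if mode.upper() == "ETFA":
        rows = [{"image_id": r.image_id, "MMS": r.MMS, "TMA": r.TMA,
                 "TSL": r.TSL, "JN": r.JN, "TL": r.TL,
                 "no_meshes": r.no_meshes} for r in records]
        return pd.DataFrame(rows, columns=ETFA_COLUMNS)
    rows = [{"image_id": r.image_id, "sphere_id": r.sphere_id,
             "TSL_S": r.TSL, "JN_S": r.JN, "TL_S": r.TL, "AJN_S": r.AJN,
             "AJN_JN_S": r.AJN_plus_JN} for r in records]
    return pd.DataFrame(rows, columns=FBA_COLUMNS)


def summarize_batch(records: list[MeasurementRecord],
                    grouping: dict[str, str] | None = None,
                    parameters: tuple[str, ...] = ("TSL", "JN", "TL", "AJN",
                                                   "MMS", "TMA"),
                    ) -> list[BatchSummary]:
    """Group means with SEM (sd / sqrt(n), sample sd).

    ``grouping`` maps image_id to a condition label; unmapped records fall
    in the "all" group.  A single-record group reports SEM 0 with an
    ``n=1`` flag.
    """
    groups: dict[str, list[MeasurementRecord]] = {}
    for r in records:
        label = (grouping or {}).get(r.image_id, "all")
        groups.setdefault(label, []).append(r)
    out: list[BatchSummary] = []
    for label in sorted(groups):
        for param in parameters:
            values = np.array([getattr(r, param) for r in groups[label]],
                              dtype=float)
            n = values.size
            if n == 0:
                continue
            mean = float(values.mean())
            if n == 1:
                out.append(BatchSummary(group=label, parameter=param,
                                        mean=mean, sem=0.0, n=1,
                                        flags=("n=1",)))
            else:
                sem = float(values.std(ddof=1) / math.sqrt(n))
                out.append(BatchSummary(group=label, parameter=param,
                                        mean=mean, sem=sem, n=n))
    return out
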