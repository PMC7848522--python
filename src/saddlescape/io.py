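"""File formats and run manifests.

Landscapes travel as JSON (``{"types": [{"id", "fitness"}], "edges":
[[a, b]]}``) or as a directory of two TSVs (``nodes.tsv``: id, fitness;
``edges.tsv``: id_a, id_b).  Trajectories are TSV time series (grid format:
time plus one fraction column per type; event format: time, kind, source,
target).  Every simulation output is accompanied by a JSON run manifest
echoing the full configuration, seed, stop reason and final state, so any
numeric file can be traced to the run that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import LandscapeError, TypeGraph, build_landscape
from .moran import JumpEvent, Trajectory

__all__ = [
    "read_landscape",
    "write_landscape",
    "write_trajectory",
    "read_trajectory_grid",
    "read_trajectory_events",
    "write_manifest",
    "RunConfig",
]


def _package_version() -> str:
    try:
        return version("saddlescape")
    except PackageNotFoundError:  # editable/dev tree
        return "unknown"


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------

def write_landscape(graph: TypeGraph, path, fmt: str = "json") -> None:
    """Write a landscape as JSON (single file) or TSV (``path`` becomes a
    directory holding nodes.tsv and edges.tsv).  Round-trips losslessly."""
    path = Path(path)
    edges = sorted(
        (min(a, b, key=graph.index), max(a, b, key=graph.index))
        for a, b in graph.graph.edges()
    )
    if fmt == "json":
        doc = {
            "types": [
                {"id": t, "fitness": float(graph.fitness[i])}
                for i, t in enumerate(graph.type_ids)
            ],
            "edges": [[a, b] for a, b in edges],
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
    elif fmt == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"id": graph.type_ids, "fitness": graph.fitness}
        ).to_csv(path / "nodes.tsv", sep="\t", index=False)
        pd.DataFrame(edges, columns=["id_a", "id_b"]).to_csv(
            path / "edges.tsv", sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown landscape format {fmt!r}")


def read_landscape(path) -> TypeGraph:
    """Read a landscape from JSON or a nodes.tsv/edges.tsv directory,
    propagating the structural validation of :func:`build_landscape`."""
    path = Path(path)
    if path.is_dir():
        nodes = pd.read_csv(path / "nodes.tsv", sep="\t", dtype={"id": str})
        for col in ("id", "fitness"):
            if col not in nodes.columns:
                raise LandscapeError(f"nodes.tsv is missing column '{col}'")
        edges_path = path / "edges.tsv"
        edge_list = []
        if edges_path.exists():
            edges = pd.read_csv(edges_path, sep="\t", dtype=str)
            for col in ("id_a", "id_b"):
                if col not in edges.columns:
                    raise LandscapeError(f"edges.tsv is missing column '{col}'")
            edge_list = list(edges[["id_a", "id_b"]].itertuples(index=False, name=None))
        return build_landscape(
            list(nodes["id"]),
            dict(zip(nodes["id"], nodes["fitness"])),
            edge_list,
        )

    doc = json.loads(path.read_text())
    if "types" not in doc:
        raise LandscapeError("landscape JSON is missing the 'types' key")
    ids, fitness = [], {}
    for entry in doc["types"]:
        if "id" not in entry or "fitness" not in entry:
            raise LandscapeError(
                "each entry of 'types' needs 'id' and 'fitness' fields"
            )
        ids.append(entry["id"])
        fitness[entry["id"]] = entry["fitness"]
    edges = doc.get("edges", [])
    for e in edges:
        if len(e) != 2:
            raise LandscapeError(f"malformed entry in 'edges': {e!r}")
    return build_landscape(ids, fitness, [tuple(e) for e in edges])


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory(trajectory: Trajectory, path, fmt: str = "tsv-grid") -> None:
    """Write a trajectory time series.

    ``tsv-grid``: header ``time`` + one fraction column per type id, one row
    per snapshot (an event-recorded trajectory degrades to its initial and
    final states).  ``tsv-events``: columns time, kind, source, target.
    """
    path = Path(path)
    if fmt == "tsv-grid":
        if trajectory.counts is not None:
            times = trajectory.times
            frac = trajectory.fractions()
        else:  # no snapshots: emit initial and final states
            times = np.array([0.0, trajectory.t_end])
            frac = (
                np.vstack([trajectory.initial_counts, trajectory.final_counts])
                / trajectory.N
            )
        df = pd.DataFrame(frac, columns=list(trajectory.type_ids))
        df.insert(0, "time", times)
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    elif fmt == "tsv-events":
        if trajectory.events is None:
            raise ValueError("trajectory has no event records")
        df = pd.DataFrame(
            [
                {"time": e.time, "kind": e.kind, "source": e.source, "target": e.target}
                for e in trajectory.events
            ],
            columns=["time", "kind", "source", "target"],
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def read_trajectory_grid(path, graph: TypeGraph, N: int) -> Trajectory:
    """Read a tsv-grid trajectory back into memory (fractions are rescaled
    to integer counts at resolution 1/N)."""
    df = pd.read_csv(path, sep="\t")
    missing = [t for t in graph.type_ids if str(t) not in df.columns]
    if missing:
        raise ValueError(f"trajectory file lacks columns for types {missing}")
    frac = df[[str(t) for t in graph.type_ids]].to_numpy()
    counts = np.rint(frac * N).astype(np.int64)
    times = df["time"].to_numpy(dtype=float)
    return Trajectory(
        type_ids=graph.type_ids,
        N=N,
        lam=float("nan"),
        initial_counts=counts[0],
        final_counts=counts[-1],
        t_end=float(times[-1]),
        stop_reason="loaded",
        seed=-1,
        times=times,
        counts=counts,
    )


def read_trajectory_events(path) -> list[JumpEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    return [
        JumpEvent(time=float(r.time), kind=r.kind, source=r.source, target=r.target)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# run configuration and manifests
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Fully serializable description of one simulation run."""

    landscape: str
    N: int
    lam: float
    initial_state: str
    t_max: float
    seed: int
    recording: str = "grid"
    epsilon: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)


def write_manifest(trajectory: Trajectory, path, extra: dict | None = None) -> None:
    """JSON manifest: config echo, seed, stop reason, final state, version."""
    doc = {
        "version": _package_version(),
        "config": trajectory.config,
        "seed": trajectory.seed,
        "stop_reason": trajectory.stop_reason,
        "t_end": trajectory.t_end,
        "n_events": trajectory.n_events,
        "final_state": {
            t: int(c)
            for t, c in zip(trajectory.type_ids, trajectory.final_counts)
            if c > 0
        },
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1, default=str) + "\n")
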