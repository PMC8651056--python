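"""Result export: CSV trajectories, TSV tables, JSON summaries.

The JSON summary is complete enough to reload for downstream filtering
(last-state distribution, fixed points, settings echo); the CSV/TSV
files are the plotting-friendly flat views.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from ..engine import SimulationResult, SimulationSettings
from ..model import InitialStateDistribution, MutationSpec

__all__ = [
    "write_result_files",
    "result_to_json_dict",
    "result_summary_from_json",
]


def write_result_files(result: SimulationResult, directory: str | Path) -> list[Path]:
    """Write the four tabular views plus the JSON summary; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []

    p = directory / "state_probabilities.csv"
    result.state_probabilities.to_csv(p, index_label="time")
    paths.append(p)

    p = directory / "node_probabilities.csv"
    result.node_probabilities.to_csv(p, index_label="time")
    paths.append(p)

    p = directory / "last_states.tsv"
    with open(p, "w") as fh:
        fh.write("state\tprobability\n")
        for label, prob in sorted(
            result.last_state_distribution.items(), key=lambda kv: -kv[1]
        ):
            fh.write(f"{label}\t{prob!r}\n")
    paths.append(p)

    p = directory / "fixed_points.tsv"
    result.fixed_points.to_csv(p, sep="\t", index=False)
    paths.append(p)

    p = directory / "result.json"
    with open(p, "w") as fh:
        json.dump(result_to_json_dict(result), fh, indent=2)
    paths.append(p)
    return paths


def _settings_dict(settings: SimulationSettings) -> dict:
    d = dataclasses.asdict(settings)
    d["initial"] = {
        "blocks": [
            {"nodes": list(nodes), "atoms": [[list(v), p] for v, p in atoms]}
            for nodes, atoms in settings.initial.blocks
        ],
        "default_p": settings.initial.default_p,
    }
    d["outputs"] = list(settings.outputs) if settings.outputs is not None else None
    return d


def result_to_json_dict(result: SimulationResult) -> dict:
    return {
        "outputs": result.outputs,
        "node_order": result.node_order,
        "window_edges": list(result.window_edges),
        "last_state_distribution": result.last_state_distribution,
        "fixed_points": result.fixed_points.to_dict(orient="records"),
        "state_probabilities": {
            "time": list(result.state_probabilities.index),
            "columns": list(result.state_probabilities.columns),
            "values": result.state_probabilities.to_numpy().tolist(),
        },
        "node_probabilities": {
            "time": list(result.node_probabilities.index),
            "columns": list(result.node_probabilities.columns),
            "values": result.node_probabilities.to_numpy().tolist(),
        },
        "settings": _settings_dict(result.settings),
    }


def result_summary_from_json(path: str | Path) -> dict:
    """Load the fields needed for phenotype filtering from a result.json."""
    with open(path) as fh:
        data = json.load(fh)
    return {
        "outputs": data["outputs"],
        "last_state_distribution": data["last_state_distribution"],
    }


def settings_from_json_dict(d: dict) -> SimulationSettings:
    initial = InitialStateDistribution(
        blocks=[
            (tuple(b["nodes"]), [(tuple(v), p) for v, p in b["atoms"]])
            for b in d["initial"]["blocks"]
        ],
        default_p=d["initial"]["default_p"],
    )
    return SimulationSettings(
        initial=initial,
        outputs=d["outputs"],
        sample_count=d["sample_count"],
        max_time=d["max_time"],
        time_points=d["time_points"],
        seed=d["seed"],
    )


def mutation_from_label(label: str) -> MutationSpec:
    """Inverse of MutationSpec.label() for screen directory names."""
    if label == "wild_type":
        return MutationSpec(())
    changes = []
    for part in label.split("__"):
        name, _, direction = part.rpartition("_")
        changes.append((name, direction))
    return MutationSpec(tuple(changes))
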