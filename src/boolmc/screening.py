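"""Automatic mutant screening and phenotype filtering.

A screen enumerates single and/or double forced-node perturbations
(knock-out OFF, knock-in ON) over a candidate node list, simulates each
mutant plus the unperturbed wild type under identical settings, and
filters the results on a phenotype query — a conjunction of required
output values whose statistic is the probability mass of matching
projected states at the end of the simulation (the "last state" pie).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .engine import SimulationResult, SimulationSettings, run_ensemble
from .model import MutationSpec, Network, NIL_LABEL, ValidationError, apply_mutation

__all__ = [
    "PhenotypeQuery",
    "ScreenEntry",
    "ScreenResult",
    "enumerate_mutants",
    "run_screen",
    "filter_phenotype",
]


@dataclass(frozen=True)
class PhenotypeQuery:
    """Required output values plus a strict probability threshold."""

    constraints: tuple[tuple[str, int], ...]
    threshold: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValidationError(f"threshold {self.threshold} outside [0, 1]")
        for name, value in self.constraints:
            if value not in (0, 1):
                raise ValidationError(f"required value for {name!r} must be 0 or 1")

    def matches(self, label: str) -> bool:
        active = set() if label == NIL_LABEL else set(label.split(" -- "))
        return all((name in active) == bool(value) for name, value in self.constraints)


@dataclass
class ScreenEntry:
    mutation: MutationSpec
    result: SimulationResult | None
    error: str | None = None
    seed: int = 0


@dataclass
class ScreenResult:
    """Wild type plus one entry per mutant, simulated under shared settings."""

    entries: list[ScreenEntry]
    settings: SimulationSettings
    network_provenance: str = ""
    master_seed: int = 0

    def entry(self, mutation: MutationSpec) -> ScreenEntry:
        for e in self.entries:
            if e.mutation == mutation:
                return e
        raise KeyError(str(mutation))


def enumerate_mutants(
    candidates: Sequence[str],
    max_order: int = 1,
    directions: Sequence[str] = ("OFF", "ON"),
) -> list[MutationSpec]:
    """All single (and, for ``max_order=2``, double) mutant specs.

    Deterministic order: candidates in the given order, directions
    OFF before ON, singles before doubles.
    """
    if not candidates:
        raise ValidationError("candidate list is empty")
    if len(set(candidates)) != len(candidates):
        raise ValidationError("duplicate candidate node")
    if max_order not in (1, 2):
        raise ValidationError(f"max_order must be 1 or 2, got {max_order}")
    directions = sorted(set(directions), key=("OFF", "ON").index)
    if not directions:
        raise ValidationError("no mutation directions given")
    specs = [
        MutationSpec(((node, d),)) for node in candidates for d in directions
    ]
    if max_order == 2:
        for a, b in combinations(candidates, 2):
            for da in directions:
                for db in directions:
                    specs.append(MutationSpec(((a, da), (b, db))))
    return specs


def _mutant_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence((int(master_seed), int(index))).generate_state(1)[0] % (2**31))


def run_screen(
    network: Network,
    settings: SimulationSettings,
    mutants: Sequence[MutationSpec],
) -> ScreenResult:
    """Simulate wild type and every mutant one after the other.

    Each entry gets its own seed derived from the master seed and its
    position, so the screen is reproducible and order-independent.  A
    failing mutant is recorded as an error without aborting the rest.
    """
    entries: list[ScreenEntry] = []
    all_specs = [MutationSpec(())] + list(mutants)
    for index, spec in enumerate(all_specs):
        seed = _mutant_seed(settings.seed, index)
        entry_settings = dataclasses.replace(settings, seed=seed)
        try:
            mutated = apply_mutation(network, spec)
            result = run_ensemble(mutated, entry_settings)
            entries.append(ScreenEntry(mutation=spec, result=result, seed=seed))
        except Exception as exc:  # noqa: BLE001 - error isolation per mutant
            entries.append(
                ScreenEntry(mutation=spec, result=None, error=str(exc), seed=seed)
            )
    return ScreenResult(
        entries=entries,
        settings=settings,
        network_provenance=network.provenance,
        master_seed=settings.seed,
    )


def filter_phenotype(
    screen: ScreenResult, query: PhenotypeQuery
) -> list[tuple[MutationSpec, float]]:
    """Mutants whose last-state mass on the queried phenotype exceeds the threshold.

    The statistic is the summed last-state probability of projected
    states satisfying every constraint; entries are sorted by statistic,
    descending, and the comparison with the threshold is strict.
    """
    checked = False
    out: list[tuple[MutationSpec, float]] = []
    for entry in screen.entries:
        if entry.result is None:
            continue
        if not checked:
            outputs = set(entry.result.outputs)
            for name, _ in query.constraints:
                if name not in outputs:
                    raise ValidationError(
                        f"phenotype constraint on {name!r}, which is not an output node"
                    )
            checked = True
        stat = sum(
            p
            for label, p in entry.result.last_state_distribution.items()
            if query.matches(label)
        )
        if stat > query.threshold:
            out.append((entry.mutation, stat))
    out.sort(key=lambda pair: -pair[1])
    return out
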