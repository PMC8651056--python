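"""Multi-valued logical models (variables with levels 0..maxLevel).

This is the in-memory form of an SBML-qual document before conversion to
a purely Boolean network.  Each variable has a target-level function
given as an ordered list of ``(condition, target level)`` rules plus a
default level; the first rule whose condition holds determines the
target.  A variable with ``rules=None`` is an input held at its current
level.

Conditions are a small expression language over variable *levels*:
comparisons between a variable and an integer, combined with and/or/
not/xor.  (Boolean node-state logic lives in :mod:`boolmc.expressions`;
level conditions are a separate, simpler language because they compare
integers, not bits.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .model import ValidationError

__all__ = [
    "LevelExpr",
    "LevelCmp",
    "LevelAnd",
    "LevelOr",
    "LevelNot",
    "LevelXor",
    "LevelConst",
    "Variable",
    "MultiValuedModel",
]

_CMP_OPS = {
    "eq": lambda a, b: a == b,
    "neq": lambda a, b: a != b,
    "geq": lambda a, b: a >= b,
    "gt": lambda a, b: a > b,
    "leq": lambda a, b: a <= b,
    "lt": lambda a, b: a < b,
}


class LevelExpr:
    def evaluate(self, levels: Mapping[str, int]) -> bool:
        raise NotImplementedError

    def variables(self) -> set[str]:
        raise NotImplementedError


@dataclass(frozen=True)
class LevelConst(LevelExpr):
    value: bool

    def evaluate(self, levels):
        return self.value

    def variables(self):
        return set()


@dataclass(frozen=True)
class LevelCmp(LevelExpr):
    """``variable <op> level`` with op in eq/neq/geq/gt/leq/lt."""

    variable: str
    op: str
    level: int

    def __post_init__(self):
        if self.op not in _CMP_OPS:
            raise ValidationError(f"unknown comparison operator {self.op!r}")

    def evaluate(self, levels):
        return _CMP_OPS[self.op](levels[self.variable], self.level)

    def variables(self):
        return {self.variable}


@dataclass(frozen=True)
class LevelAnd(LevelExpr):
    items: tuple[LevelExpr, ...]

    def evaluate(self, levels):
        return all(x.evaluate(levels) for x in self.items)

    def variables(self):
        return set().union(*(x.variables() for x in self.items)) if self.items else set()


@dataclass(frozen=True)
class LevelOr(LevelExpr):
    items: tuple[LevelExpr, ...]

    def evaluate(self, levels):
        return any(x.evaluate(levels) for x in self.items)

    def variables(self):
        return set().union(*(x.variables() for x in self.items)) if self.items else set()


@dataclass(frozen=True)
class LevelNot(LevelExpr):
    operand: LevelExpr

    def evaluate(self, levels):
        return not self.operand.evaluate(levels)

    def variables(self):
        return self.operand.variables()


@dataclass(frozen=True)
class LevelXor(LevelExpr):
    items: tuple[LevelExpr, ...]

    def evaluate(self, levels):
        return sum(bool(x.evaluate(levels)) for x in self.items) % 2 == 1

    def variables(self):
        return set().union(*(x.variables() for x in self.items)) if self.items else set()


@dataclass
class Variable:
    """One multi-valued variable and its target-level function."""

    name: str
    max_level: int = 1
    rules: list[tuple[LevelExpr, int]] | None = field(default_factory=list)
    default_level: int = 0
    initial_level: int | None = None

    def target_level(self, levels: Mapping[str, int]) -> int:
        """First-match evaluation of the rule list; identity for inputs."""
        if self.rules is None:
            return levels[self.name]
        for cond, target in self.rules:
            if cond.evaluate(levels):
                return target
        return self.default_level


@dataclass
class MultiValuedModel:
    variables: list[Variable]
    provenance: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [v.name for v in self.variables]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate variable names")
        declared = set(names)
        for v in self.variables:
            if v.max_level < 1:
                raise ValidationError(f"variable {v.name!r} has maxLevel {v.max_level} < 1")
            if not 0 <= v.default_level <= v.max_level:
                raise ValidationError(
                    f"default level {v.default_level} of {v.name!r} outside [0, {v.max_level}]"
                )
            if v.initial_level is not None and not 0 <= v.initial_level <= v.max_level:
                raise ValidationError(
                    f"initial level {v.initial_level} of {v.name!r} outside [0, {v.max_level}]"
                )
            for cond, target in v.rules or []:
                if not 0 <= target <= v.max_level:
                    raise ValidationError(
                        f"target level {target} of {v.name!r} outside [0, {v.max_level}]"
                    )
                unknown = cond.variables() - declared
                if unknown:
                    raise ValidationError(
                        f"condition of {v.name!r} references unknown variables {sorted(unknown)}"
                    )

    @property
    def is_boolean(self) -> bool:
        return all(v.max_level == 1 for v in self.variables)

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def targets(self, levels: Mapping[str, int]) -> dict[str, int]:
        return {v.name: v.target_level(levels) for v in self.variables}

    def stepwise_stg(
        self,
    ) -> dict[tuple[int, ...], set[tuple[int, ...]]]:
        """Asynchronous state-transition graph with ±1 level steps.

        From each level assignment, every variable whose target differs
        from its current level may move one level toward the target.
        """
        names = [v.name for v in self.variables]
        maxes = [v.max_level for v in self.variables]
        states: list[tuple[int, ...]] = [()]
        for m in maxes:
            states = [s + (lv,) for s in states for lv in range(m + 1)]
        stg: dict[tuple[int, ...], set[tuple[int, ...]]] = {}
        for s in states:
            levels = dict(zip(names, s))
            succ = set()
            for i, v in enumerate(self.variables):
                target = v.target_level(levels)
                if target > s[i]:
                    succ.add(s[:i] + (s[i] + 1,) + s[i + 1 :])
                elif target < s[i]:
                    succ.add(s[:i] + (s[i] - 1,) + s[i + 1 :])
            stg[s] = succ
        return stg
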