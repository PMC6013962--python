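"""Multi-attribute health-state classification systems.

A classification system describes health through J ordered attributes
(e.g. mobility, self-care), each with a small number of levels; level 1 is
always the best ("no problems") and level n_j the worst.  A health state is
one level per attribute, conventionally written as a digit string such as
``"33221"`` on the EQ-5D-3L.  The vector (1, 1, ..., 1) is perfect health.

This module defines the system and state types, the digit-string codec,
enumeration of all describable states, and the dummy design matrix that
maps states onto the free attribute-level weights of the linear logistic
(attribute-parameterized) model.  Level 1 of every attribute is the
reference and carries no column, which implements the identification
constraint alpha_{j,1} = 0 and anchors the value of perfect health at 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .exceptions import ValidationError

__all__ = [
    "Attribute",
    "ClassificationSystem",
    "HealthState",
    "DesignMatrix",
    "EQ5D3L",
    "parse_state",
    "encode_state",
    "enumerate_states",
    "build_design_matrix",
]


@dataclass(frozen=True)
class Attribute:
    """One health attribute: a name and an ordered set of levels 1..n_levels."""

    name: str
    n_levels: int
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValidationError(
                f"attribute {self.name!r}: n_levels must be >= 2, got {self.n_levels}"
            )
        if self.labels is not None and len(self.labels) != self.n_levels:
            raise ValidationError(
                f"attribute {self.name!r}: {len(self.labels)} labels for "
                f"{self.n_levels} levels"
            )


@dataclass(frozen=True)
class ClassificationSystem:
    """An ordered collection of attributes defining a universe of health states."""

    attributes: tuple[Attribute, ...]
    name: str = ""

    def __post_init__(self):
        if len(self.attributes) < 1:
            raise ValidationError("a classification system needs at least one attribute")
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValidationError(f"attribute names must be unique, got {names}")

    @property
    def J(self) -> int:
        return len(self.attributes)

    @property
    def n_levels(self) -> tuple[int, ...]:
        return tuple(a.n_levels for a in self.attributes)

    @property
    def n_states(self) -> int:
        """Number of describable states, the product of the n_j."""
        return int(np.prod(self.n_levels))

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    @property
    def single_digit(self) -> bool:
        """True when every attribute fits a one-character digit code."""
        return max(self.n_levels) <= 9

    @classmethod
    def from_config(cls, path: str | Path) -> "ClassificationSystem":
        """Load a system from a YAML config (ordered attribute list)."""
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "ClassificationSystem":
        if not isinstance(doc, dict) or "attributes" not in doc:
            raise ValidationError("classification config must have an 'attributes' list")
        attrs = []
        for entry in doc["attributes"]:
            labels = entry.get("labels")
            attrs.append(
                Attribute(
                    name=str(entry["name"]),
                    n_levels=int(entry["levels"]),
                    labels=tuple(labels) if labels else None,
                )
            )
        return cls(attributes=tuple(attrs), name=str(doc.get("name", "")))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "attributes": [
                {
                    "name": a.name,
                    "levels": a.n_levels,
                    **({"labels": list(a.labels)} if a.labels else {}),
                }
                for a in self.attributes
            ],
        }

    def to_config(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class HealthState:
    """One multi-attribute health state: a level per attribute, in system order."""

    levels: tuple[int, ...]

    @property
    def code(self) -> str:
        """Digit-string code; delimited with '-' when any level exceeds 9."""
        if all(l <= 9 for l in self.levels):
            return "".join(str(l) for l in self.levels)
        return "-".join(str(l) for l in self.levels)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


# Attribute order follows the instrument: mobility, self-care, usual
# activities, pain/discomfort, anxiety/depression.  Digit strings are read
# in this order.
EQ5D3L = ClassificationSystem(
    name="EQ-5D-3L",
    attributes=(
        Attribute("mobility", 3, ("no problems", "some problems", "confined to bed")),
        Attribute("self_care", 3, ("no problems", "some problems", "unable to")),
        Attribute("usual_activities", 3, ("no problems", "some problems", "unable to")),
        Attribute("pain_discomfort", 3, ("no", "moderate", "extreme")),
        Attribute("anxiety_depression", 3, ("not", "moderately", "extremely")),
    ),
)


def _validate_levels(levels: Sequence[int], system: ClassificationSystem) -> tuple[int, ...]:
    if len(levels) != system.J:
        raise ValidationError(
            f"state has {len(levels)} levels but system "
            f"{system.name or '<unnamed>'} has {system.J} attributes"
        )
    for attr, lev in zip(system.attributes, levels):
        if not 1 <= lev <= attr.n_levels:
            raise ValidationError(
                f"level {lev} out of range 1..{attr.n_levels} "
                f"for attribute {attr.name!r}"
            )
    return tuple(int(l) for l in levels)


def parse_state(code: str, system: ClassificationSystem) -> HealthState:
    """Decode a health-state code on the given system.

    Plain digit strings (one character per attribute) are accepted when
    every attribute has at most 9 levels; the delimited variant
    ``"3-2-2-1-1"`` is always accepted and required for wider systems.
    """
    code = code.strip()
    if "-" in code:
        parts = code.split("-")
        try:
            levels = [int(p) for p in parts]
        except ValueError as exc:
            raise ValidationError(f"malformed delimited state code {code!r}") from exc
    else:
        if not system.single_digit:
            raise ValidationError(
                f"system {system.name or '<unnamed>'} has an attribute with more "
                f"than 9 levels; use the delimited code form (e.g. '3-2-2-1-1')"
            )
        if not code.isdigit():
            raise ValidationError(f"malformed state code {code!r}")
        levels = [int(c) for c in code]
    return HealthState(_validate_levels(levels, system))


def encode_state(state: HealthState, system: ClassificationSystem) -> str:
    """Encode a state as a code valid on *system* (round-trips with parse_state)."""
    _validate_levels(state.levels, system)
    if system.single_digit:
        return "".join(str(l) for l in state.levels)
    return "-".join(str(l) for l in state.levels)


def enumerate_states(system: ClassificationSystem) -> list[HealthState]:
    """Every describable state exactly once, in lexicographic code order."""
    ranges = [range(1, n + 1) for n in system.n_levels]
    return [HealthState(tuple(combo)) for combo in itertools.product(*ranges)]


@dataclass(frozen=True)
class DesignMatrix:
    """Dummy design mapping health states to free attribute-level weights.

    One row per state; one column per non-reference level (k = 2..n_j) of
    each attribute, plus optional interaction columns (products of
    non-reference dummies of two attributes).  Entry d_{jk}(x_ij) is 1 iff
    the state sits at level k of attribute j.  There is no intercept: the
    all-reference state (1, ..., 1) is an all-zero row and thus has implied
    value 0 exactly.
    """

    matrix: np.ndarray
    columns: tuple[str, ...]
    states: tuple[HealthState, ...]
    system: ClassificationSystem

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def _main_effect_columns(system: ClassificationSystem) -> list[tuple[str, int]]:
    cols = []
    for attr in system.attributes:
        for k in range(2, attr.n_levels + 1):
            cols.append((attr.name, k))
    return cols


def build_design_matrix(
    states: Iterable[HealthState],
    system: ClassificationSystem,
    interactions: Sequence[tuple[str, str]] | None = None,
) -> DesignMatrix:
    """Build the dummy design for *states* on *system*.

    Parameters
    ----------
    states : iterable of HealthState
        The states to encode (rows, in order).
    system : ClassificationSystem
    interactions : sequence of (attribute, attribute) pairs, optional
        For each pair, one column per combination of non-reference levels,
        holding the product of the two dummies.

    Raises
    ------
    ValidationError
        If a state does not belong to the system, or an interaction names
        an unknown attribute.
    """
    states = tuple(states)
    for st in states:
        _validate_levels(st.levels, system)

    main_cols = _main_effect_columns(system)
    col_labels = [f"{name}:{k}" for name, k in main_cols]
    col_index = {c: i for i, c in enumerate(main_cols)}
    name_to_pos = {a.name: j for j, a in enumerate(system.attributes)}

    inter_specs: list[tuple[str, int, str, int]] = []
    if interactions:
        for a, b in interactions:
            for nm in (a, b):
                if nm not in name_to_pos:
                    raise ValidationError(f"unknown attribute {nm!r} in interaction")
            if a == b:
                raise ValidationError(f"interaction of {a!r} with itself")
            na = system.attributes[name_to_pos[a]].n_levels
            nb = system.attributes[name_to_pos[b]].n_levels
            for ka in range(2, na + 1):
                for kb in range(2, nb + 1):
                    inter_specs.append((a, ka, b, kb))
                    col_labels.append(f"{a}:{ka}*{b}:{kb}")

    K = len(main_cols) + len(inter_specs)
    X = np.zeros((len(states), K), dtype=float)
    for i, st in enumerate(states):
        for j, attr in enumerate(system.attributes):
            k = st.levels[j]
            if k >= 2:
                X[i, col_index[(attr.name, k)]] = 1.0
        for m, (a, ka, b, kb) in enumerate(inter_specs):
            if st.levels[name_to_pos[a]] == ka and st.levels[name_to_pos[b]] == kb:
                X[i, len(main_cols) + m] = 1.0
    return DesignMatrix(matrix=X, columns=tuple(col_labels), states=states, system=system)
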