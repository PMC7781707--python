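"""IRMA hierarchical codes and the hierarchical classification error.

An IRMA code labels a radiograph along four independent hierarchical axes —
Technical (imaging modality), Directional (body orientation), Anatomical
(body region), Biological (organ system) — written ``TTTT-DDD-AAA-BBB``.
Each axis is a root-to-leaf path in a decision tree: position ``i`` is the
``i``-th decision, so an early wrong decision invalidates every deeper one.
A ``*`` in a predicted code means "don't know" and costs half a mistake.

The per-axis error is the position-weighted sum

    sum_i (1/b_i) * (1/i) * delta_i

where ``b_i`` is the branching factor at depth ``i`` and ``delta_i`` is 0
while every decision up to ``i`` is correct, 0.5 once a wildcard has been
issued, and 1 once an actual mismatch has occurred (a mismatch dominates a
wildcard from the position where it happens).  The sum is normalized by its
all-wrong value so a completely wrong axis scores exactly 1; a whole code
scores the mean of its four axis errors, hence lies in [0, 1] per image.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass

logger = logging.getLogger(__name__)

AXIS_NAMES = ("technical", "directional", "anatomical", "biological")
AXIS_LENGTHS = (4, 3, 3, 3)
WILDCARD = "*"
_CHAR_RE = re.compile(r"^[0-9a-zA-Z*]+$")


class IRMACodeError(ValueError):
    """Malformed IRMA code string."""


@dataclass(frozen=True)
class IRMACode:
    """A four-axis hierarchical label with axis lengths (4, 3, 3, 3)."""

    axes: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.axes) != len(AXIS_LENGTHS):
            raise IRMACodeError(f"expected 4 axes, got {len(self.axes)}")
        for name, axis, length in zip(AXIS_NAMES, self.axes, AXIS_LENGTHS):
            if len(axis) != length:
                raise IRMACodeError(
                    f"{name} axis {axis!r} has length {len(axis)}, expected {length}"
                )
            if not _CHAR_RE.match(axis):
                raise IRMACodeError(f"{name} axis {axis!r} contains illegal characters")

    @property
    def has_wildcard(self) -> bool:
        return any(WILDCARD in axis for axis in self.axes)

    def __str__(self) -> str:
        return "-".join(self.axes)


def parse_irma_code(text: str) -> IRMACode:
    """Parse ``TTTT-DDD-AAA-BBB`` (wildcards allowed) into an :class:`IRMACode`."""
    parts = tuple(str(text).strip().split("-"))
    if len(parts) != 4:
        raise IRMACodeError(f"code {text!r}: expected 4 '-'-separated axes, got {len(parts)}")
    return IRMACode(axes=parts)


@dataclass(frozen=True)
class CodeScheme:
    """Per-axis, per-position branching factors ``b_i`` of the code trees.

    The official branching factors are not distributed with the dataset
    codes, so a uniform default of 10 admissible labels per decision is
    used; the normalization by the all-wrong score makes per-axis errors
    invariant to any uniform choice.
    """

    branching: tuple[tuple[int, ...], ...] = tuple(
        tuple(10 for _ in range(n)) for n in AXIS_LENGTHS
    )

    def __post_init__(self) -> None:
        if len(self.branching) != 4:
            raise ValueError("scheme must define branching for exactly 4 axes")
        for name, row, length in zip(AXIS_NAMES, self.branching, AXIS_LENGTHS):
            if len(row) != length:
                raise ValueError(f"{name} axis needs {length} branching factors")
            if any(b < 2 for b in row):
                raise ValueError(f"{name} axis has a branching factor < 2")

    @classmethod
    def from_json(cls, path) -> "CodeScheme":
        """Load ``{axis name: [b_1, b_2, ...]}`` from a JSON file."""
        with open(path) as fh:
            raw = json.load(fh)
        rows = tuple(tuple(int(b) for b in raw[name]) for name in AXIS_NAMES)
        return cls(branching=rows)


def axis_error(correct: str, predicted: str, branching) -> float:
    """Normalized hierarchical error for one axis, in [0, 1].

    delta_i tracks the first deviating decision: 0 while all positions up
    to i match, 0.5 from the first wildcard on, 1 from the first true
    mismatch on (and for all deeper positions).  The raw weighted sum is
    divided by the all-wrong raw sum, so a fully wrong axis scores 1.
    """
    if len(correct) != len(predicted):
        raise ValueError(
            f"axis length mismatch: correct {correct!r} vs predicted {predicted!r}"
        )
    if WILDCARD in correct:
        raise ValueError("the correct code may not contain wildcards")
    if len(branching) != len(correct):
        raise ValueError("branching factors do not cover every position")
    raw = 0.0
    worst = 0.0
    delta = 0.0
    for i, (lc, lp, b) in enumerate(zip(correct, predicted, branching), start=1):
        if delta < 1.0:
            if lp == WILDCARD:
                delta = 0.5
            elif lp != lc:
                delta = 1.0
        weight = (1.0 / b) * (1.0 / i)
        raw += weight * delta
        worst += weight * 1.0
    return raw / worst


def irma_error(correct: IRMACode, predicted: IRMACode, scheme: CodeScheme = CodeScheme()) -> float:
    """Per-image hierarchical error: mean of the four normalized axis errors."""
    errors = [
        axis_error(c, p, b)
        for c, p, b in zip(correct.axes, predicted.axes, scheme.branching)
    ]
    return float(sum(errors)) / len(errors)


def total_irma_error(pairs, scheme: CodeScheme = CodeScheme()) -> float:
    """Sum of per-image errors over ``(correct, predicted)`` code pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot score an empty list of code pairs")
    return float(sum(irma_error(c, p, scheme) for c, p in pairs))
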