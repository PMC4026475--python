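"""Repeat-motif inventories and run-length structure strings.

The R2 tandem array in the rhinolophid control region is built from 11-bp
repeat units falling into a handful of motif classes (labelled A, B, ...)
that differ from one another by one or two substitutions.  An array is
described compactly as a run-length *structure string* such as
``(A)4(B)1(A)5(B)2(A)6(B)2`` — full units grouped into runs — optionally
interleaved with short literal segments (truncated units), e.g.
``(C)1AACGC(D)6``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

__all__ = [
    "MotifInventory",
    "DEFAULT_INVENTORY",
    "parse_structure",
    "structure_string",
    "reconstruct_from_structure",
]

_RUN_RE = re.compile(r"\(([A-Za-z])\)_?(\d+)_?|([ACGTacgt]+)")

# One run of a repeat array: (motif label or literal sequence, count).
Run = tuple[str, int]


@dataclass(frozen=True)
class MotifInventory:
    """An ordered set of equal-length repeat-unit sequences with letter labels."""

    labels: tuple[str, ...]
    units: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.units):
            raise ValueError("labels and units must have equal length")
        if not self.units:
            raise ValueError("inventory must contain at least one unit")
        lengths = {len(u) for u in self.units}
        if len(lengths) != 1:
            raise ValueError(f"inventory units have unequal lengths: {sorted(lengths)}")
        if len(set(self.units)) != len(self.units):
            raise ValueError("inventory units must be pairwise distinct")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("inventory labels must be distinct")

    @property
    def period(self) -> int:
        """Unit length in bp (11 for the built-in inventory)."""
        return len(self.units[0])

    def unit(self, label: str) -> str:
        try:
            return self.units[self.labels.index(label)]
        except ValueError:
            raise KeyError(
                f"unknown motif label {label!r}; valid labels: {', '.join(self.labels)}"
            ) from None

    def label_of(self, unit: str) -> Union[str, None]:
        try:
            return self.labels[self.units.index(unit)]
        except ValueError:
            return None

    def as_mapping(self) -> Mapping[str, str]:
        return dict(zip(self.labels, self.units))

    @classmethod
    def from_units(cls, units: Sequence[str], labels: Sequence[str] | None = None) -> "MotifInventory":
        if labels is None:
            labels = [chr(ord("A") + i) for i in range(len(units))]
        return cls(tuple(labels), tuple(u.upper() for u in units))

    @classmethod
    def from_tsv(cls, path) -> "MotifInventory":
        labels, units = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                label, unit = line.split("\t")[:2]
                labels.append(label)
                units.append(unit.upper())
        return cls(tuple(labels), tuple(units))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tunit\n")
            for label, unit in zip(self.labels, self.units):
                fh.write(f"{label}\t{unit}\n")


#: The five 11-bp R2 motif classes observed in *Rhinolophus sinicus*.
DEFAULT_INVENTORY = MotifInventory.from_units(
    [
        "AACGTACACGT",  # A
        "GACGTACACGT",  # B
        "AACGTATACGC",  # C
        "AACGCATACGC",  # D
        "AACACATACGC",  # E
    ]
)


def parse_structure(structure: str) -> list[Run]:
    """Parse a structure string into ordered ``(label_or_literal, count)`` runs.

    Accepts both the compact form ``(C)7`` and the typeset form ``(C)_7_``;
    whitespace is ignored.  Literal segments (uppercase sequence outside
    parentheses) get count 1.
    """
    runs: list[Run] = []
    compact = re.sub(r"\s+", "", structure)
    pos = 0
    while pos < len(compact):
        m = _RUN_RE.match(compact, pos)
        if m is None:
            raise ValueError(f"cannot parse structure string at {compact[pos:]!r}")
        if m.group(1) is not None:
            runs.append((m.group(1).upper(), int(m.group(2))))
        else:
            runs.append((m.group(3).upper(), 1))
        pos = m.end()
    return runs


def structure_string(runs: Iterable[Run]) -> str:
    """Format runs back into the compact ``(X)n`` notation (literals inline)."""
    parts = []
    for label, count in runs:
        if len(label) == 1:
            parts.append(f"({label}){count}")
        else:
            parts.append(label * count)
    return "".join(parts)


def reconstruct_from_structure(
    structure: Union[str, Sequence[Run]],
    inventory: MotifInventory = DEFAULT_INVENTORY,
) -> str:
    """Expand a run-length structure into its nucleotide sequence.

    Single-letter run labels are looked up in *inventory*; multi-character
    tokens are literal partial units copied verbatim.  The result has length
    ``period * (full unit count) + sum of literal lengths``.
    """
    runs = parse_structure(structure) if isinstance(structure, str) else list(structure)
    out = []
    for label, count in runs:
        if len(label) == 1:
            out.append(inventory.unit(label) * count)
        else:
            out.append(label * count)
    return "".join(out)
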