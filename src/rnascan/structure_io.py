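"""Parsing, validation and serialization of secondary-structure and entropy inputs.

Two text formats carry the secondary-structure model: the RNAstructure-style
connectivity table (CT) and dot-bracket notation (with optional pseudoknot
bracket tiers).  Per-nucleotide Shannon entropy arrives as whitespace-delimited
text, either one value per line (implicit 1-based order) or ``position value``
pairs.  All coordinates are 1-based, closed intervals, matching the CT
convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SecondaryStructure",
    "EntropyTrack",
    "StructureParseError",
    "StructureValidationError",
    "MISSING_SENTINEL",
    "parse_ct",
    "parse_dotbracket",
    "read_entropy",
    "write_track",
    "to_ct",
    "to_dotbracket",
]

#: Sentinel written/recognised for no-data entropy positions (Superfold convention).
MISSING_SENTINEL = -999.0

#: Bracket tiers accepted in dot-bracket input; tier 0 is the nested backbone,
#: the others carry pseudoknotted pairs.
BRACKET_TIERS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]

_OPEN = {o: t for t, (o, _) in enumerate(BRACKET_TIERS)}
_CLOSE = {c: t for t, (_, c) in enumerate(BRACKET_TIERS)}
_NAN_TOKENS = {"nan", "na", "n/a", "none"}


class StructureParseError(ValueError):
    """Raised when an input file cannot be tokenized into the expected format."""


class StructureValidationError(ValueError):
    """Raised when a parsed object violates a structural invariant."""


@dataclass(frozen=True)
class SecondaryStructure:
    """The pairing state of every nucleotide of one RNA.

    ``pairing[i]`` (0-based storage) holds the 1-based partner index of
    nucleotide ``i + 1``, or 0 if unpaired.
    """

    sequence: str
    pairing: np.ndarray  # int array, 1-based partner indices, 0 = unpaired

    def __post_init__(self) -> None:
        pairing = np.asarray(self.pairing, dtype=np.int64)
        object.__setattr__(self, "pairing", pairing)
        n = pairing.size
        if len(self.sequence) != n:
            raise StructureValidationError(
                f"sequence length {len(self.sequence)} != pairing length {n}"
            )
        if n == 0:
            raise StructureValidationError("empty structure")
        if pairing.min() < 0 or pairing.max() > n:
            bad = int(np.flatnonzero((pairing < 0) | (pairing > n))[0])
            raise StructureValidationError(
                f"partner index {pairing[bad]} at position {bad + 1} outside [0, {n}]"
            )
        idx = np.arange(1, n + 1)
        if np.any(pairing == idx):
            bad = int(np.flatnonzero(pairing == idx)[0])
            raise StructureValidationError(f"nucleotide {bad + 1} pairs with itself")
        paired = pairing > 0
        back = pairing[pairing[paired] - 1]
        if not np.array_equal(back, idx[paired]):
            offending = idx[paired][back != idx[paired]][0]
            raise StructureValidationError(
                f"asymmetric pairing: {offending} -> {pairing[offending - 1]} "
                f"but {pairing[offending - 1]} -> "
                f"{pairing[pairing[offending - 1] - 1]}"
            )

    @property
    def length(self) -> int:
        return self.pairing.size

    @property
    def paired(self) -> np.ndarray:
        """Boolean vector: True where the nucleotide is base-paired."""
        return self.pairing > 0


@dataclass(frozen=True)
class EntropyTrack:
    """Per-nucleotide Shannon entropy aligned to one RNA; NaN marks missing data."""

    values: np.ndarray  # float array; NaN = missing

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        finite = values[~np.isnan(values)]
        if finite.size and finite.min() < 0:
            bad = int(np.flatnonzero(values < 0)[0])
            raise StructureValidationError(
                f"negative entropy {values[bad]} at position {bad + 1}"
            )

    @property
    def length(self) -> int:
        return self.values.size

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


def _int_field(token: str, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise StructureParseError(
            f"line {lineno}: non-integer {what} field {token!r}"
        ) from None


def parse_ct(text: str) -> SecondaryStructure:
    """Parse a connectivity table.

    The first non-blank line must begin with the sequence length; each record
    has at least six whitespace-delimited columns of which column 1 (index),
    column 2 (base) and column 5 (partner) are used.
    """
    lines = text.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.strip():
            header_idx = i
            break
    if header_idx is None:
        raise StructureParseError("empty CT input")
    header_tok = lines[header_idx].split()[0]
    n = _int_field(header_tok, header_idx + 1, "length")
    if n <= 0:
        raise StructureParseError(f"line {header_idx + 1}: non-positive length {n}")

    pairing = np.zeros(n, dtype=np.int64)
    seq = ["N"] * n
    seen = np.zeros(n, dtype=bool)
    n_records = 0
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 6:
            raise StructureParseError(
                f"line {lineno}: expected >= 6 columns, got {len(fields)}"
            )
        idx = _int_field(fields[0], lineno, "index")
        partner = _int_field(fields[4], lineno, "partner")
        if not 1 <= idx <= n:
            raise StructureParseError(
                f"line {lineno}: index {idx} outside 1..{n}"
            )
        if seen[idx - 1]:
            raise StructureParseError(f"line {lineno}: duplicate index {idx}")
        seen[idx - 1] = True
        pairing[idx - 1] = partner
        seq[idx - 1] = fields[1]
        n_records += 1
    if n_records != n:
        missing = int(np.flatnonzero(~seen)[0]) + 1 if n_records < n else n
        raise StructureParseError(
            f"header declares {n} records but {n_records} parsed "
            f"(first missing index: {missing})"
        )
    return SecondaryStructure(sequence="".join(seq), pairing=pairing)


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse dot-bracket notation with up to four independent bracket tiers.

    Accepts an optional FASTA-style ``>`` header line and an optional sequence
    line preceding the structure line.
    """
    structure_line = None
    sequence_line = None
    for line in text.splitlines():
        s = line.strip()
        if not s or s.startswith(">") or s.startswith("#"):
            continue
        if set(s) <= (set("." ) | set(_OPEN) | set(_CLOSE)):
            structure_line = s
            break
        sequence_line = s
    if structure_line is None:
        raise StructureParseError("no dot-bracket structure line found")
    n = len(structure_line)
    if sequence_line is not None and len(sequence_line) != n:
        raise StructureValidationError(
            f"sequence length {len(sequence_line)} != structure length {n}"
        )

    pairing = np.zeros(n, dtype=np.int64)
    stacks: list[list[int]] = [[] for _ in BRACKET_TIERS]
    for pos, ch in enumerate(structure_line, start=1):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN[ch]].append(pos)
        else:
            tier = _CLOSE[ch]
            if not stacks[tier]:
                o, c = BRACKET_TIERS[tier]
                raise StructureParseError(
                    f"unbalanced {o}{c} tier: unmatched {ch!r} at position {pos}"
                )
            j = stacks[tier].pop()
            pairing[j - 1] = pos
            pairing[pos - 1] = j
    for tier, stack in enumerate(stacks):
        if stack:
            o, c = BRACKET_TIERS[tier]
            raise StructureParseError(
                f"unbalanced {o}{c} tier: unmatched {o!r} at position {stack[-1]}"
            )
    seq = sequence_line if sequence_line is not None else "N" * n
    return SecondaryStructure(sequence=seq, pairing=pairing)


def _parse_value(token: str, lineno: int) -> float:
    if token.lower() in _NAN_TOKENS:
        return math.nan
    try:
        v = float(token)
    except ValueError:
        raise StructureParseError(
            f"line {lineno}: non-numeric entropy value {token!r}"
        ) from None
    if v == MISSING_SENTINEL or math.isnan(v):
        return math.nan
    return v


def read_entropy(text: str, expected_length: int) -> EntropyTrack:
    """Read a per-nucleotide entropy track.

    Lines hold either a single value (implicit 1-based order) or a
    ``position value`` pair; the two dialects may not be mixed.  ``-999`` and
    NaN tokens mark missing data and are preserved as NaN.
    """
    values = np.full(expected_length, np.nan)
    seen = np.zeros(expected_length, dtype=bool)
    one_col_cursor = 0
    n_cols = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        fields = s.split()
        if n_cols is None:
            n_cols = min(len(fields), 2)
        if len(fields) == 1 and n_cols == 1:
            one_col_cursor += 1
            if one_col_cursor > expected_length:
                raise StructureValidationError(
                    f"entropy track longer than expected length {expected_length}"
                )
            values[one_col_cursor - 1] = _parse_value(fields[0], lineno)
            seen[one_col_cursor - 1] = True
        elif len(fields) >= 2 and n_cols == 2:
            pos = _int_field(fields[0], lineno, "position")
            if not 1 <= pos <= expected_length:
                raise StructureValidationError(
                    f"line {lineno}: position {pos} outside 1..{expected_length}"
                )
            if seen[pos - 1]:
                raise StructureParseError(f"line {lineno}: duplicate position {pos}")
            values[pos - 1] = _parse_value(fields[1], lineno)
            seen[pos - 1] = True
        else:
            raise StructureParseError(
                f"line {lineno}: inconsistent column count "
                f"(expected {n_cols}, got {len(fields)})"
            )
    n_seen = int(seen.sum())
    if n_cols == 1 and n_seen != expected_length:
        raise StructureValidationError(
            f"entropy track has {n_seen} values, expected {expected_length}"
        )
    if n_cols == 2 and n_seen != expected_length:
        raise StructureValidationError(
            f"entropy track covers {n_seen} positions, expected {expected_length}"
        )
    finite = values[~np.isnan(values)]
    if finite.size and finite.min() < 0:
        bad = int(np.flatnonzero(values < 0)[0]) + 1
        raise StructureValidationError(
            f"negative entropy {values[bad - 1]} at position {bad}"
        )
    return EntropyTrack(values=values)


def write_track(values, positions=None, precision: int = 6) -> str:
    """Serialize a per-nucleotide track as two-column tab-delimited text.

    Missing values (NaN) are written with the fixed sentinel so the output
    round-trips through :func:`read_entropy`.
    """
    values = np.asarray(values, dtype=np.float64)
    if positions is None:
        positions = np.arange(1, values.size + 1)
    else:
        positions = np.asarray(positions, dtype=np.int64)
    if positions.size != values.size:
        raise ValueError(
            f"positions length {positions.size} != values length {values.size}"
        )
    lines = []
    for p, v in zip(positions, values):
        tok = f"{MISSING_SENTINEL:g}" if math.isnan(v) else f"{v:.{precision}g}"
        lines.append(f"{p}\t{tok}")
    return "\n".join(lines) + "\n"


def to_ct(structure: SecondaryStructure, title: str = "") -> str:
    """Write the six-column connectivity-table representation."""
    n = structure.length
    out = [f"{n} {title}".rstrip()]
    for i in range(1, n + 1):
        base = structure.sequence[i - 1]
        nxt = i + 1 if i < n else 0
        out.append(f"{i} {base} {i - 1} {nxt} {int(structure.pairing[i - 1])} {i}")
    return "\n".join(out) + "\n"


def to_dotbracket(structure: SecondaryStructure, header: str | None = None) -> str:
    """Write dot-bracket notation, assigning crossing pairs to higher tiers.

    Pairs are taken in order of opening position; each pair goes to the first
    bracket tier in which it does not cross an already-placed pair.  Raises if
    more than four mutually crossing tiers would be needed.
    """
    n = structure.length
    chars = ["."] * n
    pairs = [
        (i + 1, int(j))
        for i, j in enumerate(structure.pairing)
        if j > i + 1
    ]
    placed: list[list[tuple[int, int]]] = [[] for _ in BRACKET_TIERS]
    for i, j in pairs:
        for tier, existing in enumerate(placed):
            if all(not (a < i < b < j or i < a < j < b) for a, b in existing):
                existing.append((i, j))
                o, c = BRACKET_TIERS[tier]
                chars[i - 1], chars[j - 1] = o, c
                break
        else:
            raise StructureValidationError(
                f"pair {i}-{j} requires more than {len(BRACKET_TIERS)} bracket tiers"
            )
    body = "".join(chars)
    if header is not None:
        return f">{header}\n{structure.sequence}\n{body}\n"
    return body + "\n"
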