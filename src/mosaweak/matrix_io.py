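"""Readers and writers for character matrices, character settings, tip
ages, and the clade-definition registry.

The matrix dialect supported is TNT's ``xread`` block: an optional quoted
title, ``<n_char> <n_taxa>``, one row per OTU, states coded ``0``–``9``,
``?``/``-`` for full ambiguity, and multi-state cells in ``[..]`` or
``{..}`` brackets.  Comments between single quotes are ignored.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

__all__ = [
    "CharacterMatrix", "CharacterSettings", "TipCalibration", "MatrixParseError",
    "read_tnt_matrix", "parse_tnt", "write_tnt", "read_ordered_set",
    "read_tip_ages", "read_definitions",
]

FULL_AMBIGUITY = None  # sentinel stored for '?'/'-' before expansion


class MatrixParseError(ValueError):
    pass


@dataclass
class CharacterMatrix:
    """Taxa × discrete characters; each cell a non-empty frozenset of
    integer states (full-ambiguity cells expand to all states of the
    character's model)."""

    taxa: list[str]
    cells: list[list[frozenset]]          # [taxon][character]
    n_char: int
    state_count: list[int]
    weight: list[float] = field(default_factory=list)
    active: list[bool] = field(default_factory=list)

    def __post_init__(self):
        if not self.weight:
            self.weight = [1.0] * self.n_char
        if not self.active:
            self.active = [True] * self.n_char
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixParseError("duplicate taxon labels")
        for row in self.cells:
            if len(row) != self.n_char:
                raise MatrixParseError("ragged matrix row")
        for j in range(self.n_char):
            for i, row in enumerate(self.cells):
                if not row[j]:
                    raise MatrixParseError(f"empty state set at ({i},{j})")
                if max(row[j]) >= self.state_count[j]:
                    raise MatrixParseError(
                        f"state {max(row[j])} out of range for character {j + 1}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def taxon_index(self, label: str) -> int:
        return self.taxa.index(label)

    def column(self, j: int) -> list[frozenset]:
        return [row[j] for row in self.cells]

    def is_full_ambiguity(self, i: int, j: int) -> bool:
        return len(self.cells[i][j]) == self.state_count[j]

    def active_indices(self) -> list[int]:
        return [j for j in range(self.n_char) if self.active[j]]

    def subset_taxa(self, keep: Sequence[str]) -> "CharacterMatrix":
        keep = list(keep)
        idx = [self.taxon_index(t) for t in keep]
        return CharacterMatrix(
            taxa=keep,
            cells=[list(self.cells[i]) for i in idx],
            n_char=self.n_char,
            state_count=list(self.state_count),
            weight=list(self.weight),
            active=list(self.active),
        )

    def resample_characters(self, indices: Sequence[int]) -> "CharacterMatrix":
        """Bootstrap helper: build a matrix whose columns are the given
        (0-based, possibly repeated) character indices."""
        return CharacterMatrix(
            taxa=list(self.taxa),
            cells=[[row[j] for j in indices] for row in self.cells],
            n_char=len(indices),
            state_count=[self.state_count[j] for j in indices],
            weight=[self.weight[j] for j in indices],
            active=[self.active[j] for j in indices],
        )


@dataclass
class CharacterSettings:
    """Which characters are additive and how homoplasy is weighted."""

    ordered_set: frozenset = frozenset()      # 1-based character indices
    weighting: str = "EQUAL"                  # "EQUAL" or "IMPLIED"
    K: float = 3.0

    def __post_init__(self):
        self.ordered_set = frozenset(self.ordered_set)
        if self.weighting not in ("EQUAL", "IMPLIED"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.K <= 0:
            raise ValueError("K must be positive")

    def is_ordered(self, j0: int) -> bool:
        """0-based character index -> additive?"""
        return (j0 + 1) in self.ordered_set

    def validate(self, n_char: int) -> None:
        bad = [j for j in self.ordered_set if not (1 <= j <= n_char)]
        if bad:
            raise ValueError(f"ordered indices out of range: {sorted(bad)}")


@dataclass
class TipCalibration:
    """taxon -> fossil age mean (Mya), with optional [min, max] range."""

    mean: dict
    range: dict = field(default_factory=dict)

    def __post_init__(self):
        for taxon, m in self.mean.items():
            if m <= 0:
                raise ValueError(f"non-positive tip age for {taxon}")
            lo, hi = self.range.get(taxon, (m, m))
            if not (lo <= m <= hi):
                raise ValueError(f"tip age range violated for {taxon}")

    def oldest(self) -> float:
        return max(self.mean.values())


# --------------------------------------------------------------------- TNT
_TOKEN_RE = re.compile(r"\[[^\]]*\]|\{[^}]*\}|\S")


def _strip_comments(text: str) -> str:
    # TNT comments are between single quotes; keep line structure
    out, in_comment = [], False
    for ch in text:
        if ch == "'":
            in_comment = not in_comment
            out.append(" ")
        elif in_comment and ch != "\n":
            out.append(" ")
        else:
            out.append(ch)
    return "".join(out)


def parse_tnt(text: str) -> CharacterMatrix:
    raw_lines = text.splitlines()
    lowered = text.lower()
    m = re.search(r"\bxread\b", lowered)
    if m is None:
        raise MatrixParseError("no xread block found")
    body = _strip_comments(text[m.end():])
    # optional quoted title was stripped with comments; find dimensions
    tokens: list[tuple[str, int]] = []  # (token, line number)
    offset_line = text[: m.end()].count("\n")
    for ln, line in enumerate(body.splitlines(), start=offset_line + 1):
        for tok in line.split(";")[0].split() if ";" in line else line.split():
            tokens.append((tok, ln))
        if ";" in line:
            break
    if len(tokens) < 2:
        raise MatrixParseError("xread block truncated before dimensions")
    try:
        n_char = int(tokens[0][0])
        n_taxa = int(tokens[1][0])
    except ValueError as exc:
        raise MatrixParseError(
            f"bad dimensions near line {tokens[0][1] + 1}: {exc}") from exc

    pos = 2
    taxa: list[str] = []
    rows: list[list[Optional[frozenset]]] = []
    while pos < len(tokens):
        name, name_line = tokens[pos]
        pos += 1
        row: list[Optional[frozenset]] = []
        while pos < len(tokens) and len(row) < n_char:
            chunk, ln = tokens[pos]
            pos += 1
            row.extend(_parse_cells(chunk, ln))
        if len(row) != n_char:
            raise MatrixParseError(
                f"row for {name!r} (line {name_line + 1}) has {len(row)} cells, "
                f"expected {n_char}")
        taxa.append(name)
        rows.append(row)
        if len(taxa) == n_taxa:
            break
    if len(taxa) != n_taxa:
        raise MatrixParseError(
            f"declared {n_taxa} taxa but parsed {len(taxa)}")

    state_count = []
    for j in range(n_char):
        mx = 0
        for row in rows:
            if row[j] is not FULL_AMBIGUITY:
                mx = max(mx, max(row[j]))
        state_count.append(max(mx + 1, 2))
    cells = [
        [frozenset(range(state_count[j])) if row[j] is FULL_AMBIGUITY else row[j]
         for j in range(n_char)]
        for row in rows
    ]
    return CharacterMatrix(taxa=taxa, cells=cells, n_char=n_char,
                           state_count=state_count)


def _parse_cells(chunk: str, line: int) -> list[Optional[frozenset]]:
    out = []
    for tok in _TOKEN_RE.findall(chunk):
        for piece in _iter_cell_tokens(tok, line):
            out.append(piece)
    return out


def _iter_cell_tokens(tok: str, line: int):
    i = 0
    while i < len(tok):
        ch = tok[i]
        if ch in "[{":
            close = "]" if ch == "[" else "}"
            j = tok.find(close, i)
            if j < 0:
                raise MatrixParseError(f"unclosed bracket on line {line + 1}")
            inner = tok[i + 1:j]
            states = frozenset(_state_value(c, line) for c in inner if not c.isspace())
            if not states:
                raise MatrixParseError(f"empty bracket on line {line + 1}")
            yield states
            i = j + 1
        elif ch in "?-":
            yield FULL_AMBIGUITY
            i += 1
        else:
            yield frozenset([_state_value(ch, line)])
            i += 1


def _state_value(ch: str, line: int) -> int:
    if ch.isdigit():
        return int(ch)
    if ch.isalpha():  # TNT allows A=10, B=11, ...
        return 10 + ord(ch.upper()) - ord("A")
    raise MatrixParseError(f"undeclared state symbol {ch!r} on line {line + 1}")


def read_tnt_matrix(path: Union[str, Path]) -> CharacterMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return parse_tnt(path.read_text())


def write_tnt(matrix: CharacterMatrix, path: Union[str, Path],
              title: str = "mosaweak export") -> None:
    def cell(s: frozenset, j: int) -> str:
        if len(s) == matrix.state_count[j]:
            return "?"
        if len(s) == 1:
            return _state_symbol(next(iter(s)))
        return "[" + "".join(_state_symbol(x) for x in sorted(s)) + "]"

    with open(path, "w") as fh:
        fh.write(f"xread\n'{title}'\n{matrix.n_char} {matrix.n_taxa}\n")
        for i, taxon in enumerate(matrix.taxa):
            row = "".join(cell(matrix.cells[i][j], j) for j in range(matrix.n_char))
            fh.write(f"{taxon.replace(' ', '_')}\t{row}\n")
        fh.write(";\n")


def _state_symbol(v: int) -> str:
    return str(v) if v < 10 else chr(ord("A") + v - 10)


def read_ordered_set(path: Union[str, Path]) -> frozenset:
    """One or more whitespace/comma-separated 1-based character indices."""
    text = Path(path).read_text()
    vals = frozenset(int(t) for t in re.split(r"[\s,]+", text.strip()) if t)
    if any(v < 1 for v in vals):
        raise ValueError("ordered character indices are 1-based")
    return vals


# ------------------------------------------------------------------- ages
def read_tip_ages(path: Union[str, Path]) -> TipCalibration:
    """TSV sidecar: ``taxon<TAB>mean[<TAB>min<TAB>max]``; '#' comments."""
    mean, rng = {}, {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() in ("taxon", "otu"):
            continue
        if len(parts) < 2:
            raise ValueError(f"tip-age line {ln}: need taxon and mean")
        taxon = parts[0]
        mean[taxon] = float(parts[1])
        if len(parts) >= 4:
            rng[taxon] = (float(parts[2]), float(parts[3]))
    return TipCalibration(mean=mean, range=rng)


# ------------------------------------------------------------ definitions
def read_definitions(path: Union[str, Path]):
    """Load a JSON clade-definition registry.

    Schema: a list of objects ``{name, type: "node"|"branch",
    internal: [taxon | {"node_of": [taxa]}], external: [...], authorship}``.
    """
    from .definitions import PhyloDefinition, Specifier

    data = json.loads(Path(path).read_text())
    out = []
    for entry in data:
        kind = entry.get("type", "").upper()
        if kind not in ("NODE", "BRANCH"):
            raise ValueError(
                f"{entry.get('name')}: unknown definition type {entry.get('type')!r}")
        internal = [_parse_specifier(s) for s in entry.get("internal", [])]
        external = [_parse_specifier(s) for s in entry.get("external", [])]
        if not internal:
            raise ValueError(f"{entry.get('name')}: empty internal specifier list")
        out.append(PhyloDefinition(
            name=entry["name"], kind=kind, internal=internal, external=external,
            authorship=entry.get("authorship", "")))
    return out


def _parse_specifier(raw):
    from .definitions import Specifier

    if isinstance(raw, str):
        return Specifier(taxon=raw)
    if isinstance(raw, dict) and "node_of" in raw:
        return Specifier(node_of=tuple(raw["node_of"]))
    raise ValueError(f"bad specifier: {raw!r}")
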