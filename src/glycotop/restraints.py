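"""XPLOR-style distance-restraint tables: parsing ``assign`` statements and
counting restraints between two atom selections (e.g. how many NOEs tie a
sugar to the protein — a direct readout of how well-determined the sugar's
pose can be)."""

from __future__ import annotations

import fnmatch
import re
from dataclasses import dataclass
from typing import Sequence

from .ensemble import AtomMeta


class RestraintError(ValueError):
    pass


# ---------------------------------------------------------------------------
# selection expressions
# ---------------------------------------------------------------------------

class SelExpr:
    """Boolean selection over atom metadata; subset of the XPLOR selection
    language: ``segid``, ``resid``, ``resname``, ``name``, ``and``, ``or``,
    ``not``, parentheses, ``*``/``#``/``%`` wildcards in names."""

    def matches(self, atom: AtomMeta) -> bool:
        raise NotImplementedError

    def __call__(self, atom: AtomMeta) -> bool:
        return self.matches(atom)


@dataclass(frozen=True)
class _Prim(SelExpr):
    field: str
    value: str

    def matches(self, atom: AtomMeta) -> bool:
        if self.field == "resid":
            return atom.resnum == int(self.value)
        val = {"segid": atom.chain, "resname": atom.resname,
               "name": atom.name}[self.field]
        pattern = self.value.replace("#", "[0-9]").replace("%", "?")
        return fnmatch.fnmatchcase(val.upper(), pattern.upper())


@dataclass(frozen=True)
class _And(SelExpr):
    parts: tuple
    def matches(self, atom):
        return all(p.matches(atom) for p in self.parts)


@dataclass(frozen=True)
class _Or(SelExpr):
    parts: tuple
    def matches(self, atom):
        return any(p.matches(atom) for p in self.parts)


@dataclass(frozen=True)
class _Not(SelExpr):
    part: SelExpr
    def matches(self, atom):
        return not self.part.matches(atom)


_FIELDS = {"segi": "segid", "resi": "resid", "resn": "resname",
           "name": "name", "atom": "name"}


def parse_selection(text: str) -> SelExpr:
    """Parse one selection expression (without its outer parentheses)."""
    toks = re.findall(r"\(|\)|[^\s()]+", text)
    expr, rest = _parse_or(toks, 0)
    if rest != len(toks):
        raise RestraintError(f"trailing tokens in selection: {toks[rest:]}")
    return expr


def _parse_or(toks, i):
    left, i = _parse_and(toks, i)
    parts = [left]
    while i < len(toks) and toks[i].lower() == "or":
        nxt, i = _parse_and(toks, i + 1)
        parts.append(nxt)
    return (parts[0] if len(parts) == 1 else _Or(tuple(parts))), i


def _parse_and(toks, i):
    left, i = _parse_unit(toks, i)
    parts = [left]
    while i < len(toks) and toks[i].lower() == "and":
        nxt, i = _parse_unit(toks, i + 1)
        parts.append(nxt)
    return (parts[0] if len(parts) == 1 else _And(tuple(parts))), i


def _parse_unit(toks, i):
    if i >= len(toks):
        raise RestraintError("unexpected end of selection")
    t = toks[i]
    if t == "(":
        expr, i = _parse_or(toks, i + 1)
        if i >= len(toks) or toks[i] != ")":
            raise RestraintError("unbalanced parentheses in selection")
        return expr, i + 1
    if t.lower() == "not":
        expr, i = _parse_unit(toks, i + 1)
        return _Not(expr), i
    key = t[:4].lower()
    if key in _FIELDS:
        if i + 1 >= len(toks):
            raise RestraintError(f"selection keyword {t!r} without a value")
        return _Prim(_FIELDS[key], toks[i + 1]), i + 2
    raise RestraintError(f"unknown selection token {t!r}")


# ---------------------------------------------------------------------------
# restraint records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RestraintRecord:
    """One ``assign (selA) (selB) d dminus dplus`` distance restraint."""

    sel_a: SelExpr
    sel_b: SelExpr
    distance: float
    dminus: float
    dplus: float
    line: int

    @property
    def lower(self) -> float:
        return self.distance - self.dminus

    @property
    def upper(self) -> float:
        return self.distance + self.dplus


def parse_distance_restraints(text: str) -> list[RestraintRecord]:
    """Parse every ``assign`` statement; statements may span lines, ``!``
    starts a comment.  Malformed statements raise with the line number."""
    # strip comments but remember line numbers per character
    records = []
    clean_lines = [(_strip(line), n) for n, line in enumerate(text.splitlines(), 1)]
    joined = "\n".join(line for line, _ in clean_lines)
    for m in re.finditer(r"(?is)\bassi\w*\s*(.*?)(?=\bassi\w*\b|\Z)", joined):
        body = m.group(1)
        line_no = joined[:m.start()].count("\n") + 1
        sels = _balanced_groups(body, line_no)
        if len(sels) < 2:
            raise RestraintError(
                f"line {line_no}: assign needs two parenthesized selections")
        tail = body
        for s in sels[:2]:
            tail = tail.replace(f"({s})", " ", 1)
        nums = re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", tail)
        if len(nums) < 3:
            raise RestraintError(
                f"line {line_no}: assign needs d, dminus, dplus")
        records.append(RestraintRecord(
            parse_selection(sels[0]), parse_selection(sels[1]),
            float(nums[0]), float(nums[1]), float(nums[2]), line_no))
    return records


def _strip(line: str) -> str:
    i = line.find("!")
    return line if i < 0 else line[:i]


def _balanced_groups(text: str, line_no: int) -> list[str]:
    """Top-level parenthesized groups of a statement body."""
    groups = []
    depth = 0
    start = 0
    for i, ch in enumerate(text):
        if ch == "(":
            if depth == 0:
                start = i + 1
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise RestraintError(f"line {line_no}: unbalanced parentheses")
            if depth == 0:
                groups.append(text[start:i])
    if depth != 0:
        raise RestraintError(f"line {line_no}: unbalanced parentheses")
    return groups


def count_between(records: Sequence[RestraintRecord],
                  selection_a, selection_b,
                  atoms: Sequence[AtomMeta]) -> int:
    """Number of restraints with one member inside ``selection_a`` and the
    other inside ``selection_b`` (symmetric in the two selections).

    A restraint member is "inside" a selection when some atom of the roster
    satisfies both the member's own selection and the query selection.
    """
    if isinstance(selection_a, str):
        selection_a = parse_selection(selection_a)
    if isinstance(selection_b, str):
        selection_b = parse_selection(selection_b)

    def hits(member: SelExpr, query) -> bool:
        return any(member.matches(a) and query(a) for a in atoms)

    n = 0
    for r in records:
        ab = hits(r.sel_a, selection_a) and hits(r.sel_b, selection_b)
        ba = hits(r.sel_a, selection_b) and hits(r.sel_b, selection_a)
        if ab or ba:
            n += 1
    return n
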