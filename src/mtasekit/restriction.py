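"""Restriction enzymes with explicit methylation-sensitivity semantics.

Each enzyme carries an IUPAC recognition motif, a top-strand cut offset and
a list of sensitivity rules.  A rule watches specific cytosines of the
recognition duplex, given as (position-within-motif, motif-relative strand)
pairs, and fires in one of two modes:

* ``any``  — blocked when at least one watched cytosine carries 5mC;
* ``both`` — blocked only when every watched cytosine carries 5mC (used
  for rules that require the site to be methylated on both strands).

A site is blocked if any of its enzyme's rules fires.  Only the cytosines a
rule names are watched; 5mC elsewhere inside the recognition sequence does
not block cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .sequence import DuplexSequence, IUPAC_EXPANSION, SiteMatch, is_palindromic, _validate_iupac
from .methylation import MethylationState

MODES = ("any", "both")
_MODE_ALIASES = {
    "any": "any", "blocked_if_any_strand": "any",
    "both": "both", "blocked_if_both_strands": "both",
}


@dataclass(frozen=True)
class SensitivityRule:
    """Watched cytosines plus blocking mode.

    ``positions`` are (1-based position within the motif, strand) pairs;
    the strand is relative to the motif's own reading ("top" = the strand
    the motif is written on, "bottom" = its complement).
    """

    positions: tuple
    mode: str
    note: str = ""

    def __post_init__(self) -> None:
        mode = _MODE_ALIASES.get(self.mode)
        if mode is None:
            raise ValueError(f"unknown blocking mode {self.mode!r}")
        object.__setattr__(self, "mode", mode)
        positions = tuple((int(p), s) for p, s in self.positions)
        if not positions:
            raise ValueError("rule must watch at least one cytosine")
        for p, s in positions:
            if s not in ("top", "bottom"):
                raise ValueError(f"watched strand must be top/bottom, got {s!r}")
        object.__setattr__(self, "positions", positions)

    def validate_against(self, motif: str) -> None:
        for p, s in self.positions:
            if not 1 <= p <= len(motif):
                raise ValueError(f"watched position {p} outside motif {motif}")
            letter = motif[p - 1]
            expansion = IUPAC_EXPANSION[letter]
            # a C exists on the watched strand in >=1 concretization
            ok = ("C" in expansion) if s == "top" else ("G" in expansion)
            if not ok:
                raise ValueError(
                    f"watched position {p}:{s} of motif {motif} can never be a cytosine")


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    motif: str
    cut_offset: int
    rules: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        motif = _validate_iupac(self.motif, f"motif of {self.name}")
        object.__setattr__(self, "motif", motif)
        if not 0 <= self.cut_offset <= len(motif):
            raise ValueError(f"{self.name}: cut_offset must be within 0..{len(motif)}")
        rules = tuple(self.rules)
        for r in rules:
            r.validate_against(motif)
        object.__setattr__(self, "rules", rules)

    @property
    def is_palindromic(self) -> bool:
        return is_palindromic(self.motif)


def _watched_duplex_coordinates(site: SiteMatch, enz: RestrictionEnzyme, length: int,
                                circular: bool, rule: SensitivityRule) -> list[tuple[str, int]]:
    """Map motif-relative watched positions to absolute duplex coordinates."""
    m = len(enz.motif)
    coords = []
    for p, s in rule.positions:
        if site.strand == "top":
            col = site.start + p - 1
            strand = s
        else:  # motif read along the bottom strand: mirror the column, swap strands
            col = site.start + (m - p)
            strand = "bottom" if s == "top" else "top"
        if circular:
            col = (col - 1) % length + 1
        coords.append((strand, col))
    return coords


def is_blocked(seq: DuplexSequence, meth: MethylationState, site: SiteMatch,
               enz: RestrictionEnzyme) -> tuple[bool, list[SensitivityRule]]:
    """Evaluate every sensitivity rule of ``enz`` at ``site``.

    Returns (blocked, list of rules that fired).
    """
    if site.motif_id not in (enz.name, enz.motif):
        raise ValueError(f"site {site.motif_id!r} is not a match of enzyme {enz.name}")
    fired = []
    for rule in enz.rules:
        coords = _watched_duplex_coordinates(site, enz, len(seq), seq.is_circular, rule)
        hits = [c in meth.marks for c in coords]
        ok = any(hits) if rule.mode == "any" else all(hits)
        if ok:
            fired.append(rule)
    return bool(fired), fired


# -- enzyme table serialization -------------------------------------------
#
# TSV columns: name, motif, cut_offset, rules, note
# rules syntax: rule(;rule)* with rule = "pos:strand(,pos:strand)*|mode"

def _parse_rules(text: str, note: str = "") -> tuple:
    rules = []
    for chunk in filter(None, (c.strip() for c in text.split(";"))):
        try:
            pos_part, mode = chunk.split("|")
            positions = tuple(
                (int(p), s) for p, s in
                (item.split(":") for item in pos_part.split(","))
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed rule {chunk!r}") from exc
        rules.append(SensitivityRule(positions, mode.strip(), note))
    return tuple(rules)


def _format_rules(rules: Iterable[SensitivityRule]) -> str:
    return ";".join(
        ",".join(f"{p}:{s}" for p, s in r.positions) + "|" + r.mode for r in rules
    )


def load_enzyme_table(lines: Iterable[str]) -> list[RestrictionEnzyme]:
    """Parse a tab-separated enzyme table; malformed rows raise with the
    row and field named."""
    enzymes = []
    for lineno, raw in enumerate(lines, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"row {lineno}: expected >=4 tab-separated fields, got {len(parts)}")
        name, motif, offset, rules_text = parts[:4]
        note = parts[4] if len(parts) > 4 else ""
        try:
            cut_offset = int(offset)
        except ValueError as exc:
            raise ValueError(f"row {lineno} ({name}): field cut_offset is not an integer") from exc
        try:
            rules = _parse_rules(rules_text, note)
            enzymes.append(RestrictionEnzyme(name, motif, cut_offset, rules))
        except ValueError as exc:
            raise ValueError(f"row {lineno} ({name}): {exc}") from exc
    if not enzymes:
        import warnings
        warnings.warn("enzyme table contained no enzymes")
    return enzymes


def format_enzyme_table(enzymes: Iterable[RestrictionEnzyme]) -> str:
    lines = ["#name\tmotif\tcut_offset\trules\tnote"]
    for e in enzymes:
        note = e.rules[0].note if e.rules else ""
        lines.append(f"{e.name}\t{e.motif}\t{e.cut_offset}\t{_format_rules(e.rules)}\t{note}")
    return "\n".join(lines) + "\n"


def shipped_enzymes() -> dict[str, RestrictionEnzyme]:
    """The nine methylation-sensitive enzymes of the assay panel, keyed by name."""
    from importlib.resources import files
    text = files("mtasekit.data").joinpath("enzymes.tsv").read_text()
    return {e.name: e for e in load_enzyme_table(text.splitlines())}
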