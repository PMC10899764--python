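"""DNA methyltransferase specificity hypotheses and applying 5mC marks.

An MTase hypothesis is a set of core target dinucleotides (the methylated
base is the 5' C of CG/CA/CC/CT) plus multiplicative flanking-preference
weights for the bases immediately before the C and after the dinucleotide.
The two strands of a duplex are methylated in independent events, so marks
are per-strand, per-position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np

from .sequence import CIRCULAR, LINEAR, DuplexSequence, complement_base

CORE_DINUCLEOTIDES = ("CG", "CA", "CC", "CT")
BASES = "ACGT"

FLAT_WEIGHTS = {b: 1.0 for b in BASES}


def _check_weights(w: dict, which: str) -> dict:
    w = dict(w)
    for b in BASES:
        w.setdefault(b, 1.0)
    for b, v in w.items():
        if b not in BASES:
            raise ValueError(f"{which} weight for unknown base {b!r}")
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{which} weight for {b} must be in [0,1], got {v}")
    return w


@dataclass(frozen=True)
class MTaseSpecificity:
    """Core dinucleotide set + flanking preferences + per-strand efficiency.

    All flank weights 1 reproduces pure dinucleotide specificity.  An empty
    core denotes an inactive enzyme (used as the no-methylation baseline
    hypothesis and for dead mutants in selection simulations).
    """

    name: str
    core: frozenset = frozenset()
    flank5_weights: dict = field(default_factory=lambda: dict(FLAT_WEIGHTS))
    flank3_weights: dict = field(default_factory=lambda: dict(FLAT_WEIGHTS))
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        core = frozenset(d.upper() for d in self.core)
        bad = core - set(CORE_DINUCLEOTIDES)
        if bad:
            raise ValueError(f"core dinucleotides must be drawn from CG/CA/CC/CT, got {sorted(bad)}")
        object.__setattr__(self, "core", core)
        object.__setattr__(self, "flank5_weights", _check_weights(self.flank5_weights, "flank5"))
        object.__setattr__(self, "flank3_weights", _check_weights(self.flank3_weights, "flank3"))
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must be in [0,1]")

    @classmethod
    def simple(cls, cores: Iterable[str], name: Optional[str] = None, efficiency: float = 1.0) -> "MTaseSpecificity":
        """Pure dinucleotide specificity (all flank weights 1)."""
        cores = sorted({c.upper() for c in cores})
        return cls(name or "+".join(cores), frozenset(cores), efficiency=efficiency)

    @classmethod
    def inactive(cls, name: str = "none") -> "MTaseSpecificity":
        return cls(name, frozenset(), efficiency=0.0)

    @property
    def is_inactive(self) -> bool:
        return not self.core


# Qualitative flank ordering of the evolved CC-specific quadruple mutant
# (strong 3' preference for A, weaker for C, 3' G/T very poor; 5' A least
# preferred).  These numbers are a configurable stand-in for a graphically
# reported ordering, not measured weights.
QUADRUPLE_MUTANT_CC = MTaseSpecificity(
    name="quadruple_mutant_CC",
    core=frozenset({"CC"}),
    flank5_weights={"G": 1.0, "C": 1.0, "T": 1.0, "A": 0.4},
    flank3_weights={"A": 1.0, "C": 0.6, "G": 0.05, "T": 0.05},
)

WILD_TYPE_CG = MTaseSpecificity.simple({"CG"}, name="wild_type_CG")


@dataclass(frozen=True)
class MethylationState:
    """Set of (strand, 1-based top-strand position) pairs carrying 5mC."""

    marks: frozenset = frozenset()

    def __post_init__(self) -> None:
        marks = frozenset(self.marks)
        for strand, pos in marks:
            if strand not in ("top", "bottom"):
                raise ValueError(f"mark strand must be top/bottom, got {strand!r}")
        object.__setattr__(self, "marks", marks)

    def __len__(self) -> int:
        return len(self.marks)

    def __contains__(self, item) -> bool:
        return item in self.marks

    def validate(self, seq: DuplexSequence) -> None:
        """Check every mark sits on a cytosine of the indicated strand."""
        L = len(seq)
        for strand, pos in self.marks:
            if not 1 <= pos <= L:
                raise ValueError(f"mark position {pos} outside 1..{L}")
            base = seq.top_base(pos) if strand == "top" else seq.bottom_base(pos)
            if base != "C":
                raise ValueError(f"mark at {strand}:{pos} is on {base!r}, not C")

    def union(self, other: "MethylationState") -> "MethylationState":
        return MethylationState(self.marks | other.marks)


class TargetSite(NamedTuple):
    """An eligible methylation target: a C forming a core dinucleotide."""

    strand: str
    position: int            # top-strand coordinate of the C
    core: str                # the dinucleotide (C + its 3' neighbor)
    flank5: Optional[str]    # base 5' of the C on the same strand
    flank3: Optional[str]    # base 3' of the dinucleotide on the same strand
    weight: float


def list_target_sites(seq: DuplexSequence, spec: MTaseSpecificity) -> list[TargetSite]:
    """Every C on either strand whose 3' neighbor forms a core dinucleotide.

    site weight = flank5_weight[5' base] x flank3_weight[3' base]; a flank
    past the end of a linear duplex contributes a neutral factor 1.  Sites
    inside restriction recognition sequences are listed like any other.
    """
    out: list[TargetSite] = []
    if spec.is_inactive:
        return out
    L = len(seq)
    for pos in range(1, L + 1):
        # top strand: C at pos, partner at pos+1, flanks pos-1 / pos+2
        if seq.top_base(pos) == "C":
            nxt = seq.top_base(pos + 1)
            if nxt is not None and "C" + nxt in spec.core:
                f5, f3 = seq.top_base(pos - 1), seq.top_base(pos + 2)
                w = (spec.flank5_weights[f5] if f5 else 1.0) * (spec.flank3_weights[f3] if f3 else 1.0)
                out.append(TargetSite("top", pos, "C" + nxt, f5, f3, w))
        # bottom strand runs 3'->5' in top coordinates: the bottom C at pos
        # has its 3' neighbor at pos-1 and 5' neighbor at pos+1
        if seq.bottom_base(pos) == "C":
            nxt = seq.bottom_base(pos - 1)
            if nxt is not None and "C" + nxt in spec.core:
                f5, f3 = seq.bottom_base(pos + 1), seq.bottom_base(pos - 2)
                w = (spec.flank5_weights[f5] if f5 else 1.0) * (spec.flank3_weights[f3] if f3 else 1.0)
                out.append(TargetSite("bottom", pos, "C" + nxt, f5, f3, w))
    return out


def apply_methylation(
    seq: DuplexSequence,
    spec: MTaseSpecificity,
    mode: str = "deterministic",
    threshold: float = 0.5,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> MethylationState:
    """Methylate a duplex per a specificity hypothesis.

    deterministic: mark every target site whose weight >= ``threshold``.
    stochastic: mark each site independently with probability
    efficiency x weight (strand independence preserved).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0,1]")
    sites = list_target_sites(seq, spec)
    if mode == "deterministic":
        marks = {(s.strand, s.position) for s in sites if s.weight >= threshold}
    elif mode == "stochastic":
        if rng is None:
            if seed is None:
                raise ValueError("stochastic mode requires a seed or rng")
            rng = np.random.default_rng(seed)
        marks = set()
        for s in sites:
            if rng.random() < spec.efficiency * s.weight:
                marks.add((s.strand, s.position))
    else:
        raise ValueError(f"mode must be 'deterministic' or 'stochastic', got {mode!r}")
    return MethylationState(frozenset(marks))


# -- oligonucleotide duplex substrates ------------------------------------

#: constant A/T backbone unit; an all-A/T backbone carries no cytosine on
#: either strand, so the only methylatable sites of an oligo are in the
#: planted cassette
_BACKBONE_UNIT = "AATTAT"


def _backbone(length: int) -> str:
    return (_BACKBONE_UNIT * (length // len(_BACKBONE_UNIT) + 1))[:length]


def build_oligo_duplex(
    flank5: str,
    core: str,
    flank3: str,
    length: int = 23,
    premeth: Optional[tuple[str, str]] = None,
    name: Optional[str] = None,
) -> tuple[DuplexSequence, MethylationState]:
    """Linear duplex with a variable cassette centered in a fixed backbone.

    The cassette is ``flank5 + core + flank3`` with ``core`` a 2- or 4-mer;
    the surrounding backbone is a constant A/T sequence free of any
    CG/CA/CC/CT target on either strand.  ``premeth`` places one 5mC mark,
    given as (strand, dinucleotide) where the dinucleotide names the
    palindromic core to premethylate (the hemimethylated CG control).
    """
    flank5, core, flank3 = flank5.upper(), core.upper(), flank3.upper()
    cassette = flank5 + core + flank3
    if set(cassette) - set(BASES):
        raise ValueError("cassette must be concrete A/C/G/T bases")
    if len(core) not in (2, 4):
        raise ValueError("core must be a dinucleotide or a 4-mer")
    if length < len(core) + 4:
        raise ValueError(f"length {length} too short for core of {len(core)} bases")
    if length < len(cassette) + 2:
        raise ValueError("cassette does not fit the backbone with margins")
    bb = _backbone(length)
    start0 = (length - len(cassette)) // 2
    residues = bb[:start0] + cassette + bb[start0 + len(cassette):]
    seq = DuplexSequence(residues, LINEAR, name or f"oligo_{cassette}")

    marks: frozenset = frozenset()
    if premeth is not None:
        strand, dinuc = premeth
        dinuc = dinuc.upper()
        idx = core.find(dinuc)
        if idx < 0 or dinuc not in CORE_DINUCLEOTIDES:
            raise ValueError(f"premethylation dinucleotide {dinuc!r} not found in core {core!r}")
        c_pos = start0 + len(flank5) + idx + 1  # top coordinate of the dinucleotide's C
        if strand == "top":
            marks = frozenset({("top", c_pos)})
        elif strand == "bottom":
            # the bottom-strand C of a palindromic dinucleotide pairs with
            # the top-strand partner base (a G for CG)
            if dinuc != "CG":
                raise ValueError("bottom-strand premethylation is defined for the palindromic CG core")
            marks = frozenset({("bottom", c_pos + 1)})
        else:
            raise ValueError(f"premeth strand must be top/bottom, got {strand!r}")
    state = MethylationState(marks)
    state.validate(seq)
    return seq, state
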