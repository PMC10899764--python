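"""In silico digestion of a (sequence, methylation state) pair.

Deterministic mode performs a complete digest: every recognition site not
blocked by a sensitivity rule is cut.  Partial bands are modeled solely as
molecule-to-molecule methylation heterogeneity in population mode, never
as stochastic enzyme failure.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .sequence import DuplexSequence, scan_motif
from .methylation import MethylationState, MTaseSpecificity, apply_methylation
from .restriction import RestrictionEnzyme, is_blocked

UNCUT_CIRCULAR = "uncut_circular"
CUT = "cut"


@dataclass(frozen=True)
class FragmentSet:
    """Digestion output: status plus a multiset of fragment lengths.

    Fragment lengths are exact; gel-resolution blur belongs to the
    pattern-comparison tolerance, not here.  ``cut_positions`` are the
    top-strand coordinates after which the duplex is cleaved.
    """

    status: str
    fragments: tuple
    cut_positions: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragments", tuple(sorted(self.fragments, reverse=True)))
        object.__setattr__(self, "cut_positions", tuple(sorted(self.cut_positions)))

    @property
    def n_cuts(self) -> int:
        return len(self.cut_positions)

    def is_full_length_linear(self, length: int) -> bool:
        return self.status == CUT and self.fragments == (length,)


def _cut_coordinate(site, enz: RestrictionEnzyme, length: int, circular: bool) -> Optional[int]:
    """Top-strand coordinate after which this site's cut falls."""
    m = len(enz.motif)
    if site.strand == "top":
        c = site.start + enz.cut_offset - 1
    else:
        c = site.start + (m - enz.cut_offset) - 1
    if circular:
        return (c - 1) % length + 1 if c != 0 else length
    return c if 1 <= c <= length - 1 else None  # boundary cuts free no fragment


def digest(seq: DuplexSequence, meth: MethylationState,
           enzymes: Iterable[RestrictionEnzyme]) -> FragmentSet:
    """Complete digest: cut at every site not blocked under ``meth``.

    Deterministic and origin-independent; coincident cuts count once.
    """
    L = len(seq)
    cuts = set()
    for enz in enzymes:
        for site in scan_motif(seq, enz.motif, motif_id=enz.name):
            blocked, _ = is_blocked(seq, meth, site, enz)
            if not blocked:
                c = _cut_coordinate(site, enz, L, seq.is_circular)
                if c is not None:
                    cuts.add(c)
    cuts_sorted = sorted(cuts)
    if seq.is_circular:
        if not cuts_sorted:
            return FragmentSet(UNCUT_CIRCULAR, (), ())
        if len(cuts_sorted) == 1:
            return FragmentSet(CUT, (L,), tuple(cuts_sorted))
        frags = [b - a for a, b in zip(cuts_sorted, cuts_sorted[1:])]
        frags.append(L - cuts_sorted[-1] + cuts_sorted[0])
        return FragmentSet(CUT, tuple(frags), tuple(cuts_sorted))
    bounds = [0] + cuts_sorted + [L]
    frags = [b - a for a, b in zip(bounds, bounds[1:])]
    return FragmentSet(CUT, tuple(frags), tuple(cuts_sorted))


@dataclass(frozen=True)
class BandProfile:
    """Length -> DNA-mass fraction over a simulated molecule population.

    ``uncut_mass`` is the mass fraction remaining as uncut circles; band
    fractions plus uncut mass sum to 1.
    """

    bands: dict
    uncut_mass: float
    n_molecules: int

    def total_mass(self) -> float:
        return self.uncut_mass + sum(self.bands.values())


def digest_population(seq: DuplexSequence, spec: MTaseSpecificity,
                      enzymes: Iterable[RestrictionEnzyme], n_molecules: int,
                      seed: int) -> BandProfile:
    """Simulate ``n_molecules`` independent stochastic methylation states,
    digest each and aggregate band intensities (seeded, reproducible)."""
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    enzymes = list(enzymes)
    rng = np.random.default_rng(seed)
    L = len(seq)
    bands: dict[int, float] = defaultdict(float)
    uncut = 0.0
    per_molecule = 1.0 / n_molecules
    for _ in range(n_molecules):
        meth = apply_methylation(seq, spec, mode="stochastic", rng=rng)
        fs = digest(seq, meth, enzymes)
        if fs.status == UNCUT_CIRCULAR:
            uncut += per_molecule
        else:
            for frag in fs.fragments:
                bands[frag] += per_molecule * frag / L
    return BandProfile(dict(bands), uncut, n_molecules)
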