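"""Duplex DNA sequences and IUPAC motif scanning.

The package models double-stranded DNA as a top strand (5'->3') plus
implicit Watson-Crick complement.  All coordinates are 1-based, inclusive,
on the top strand; bottom-strand features are reported in top-strand
coordinates.  Circular sequences use modular position arithmetic, so a
motif (or a flanking base) may wrap across the origin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

#: expansion of every IUPAC nucleotide letter into its concrete base set
IUPAC_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CIRCULAR = "circular"
LINEAR = "linear"


def _validate_iupac(s: str, what: str = "sequence") -> str:
    s = s.upper()
    for ch in s:
        if ch not in IUPAC_EXPANSION:
            raise ValueError(f"invalid IUPAC letter {ch!r} in {what}")
    return s


def reverse_complement(s: str) -> str:
    """Reverse complement of a base string; degenerate letters map to their
    complements (W<->W, M<->K, S<->S, ...)."""
    return _validate_iupac(s).translate(_COMPLEMENT)[::-1]


def complement_base(b: Optional[str]) -> Optional[str]:
    if b is None:
        return None
    return _validate_iupac(b, "base").translate(_COMPLEMENT)


@dataclass(frozen=True)
class DuplexSequence:
    """Double-stranded DNA: concrete top strand plus topology.

    ``residues`` is the top strand 5'->3' over {A,C,G,T}; degenerate
    letters are allowed only in motifs, never in concrete sequences.
    """

    residues: str
    topology: str = CIRCULAR
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one base")
        bad = set(self.residues) - set("ACGT")
        if bad:
            raise ValueError(f"concrete sequence may contain only A/C/G/T, found {sorted(bad)}")
        if self.topology not in (CIRCULAR, LINEAR):
            raise ValueError(f"topology must be 'circular' or 'linear', got {self.topology!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_circular(self) -> bool:
        return self.topology == CIRCULAR

    def top_base(self, pos: int) -> Optional[str]:
        """Top-strand base at 1-based position ``pos``.

        Circular sequences wrap (position L+1 == position 1); linear
        sequences return ``None`` outside 1..L (the distinguished "no
        flank" value).
        """
        L = len(self.residues)
        if self.is_circular:
            return self.residues[(pos - 1) % L]
        if 1 <= pos <= L:
            return self.residues[pos - 1]
        return None

    def bottom_base(self, pos: int) -> Optional[str]:
        """Bottom-strand base paired at top-strand position ``pos``."""
        return complement_base(self.top_base(pos))


@dataclass(frozen=True)
class SiteMatch:
    """One motif match, reported in top-strand coordinates.

    For a palindromic motif the two strand-symmetric matches at a locus are
    collapsed into a single ``SiteMatch`` (strand="top") carrying flank
    annotations for both strands.  Flanks are the single bases adjacent to
    the site on each strand; ``None`` marks a flank beyond the end of a
    linear sequence.
    """

    motif_id: str
    start: int
    strand: str
    matched: str
    flank5_top: Optional[str]
    flank3_top: Optional[str]
    flank5_bottom: Optional[str]
    flank3_bottom: Optional[str]

    def __len__(self) -> int:
        return len(self.matched)

    @property
    def end(self) -> int:
        """Rightmost footprint coordinate (may exceed L when wrapping)."""
        return self.start + len(self.matched) - 1


def is_palindromic(motif: str) -> bool:
    """True when the motif equals its own reverse complement (after
    degenerate expansion; letterwise equality suffices for IUPAC codes)."""
    motif = _validate_iupac(motif, "motif")
    return reverse_complement(motif) == motif


def _motif_regex(motif: str) -> "re.Pattern[str]":
    parts = [f"[{IUPAC_EXPANSION[ch]}]" for ch in motif]
    return re.compile("(?=(" + "".join(parts) + "))")


def _flanks(seq: DuplexSequence, start: int, m: int):
    f5t = seq.top_base(start - 1)
    f3t = seq.top_base(start + m)
    return f5t, f3t, complement_base(f3t), complement_base(f5t)


def scan_motif(seq: DuplexSequence, motif: str, motif_id: Optional[str] = None) -> list[SiteMatch]:
    """All matches of an IUPAC ``motif`` on both strands of ``seq``.

    Palindromic motifs yield one ``SiteMatch`` per locus with per-strand
    flank annotations; non-palindromic motifs yield separate top and
    bottom matches (bottom matches report the leftmost top-strand
    coordinate of the footprint as ``start`` and the bottom-strand 5'->3'
    reading as ``matched``).  Circular sequences report matches spanning
    the origin once.
    """
    motif = _validate_iupac(motif, "motif")
    if not motif:
        raise ValueError("motif must be non-empty")
    mid = motif_id if motif_id is not None else motif
    m = len(motif)
    L = len(seq)
    pat = _motif_regex(motif)

    text = seq.residues + (seq.residues[: m - 1] if seq.is_circular and m > 1 else "")
    sites: list[SiteMatch] = []
    for hit in pat.finditer(text):
        i = hit.start()
        if i >= L:
            break
        matched = text[i: i + m]
        f5t, f3t, f5b, f3b = _flanks(seq, i + 1, m)
        sites.append(SiteMatch(mid, i + 1, "top", matched, f5t, f3t, f5b, f3b))

    if not is_palindromic(motif):
        rc = reverse_complement(seq.residues)
        rc_text = rc + (rc[: m - 1] if seq.is_circular and m > 1 else "")
        seen = {s.start for s in sites}  # distinct strands; starts may legitimately collide
        for hit in pat.finditer(rc_text):
            j = hit.start()
            if j >= L:
                break
            matched = rc_text[j: j + m]
            start = (L - j - m) % L + 1 if seq.is_circular else L - j - m + 1
            f5t, f3t, f5b, f3b = _flanks(seq, start, m)
            sites.append(SiteMatch(mid, start, "bottom", matched, f5t, f3t, f5b, f3b))
        del seen
    return sorted(sites, key=lambda s: (s.start, s.strand))


def dinucleotide_context(seq: DuplexSequence, site: SiteMatch, anchor: int, strand: str) -> str:
    """2-mer formed by an anchored cytosine of a site and its 3' neighbor.

    ``anchor`` is the 1-based position of the C within the site, counted
    along the given physical strand's own 5'->3' reading of the footprint
    (so the terminal C of a palindromic motif has the same anchor on both
    strands).  The neighbor may lie outside the site boundary.
    """
    m = len(site)
    if not 1 <= anchor <= m:
        raise ValueError(f"anchor {anchor} outside motif of length {m}")
    if strand == "top":
        pos = site.start + anchor - 1
        base = seq.top_base(pos)
        if base != "C":
            raise ValueError(f"anchor base at top:{pos} is {base!r}, not C")
        nxt = seq.top_base(pos + 1)
    elif strand == "bottom":
        pos = site.start + (m - anchor)
        base = seq.bottom_base(pos)
        if base != "C":
            raise ValueError(f"anchor base at bottom:{pos} is {base!r}, not C")
        nxt = seq.bottom_base(pos - 1)
    else:
        raise ValueError(f"strand must be 'top' or 'bottom', got {strand!r}")
    if nxt is None:
        raise ValueError("anchored C has no 3' neighbor (end of linear sequence)")
    return "C" + nxt
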