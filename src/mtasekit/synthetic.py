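"""Synthetic plasmids and oligonucleotide panels.

The real assay plasmids are not publicly deposited, so every input the
pipeline needs is generated here: a circular 6421 bp plasmid whose three
Alw44I sites reproduce the printed complete-digest arithmetic
(1935/3986/500) and flanking contexts; a selection plasmid whose three
Eco47I sites cover the CA/CC/CT contexts while excluding CG; random
plasmids with planted sites; one-codon deletion variants; and the 23-mer
oligo substrate panels.  All generators are seeded and byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .sequence import (CIRCULAR, DuplexSequence, complement_base, reverse_complement,
                       scan_motif, IUPAC_EXPANSION)
from .methylation import MethylationState, build_oligo_duplex

#: motifs scrubbed from fixture backbones unless explicitly requested
DEFAULT_SCRUB = ("GTGCAC", "GTMKAC", "GGWCC")


@dataclass(frozen=True)
class PlantedSite:
    """A concrete recognition site to embed at a fixed position.

    ``flank3_top``/``flank3_bottom`` are the requested per-strand 3'
    flanking bases (bottom given as the base read on the bottom strand);
    planting writes flank3_top immediately after the site and the
    complement of flank3_bottom immediately before it.
    """

    motif: str
    site: str
    start: int               # 1-based top-strand start
    flank3_top: str
    flank3_bottom: str
    junction: str = ""

    def __post_init__(self) -> None:
        if len(self.site) != len(self.motif):
            raise ValueError("concrete site and motif lengths differ")
        for s, m in zip(self.site, self.motif):
            if s not in IUPAC_EXPANSION[m]:
                raise ValueError(f"planted site {self.site} does not match motif {self.motif}")

    @property
    def end(self) -> int:
        return self.start + len(self.site) - 1


def _matches_not_planted(seq: DuplexSequence, motifs: Iterable[str],
                         planted_footprints: set) -> list:
    bad = []
    for motif in motifs:
        for site in scan_motif(seq, motif):
            if (site.start, len(site)) not in planted_footprints:
                bad.append(site)
    return bad


def make_random_plasmid(length: int, planted: Iterable[PlantedSite], seed: int,
                        scrub_motifs: Optional[Iterable[str]] = None,
                        topology: str = CIRCULAR) -> DuplexSequence:
    """Seeded random background with sites planted at requested positions
    and flanks; the background is scrubbed of accidental matches to the
    planted (or requested) motifs by local resampling."""
    planted = list(planted)
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    arr = list(rng.choice(bases, size=length))

    protected: set[int] = set()   # 0-based indices that must not be resampled
    footprints: set[tuple[int, int]] = set()
    for p in planted:
        if not 1 <= p.start <= length:
            raise ValueError(f"planted site start {p.start} outside 1..{length}")
        if topology != CIRCULAR and not (2 <= p.start and p.end <= length - 1):
            raise ValueError("planted site and flanks must fit inside a linear sequence")
        left = (p.start - 2) % length     # 0-based index of base before site
        right = p.end % length            # 0-based index of base after site
        window = [(p.start - 1 + k) % length for k in range(len(p.site))]
        for idx in window + [left, right]:
            if idx in protected:
                raise ValueError(f"planted sites/flanks overlap near position {idx + 1}")
        for k, idx in enumerate(window):
            arr[idx] = p.site[k]
        arr[left] = complement_base(p.flank3_bottom)
        arr[right] = p.flank3_top
        protected.update(window + [left, right])
        footprints.add((p.start, len(p.site)))

    motifs = set(m for m in (scrub_motifs if scrub_motifs is not None else DEFAULT_SCRUB))
    motifs.update(p.motif for p in planted)

    for _ in range(2000):
        seq = DuplexSequence("".join(arr), topology, name=f"synthetic_{length}bp")
        offenders = _matches_not_planted(seq, motifs, footprints)
        if not offenders:
            return seq
        for site in offenders:
            idxs = [(site.start - 1 + k) % length for k in range(len(site))]
            free = [i for i in idxs if i not in protected]
            if not free:
                raise ValueError(
                    f"accidental {site.motif_id} match at {site.start} overlaps planted bases only")
            i = free[int(rng.integers(len(free)))]
            arr[i] = str(rng.choice(bases))
    raise RuntimeError("scrubbing did not converge")


# -- the Alw44I protection fixture ----------------------------------------
#
# Three GTGCAC sites on a 6421 bp circle with complete-digest fragments
# 1935 / 3986 / 500 and per-strand 3'-flank contexts:
#   3986|500 junction -> {A, G}   (protected by CG or CA methylation -> 4486)
#   1935|3986 junction -> {C, C}  (protected by CC methylation)
#   500|1935 junction -> {C, T}   (protected by CC or CT methylation -> 2435)
# The C/C assignment at the 1935|3986 junction is the unique solution of the
# printed protection statements; see the methods note.

ALW44I_LENGTH = 6421
ALW44I_FRAGMENTS = (3986, 1935, 500)


def alw44i_planted_sites() -> list[PlantedSite]:
    s1 = 1000                       # cut coordinates equal the starts (offset 1)
    s2 = s1 + 1935                  # 2935
    s3 = (s2 + 3986) % ALW44I_LENGTH  # 500, wrapping the origin
    return [
        PlantedSite("GTGCAC", "GTGCAC", s3, flank3_top="A", flank3_bottom="G",
                    junction="3986|500"),
        PlantedSite("GTGCAC", "GTGCAC", s1, flank3_top="C", flank3_bottom="T",
                    junction="500|1935"),
        PlantedSite("GTGCAC", "GTGCAC", s2, flank3_top="C", flank3_bottom="C",
                    junction="1935|3986"),
    ]


def make_alw44i_fixture(seed: int = 0) -> DuplexSequence:
    """Circular 6421 bp plasmid reproducing the Alw44I fragment arithmetic
    (4486 = 3986+500, 5921 = 1935+3986, 2435 = 500+1935)."""
    seq = make_random_plasmid(ALW44I_LENGTH, alw44i_planted_sites(), seed)
    return DuplexSequence(seq.residues, CIRCULAR, name="alw44i_fixture")


# -- the Eco47I selection fixture -----------------------------------------
#
# Three GGWCC sites whose six terminal-C contexts cover {CA, CC, CT} and
# exclude CG, one of them T/A-flanked, plus one GTMKAC site flanked by A on
# both strands.  The T/A-flanked site is planted as GGACC (W = A) so that
# the internal CC of the motif remains methylatable on the bottom strand
# under flank-weighted CC profiles.

SELECTION_LENGTH = 5000


def selection_planted_sites() -> list[PlantedSite]:
    return [
        PlantedSite("GGWCC", "GGACC", 600, flank3_top="A", flank3_bottom="C",
                    junction="eco47i_1"),
        PlantedSite("GGWCC", "GGTCC", 1900, flank3_top="C", flank3_bottom="T",
                    junction="eco47i_2"),
        PlantedSite("GGWCC", "GGACC", 3600, flank3_top="T", flank3_bottom="A",
                    junction="eco47i_3"),
        PlantedSite("GTMKAC", "GTAGAC", 4500, flank3_top="A", flank3_bottom="A",
                    junction="xmii"),
    ]


def make_selection_fixture(seed: int = 0) -> DuplexSequence:
    seq = make_random_plasmid(SELECTION_LENGTH, selection_planted_sites(), seed)
    return DuplexSequence(seq.residues, CIRCULAR, name="selection_fixture")


# -- deletion variants -----------------------------------------------------

def make_deletion_variant(plasmid: DuplexSequence, start: int, length: int = 3,
                          site_motifs: Iterable[str] = DEFAULT_SCRUB) -> DuplexSequence:
    """Remove ``length`` bases starting at ``start`` (a one-codon deletion
    by default); rejected if the window overlaps any site of the given
    motifs or their immediate flanks."""
    L = len(plasmid)
    if length == 0:
        return plasmid
    if length < 0 or not 1 <= start <= L:
        raise ValueError("invalid deletion window")
    window = {(start - 1 + k) % L for k in range(length)}
    for motif in site_motifs:
        for site in scan_motif(plasmid, motif):
            foot = {(site.start - 2 + k) % L for k in range(len(site) + 2)}  # site + flanks
            if window & foot:
                raise ValueError(
                    f"deletion {start}..{start + length - 1} overlaps a {site.motif_id} site at {site.start}")
    if start - 1 + length <= L:
        residues = plasmid.residues[: start - 1] + plasmid.residues[start - 1 + length:]
    else:  # window wraps the origin
        tail = (start - 1 + length) % L
        residues = plasmid.residues[tail: start - 1]
    return DuplexSequence(residues, plasmid.topology, name=plasmid.name + f"_del{start}+{length}")


# -- oligonucleotide substrate panels -------------------------------------

def make_oligo_panel(kind: str, length: int = 23) -> list[tuple[DuplexSequence, MethylationState]]:
    """Shared-backbone 23-mer duplex panels.

    AXXA_core_panel: the four AXXA cassettes (CG hemimethylated on the
    bottom strand, CA, CC, CT).
    flank3_panel: TccX for X in A/C/G/T (preferred 5' T held fixed).
    flank5_panel: XccA for X in A/C/G/T (preferred 3' A held fixed).
    ANccCT_panel: ANCCCT cassettes, the ccC probe without a trailing ccA.
    """
    panels = {
        "AXXA_core_panel": lambda: [
            build_oligo_duplex("A", core, "A", length,
                               premeth=("bottom", "CG") if core == "CG" else None,
                               name=f"A{core.lower()}A")
            for core in ("CG", "CA", "CC", "CT")
        ],
        "flank3_panel": lambda: [
            build_oligo_duplex("T", "CC", x, length, name=f"Tcc{x}")
            for x in "ACGT"
        ],
        "flank5_panel": lambda: [
            build_oligo_duplex(x, "CC", "A", length, name=f"{x}ccA")
            for x in "ACGT"
        ],
        "ANccCT_panel": lambda: [
            build_oligo_duplex("A" + n, "CCCT", "", length, name=f"A{n}ccCT")
            for n in "ACGT"
        ],
    }
    if kind not in panels:
        raise ValueError(f"unknown panel kind {kind!r}; choose from {sorted(panels)}")
    return panels[kind]()
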