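"""Restriction-protection reasoning: predict band patterns under MTase
specificity hypotheses, test them against observed gel patterns, enumerate
the consistent hypotheses, and audit selection designs.

This is the interpretive engine of a restriction-protection assay: a
plasmid self-methylated in vivo is digested with methylation-sensitive
enzymes, and the fragment sizes that appear (or fail to appear) constrain
which target dinucleotides the expressed MTase methylates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

from .sequence import DuplexSequence, dinucleotide_context, scan_motif
from .methylation import CORE_DINUCLEOTIDES, MTaseSpecificity, apply_methylation
from .restriction import RestrictionEnzyme
from .digestion import UNCUT_CIRCULAR, FragmentSet, digest


@dataclass(frozen=True)
class ObservedPattern:
    """Band sizes read off a gel for one enzyme digest.

    ``full_length_linear`` flags the single full-length linear species
    (one cut); ``uncut`` flags surviving circles (zero cuts).
    """

    enzyme: str
    bands: tuple = ()
    full_length_linear: bool = False
    uncut: bool = False

    def __post_init__(self) -> None:
        bands = tuple(sorted((int(b) for b in self.bands), reverse=True))
        if any(b <= 0 for b in bands):
            raise ValueError("band sizes must be positive")
        object.__setattr__(self, "bands", bands)


@dataclass
class HypothesisSpace:
    """Candidate MTase specificities to test.

    The default space is the 15 non-empty subsets of {CG,CA,CC,CT} with
    flat flank weights, plus an inactive "none" baseline; flank-weighted
    profiles are added only explicitly, keeping the search exact and small.
    """

    candidates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.candidates]
        if len(names) != len(set(names)):
            raise ValueError("candidate names must be unique")

    @classmethod
    def default(cls, include_baseline: bool = True,
                extra: Iterable[MTaseSpecificity] = ()) -> "HypothesisSpace":
        cands = []
        if include_baseline:
            cands.append(MTaseSpecificity.inactive("none"))
        for k in range(1, 5):
            for combo in combinations(CORE_DINUCLEOTIDES, k):
                cands.append(MTaseSpecificity.simple(combo))
        cands.extend(extra)
        return cls(cands)


def predict_pattern(plasmid: DuplexSequence, spec: MTaseSpecificity,
                    enzyme: RestrictionEnzyme, threshold: float = 0.5) -> FragmentSet:
    """Deterministic methylation (threshold semantics) composed with a
    complete digest by one enzyme."""
    meth = apply_methylation(plasmid, spec, mode="deterministic", threshold=threshold)
    return digest(plasmid, meth, [enzyme])


def patterns_consistent(predicted: FragmentSet, observed: ObservedPattern,
                        rel_tol: float = 0.05,
                        seq_length: Optional[int] = None) -> tuple[bool, list]:
    """Compare a predicted fragment set with an observed band pattern.

    Bands are matched bijectively and greedily on size-sorted lists; each
    observed band must sit within ``rel_tol`` relative tolerance of its
    predicted partner (|obs - pred| <= rel_tol * pred).  The uncut and
    full-length-linear flags must agree: "uncut" matches only a zero-cut
    prediction, "full-length linear" matches any single-cut outcome.
    """
    if not 0.0 <= rel_tol <= 0.2:
        raise ValueError("rel_tol must be in [0, 0.2]")
    if observed.uncut:
        return predicted.status == UNCUT_CIRCULAR, []
    if predicted.status == UNCUT_CIRCULAR:
        return False, []
    if observed.full_length_linear:
        return len(predicted.fragments) == 1, []
    pred = list(predicted.fragments)  # already sorted descending
    obs = list(observed.bands)
    if len(pred) != len(obs):
        return False, [(o, None, False) for o in obs]
    matching = []
    ok = True
    for o, p in zip(obs, pred):  # greedy on sorted lists, ties toward larger predicted
        hit = abs(o - p) <= rel_tol * p
        ok = ok and hit
        matching.append((o, p, hit))
    return ok, matching


@dataclass(frozen=True)
class InferenceResult:
    consistent: tuple
    table: dict              # (hypothesis name, enzyme) -> (bool, detail)
    message: str


def infer_specificities(plasmid: DuplexSequence, observations: Iterable[ObservedPattern],
                        space: Optional[HypothesisSpace] = None,
                        enzymes: Optional[dict] = None,
                        rel_tol: float = 0.05,
                        threshold: float = 0.5) -> InferenceResult:
    """Exhaustively test every candidate specificity against every
    observation; return all candidates consistent with ALL observations,
    ranked by parsimony (fewest core dinucleotides, then name)."""
    observations = list(observations)
    if not observations:
        raise ValueError("at least one observation required")
    if space is None:
        space = HypothesisSpace.default()
    if enzymes is None:
        from .restriction import shipped_enzymes
        enzymes = shipped_enzymes()
    table = {}
    survivors = []
    for cand in space.candidates:
        all_ok = True
        for obs in observations:
            enz = enzymes[obs.enzyme] if isinstance(obs.enzyme, str) else obs.enzyme
            predicted = predict_pattern(plasmid, cand, enz, threshold=threshold)
            ok, matching = patterns_consistent(predicted, obs, rel_tol=rel_tol,
                                              seq_length=len(plasmid))
            table[(cand.name, enz.name)] = (ok, matching)
            all_ok = all_ok and ok
        if all_ok:
            survivors.append(cand)
    survivors.sort(key=lambda c: (len(c.core), c.name))
    if survivors and all(c.is_inactive for c in survivors):
        message = "no methylation detected"
    elif not survivors:
        message = "no candidate specificity is consistent with all observations"
    else:
        message = f"{len(survivors)} consistent specificities"
    return InferenceResult(tuple(survivors), table, message)


# -- selection-design auditing --------------------------------------------

def terminal_c_anchor(enzyme: RestrictionEnzyme) -> int:
    """Default context anchor: the 3'-most C of the motif reading."""
    for p in range(len(enzyme.motif), 0, -1):
        if enzyme.motif[p - 1] == "C":
            return p
    raise ValueError(f"motif {enzyme.motif} contains no concrete C")


def context_coverage(plasmid: DuplexSequence, enzyme: RestrictionEnzyme,
                     anchor: Optional[int] = None) -> Counter:
    """Multiset of dinucleotide contexts formed by the anchored C of every
    site, on both strands (2 contexts per palindromic site)."""
    if anchor is None:
        anchor = terminal_c_anchor(enzyme)
    contexts: Counter = Counter()
    for site in scan_motif(plasmid, enzyme.motif, motif_id=enzyme.name):
        for strand in ("top", "bottom"):
            contexts[dinucleotide_context(plasmid, site, anchor, strand)] += 1
    return contexts


def internal_protection_routes(enzyme: RestrictionEnzyme) -> list[str]:
    """Flank-independent protection routes: watched cytosines whose core
    dinucleotide lies entirely inside the motif with a concrete partner
    base (e.g. the inner C of GGWCC forms CC regardless of flanks)."""
    routes = []
    motif = enzyme.motif
    m = len(motif)
    for rule in enzyme.rules:
        for p, s in rule.positions:
            if s == "top":
                if motif[p - 1] == "C" and p < m and motif[p] in "ACGT":
                    dinuc = "C" + motif[p]
                    routes.append(f"internal {dinuc} at motif position {p} (top): "
                                  f"{dinuc}-specific methylation blocks independent of flanks")
            else:
                if motif[p - 1] == "G" and p > 1 and motif[p - 2] in "ACGT":
                    from .sequence import complement_base
                    dinuc = "C" + complement_base(motif[p - 2])
                    routes.append(f"internal {dinuc} at motif position {p} (bottom): "
                                  f"{dinuc}-specific methylation blocks independent of flanks")
    return routes


@dataclass(frozen=True)
class SuitabilityReport:
    suitable: bool
    contexts: Counter
    per_site: tuple          # (start, (context_top, context_bottom)) per site
    missing_desired: tuple
    forbidden_present: tuple
    secondary_routes: tuple


def selection_suitability(plasmid: DuplexSequence, enzyme: RestrictionEnzyme,
                          desired: Iterable[str], forbidden: Iterable[str],
                          anchor: Optional[int] = None) -> SuitabilityReport:
    """Is this enzyme/plasmid pair a valid selection for the desired
    methylation contexts?

    Suitable iff every desired context occurs at least once among the
    enzyme's anchored-C site contexts and no forbidden context occurs.
    The report also lists secondary (flank-independent) protection routes
    that can let undesired specificities survive the selection.
    """
    desired = {d.upper() for d in desired}
    forbidden = {f.upper() for f in forbidden}
    if desired & forbidden:
        raise ValueError("desired and forbidden context sets must be disjoint")
    if anchor is None:
        anchor = terminal_c_anchor(enzyme)
    per_site = []
    contexts: Counter = Counter()
    for site in scan_motif(plasmid, enzyme.motif, motif_id=enzyme.name):
        ctx = tuple(dinucleotide_context(plasmid, site, anchor, s) for s in ("top", "bottom"))
        per_site.append((site.start, ctx))
        contexts.update(ctx)
    missing = tuple(sorted(desired - set(contexts)))
    present_forbidden = tuple(sorted(forbidden & set(contexts)))
    suitable = not missing and not present_forbidden
    return SuitabilityReport(suitable, contexts, tuple(per_site), missing,
                             present_forbidden, tuple(internal_protection_routes(enzyme)))
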