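"""Directed-evolution loop: error-prone PCR libraries and restriction-based
selection.

The mutagenesis model emulates Mn2+/dITP-biased error-prone PCR: mutation
counts per gene are Poisson, mutated positions concentrate on A/T (the
epPCR hotspot bias) via per-base mutability weights, and substitutions
follow per-base bias rows applied strand-symmetrically (an A->G event on
the bottom strand is recorded as T->C on the top strand).  With the
default calibration (~2.5 mutations per gene, rows 90% transition from
A/T, A/T eightfold hotter than G/C) roughly 80% of substitutions are
A:T->G:C transitions on a gene of typical composition.

Selection is binary uncut-survival: each clone's plasmid is methylated per
its phenotype and digested with the selection enzyme; the clone survives
iff the plasmid remains an uncut circle.  Indels are excluded from the
mutagenesis model; codon deletions are constructed explicitly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .sequence import DuplexSequence, complement_base
from .methylation import MTaseSpecificity, apply_methylation, MethylationState
from .restriction import RestrictionEnzyme
from .digestion import UNCUT_CIRCULAR, digest

BASES = "ACGT"


def _default_bias() -> dict:
    # 90% transitions from A/T; purine/pyrimidine rows mirror each other
    return {
        "A": {"G": 0.9, "C": 0.05, "T": 0.05},
        "T": {"C": 0.9, "G": 0.05, "A": 0.05},
        "G": {"A": 1 / 3, "C": 1 / 3, "T": 1 / 3},
        "C": {"T": 1 / 3, "G": 1 / 3, "A": 1 / 3},
    }


@dataclass
class MutagenesisModel:
    """Poisson per-gene mutation rate with biased substitution spectrum."""

    mean_mutations_per_gene: float = 2.5
    substitution_bias: dict = field(default_factory=_default_bias)
    base_mutability: dict = field(default_factory=lambda: {"A": 8.0, "T": 8.0, "G": 1.0, "C": 1.0})

    def __post_init__(self) -> None:
        if self.mean_mutations_per_gene < 0:
            raise ValueError("mean mutation rate must be non-negative")
        for b, row in self.substitution_bias.items():
            if b in row:
                raise ValueError(f"self-substitution {b}->{b} not allowed")
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"bias row for {b} sums to {total}, expected 1")


def mutagenize_library(gene: str, model: MutagenesisModel, n: int, seed: int) -> list[str]:
    """Generate ``n`` mutant sequences of ``gene``.

    Per clone the mutation count is Poisson(mean); positions are drawn
    without replacement with probability proportional to the mutability of
    their base; each substitution follows the bias row of the mutated
    strand, chosen by a fair coin, and is recorded in top-strand letters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    gene = gene.upper()
    if set(gene) - set(BASES):
        raise ValueError("gene must be a concrete A/C/G/T string")
    rng = np.random.default_rng(seed)
    L = len(gene)
    weights = np.array([model.base_mutability[b] for b in gene], dtype=float)
    weights /= weights.sum()
    rows = {
        b: (list(row.keys()), np.array(list(row.values())))
        for b, row in model.substitution_bias.items()
    }
    library = []
    for _ in range(n):
        k = rng.poisson(model.mean_mutations_per_gene)
        if k == 0:
            library.append(gene)
            continue
        k = min(k, L)
        positions = rng.choice(L, size=k, replace=False, p=weights)
        clone = list(gene)
        for i in positions:
            ref_top = gene[i]
            on_bottom = rng.random() < 0.5
            ref = complement_base(ref_top) if on_bottom else ref_top
            targets, probs = rows[ref]
            new = targets[int(rng.choice(len(targets), p=probs))]
            clone[i] = complement_base(new) if on_bottom else new
        library.append("".join(clone))
    return library


def estimate_mutation_stats(library: Sequence[str], reference: str) -> tuple[float, Counter]:
    """Mean Hamming distance per clone and the (ref->obs) substitution
    spectrum, tabulated in top-strand letters."""
    reference = reference.upper()
    spectrum: Counter = Counter()
    total = 0
    for clone in library:
        if len(clone) != len(reference):
            raise ValueError("clone length differs from reference (indels are out of scope)")
        for r, o in zip(reference, clone.upper()):
            if r != o:
                spectrum[(r, o)] += 1
                total += 1
    mean = total / len(library) if library else 0.0
    return mean, spectrum


def transition_fraction(spectrum: Counter) -> float:
    """Fraction of substitutions that are A->G or T->C (strand-symmetric
    A:T->G:C transitions)."""
    total = sum(spectrum.values())
    if total == 0:
        return 0.0
    return (spectrum[("A", "G")] + spectrum[("T", "C")]) / total


# -- selection -------------------------------------------------------------

@dataclass
class SelectionRound:
    selection_enzyme: RestrictionEnzyme
    survival_rule: str = "survive_if_uncut"
    library_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.survival_rule != "survive_if_uncut":
            raise ValueError(f"unknown survival rule {self.survival_rule!r}")
        if self.library_size is not None and self.library_size < 1:
            raise ValueError("library_size must be >= 1")


@dataclass(frozen=True)
class SelectionResult:
    survivors: tuple                 # surviving genotypes, input order preserved
    input_counts: dict               # phenotype class -> clones in
    survivor_counts: dict            # phenotype class -> clones out
    enrichment: dict                 # phenotype class -> survivor freq / input freq


def simulate_selection(library: Sequence[str],
                       phenotype_map: Callable[[str], Optional[MTaseSpecificity]],
                       plasmid: DuplexSequence, round_: SelectionRound,
                       seed: int = 0, threshold: float = 0.5) -> SelectionResult:
    """Single round of uncut-survival selection.

    Each clone's plasmid is self-methylated per its phenotype
    (deterministic threshold mode) and digested with the selection enzyme;
    clones whose plasmid remains an uncut circle survive.  Unknown
    genotypes map to the inactive phenotype.
    """
    enzyme = round_.selection_enzyme
    input_counts: Counter = Counter()
    survivor_counts: Counter = Counter()
    survivors = []
    survival_cache: dict[str, bool] = {}
    for genotype in library:
        spec = phenotype_map(genotype)
        if spec is None:
            spec = MTaseSpecificity.inactive()
        label = spec.name
        input_counts[label] += 1
        if label not in survival_cache:
            meth = apply_methylation(plasmid, spec, mode="deterministic", threshold=threshold)
            survival_cache[label] = digest(plasmid, meth, [enzyme]).status == UNCUT_CIRCULAR
        if survival_cache[label]:
            survivor_counts[label] += 1
            survivors.append(genotype)
    n_in = len(library)
    n_out = len(survivors)
    enrichment = {}
    for label, cin in input_counts.items():
        fin = cin / n_in
        fout = (survivor_counts[label] / n_out) if n_out else 0.0
        enrichment[label] = fout / fin
    return SelectionResult(tuple(survivors), dict(input_counts),
                           dict(survivor_counts), enrichment)
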