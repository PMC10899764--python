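# mtasekit

Toolkit for interpreting **restriction-protection assays** of DNA
(cytosine-5) methyltransferases (MTases), and for designing and simulating
restriction-based selections of altered-specificity MTase mutants.

When an MTase is expressed in *E. coli*, the plasmid encoding it is
self-methylated wherever the enzyme's sequence specificity dictates.
Digesting that plasmid with restriction enzymes whose cleavage is blocked
by 5-methylcytosine (5mC) in defined positions turns the methylation
pattern into a gel band pattern: a protected site fuses two
complete-digest fragments into one new, larger band.  `mtasekit` models
this chain quantitatively:

- **Duplex sequences and IUPAC motif scanning** on both strands with
  circular wraparound, palindrome-aware, with per-strand flanking-base
  annotation (`mtasekit.sequence`).
- **MTase specificity hypotheses**: a set of core target dinucleotides
  (CG/CA/CC/CT, the methylated base is the 5′ C) plus multiplicative
  flanking-preference weights, applied strand-independently either
  deterministically (weight ≥ threshold) or stochastically
  (`mtasekit.methylation`).
- **Methylation-sensitive restriction enzymes** with explicit blocking
  rules — which cytosines of the recognition duplex are watched, and
  whether one or both strands must carry 5mC.  Nine assay enzymes ship
  with the package (Alw44I, XmiI, BsuRI, Bsh1236I, Hin6I, Eco47I, MspI,
  BamHI, NcoI) (`mtasekit.restriction`).
- **Complete and population digestion** into exact fragment multisets or
  band-intensity profiles under partial in vivo methylation
  (`mtasekit.digestion`).
- **Protection inference**: predict band patterns under every candidate
  specificity, compare with observed bands at a gel-reading tolerance,
  and return the parsimony-ranked consistent hypotheses; audit whether an
  enzyme/plasmid pair can select for a desired set of methylation
  contexts (`mtasekit.inference`).
- **Directed-evolution simulation**: Poisson error-prone PCR libraries
  with an A:T→G:C-biased substitution spectrum, and single rounds of
  uncut-survival selection with per-phenotype enrichment factors
  (`mtasekit.evolution`).
- **Michaelis–Menten kinetics** of methyl transfer: v = k_cat·E·S/(K_M+S),
  closed-form time courses with ³H-label accounting (Bq ↔ pmol), nonlinear
  least-squares fitting, and catalytic-efficiency (k_cat/K_M) comparisons
  (`mtasekit.kinetics`).
- **Synthetic fixtures** (`mtasekit.synthetic`): the assay plasmids are
  not publicly deposited, so seeded generators build circular plasmids
  with recognition sites planted at positions and flanking contexts that
  reproduce the published fragment arithmetic, plus the 23-mer oligo
  substrate panels.

## Worked example

The protection fixture is a circular 6421 bp plasmid with three Alw44I
(`GTGCAC`) sites.  A complete digest of the unmethylated plasmid gives
1935 + 3986 + 500 bp.  Alw44I does not cut when the 3′ cytosine of its
site is methylated on either strand, and the three sites' 3′-flanking
bases (A/G, C/C, C/T per strand) make the digest a readout of all four CN
dinucleotide specificities:

```python
import mtasekit as mk

plasmid = mk.make_alw44i_fixture(seed=0)
alw44i = mk.shipped_enzymes()["Alw44I"]

for cores in ({"CG"}, {"CA"}, {"CC"}, {"CT"}):
    spec = mk.MTaseSpecificity.simple(cores)
    fs = mk.predict_pattern(plasmid, spec, alw44i)
    print(sorted(cores), fs.fragments)
```

prints

```
['CG'] (4486, 1935)
['CA'] (4486, 1935)
['CC'] (6421,)
['CT'] (3986, 2435)
```

CG-specific methylation protects the A/G-flanked site and fuses
3986 + 500 into a 4486 bp band — but CA methylation predicts the same
pattern, which is exactly the ambiguity a single digest leaves.  The
inference engine makes this explicit:

```python
obs = [mk.ObservedPattern("Alw44I", (4486, 1935))]
result = mk.infer_specificities(plasmid, obs)
print([c.name for c in result.consistent][:2])   # ['CA', 'CG']
```

Resolving it takes a second observation, e.g. an XmiI (`GTMKAC`) site
flanked by A on both strands that is still cut: that eliminates CA and
leaves CG.

The same machinery runs from the shell:

```
mtasekit fixtures --out-dir fixtures --seed 0
mtasekit digest --plasmid fixtures/alw44i_fixture.gb --enzymes Alw44I --mtase CG
```

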