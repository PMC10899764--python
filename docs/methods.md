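# Methods

## The model

`mtasekit` treats a plasmid as a duplex of a concrete top strand and its
Watson–Crick complement, with circular or linear topology.  Three layers
sit on top of it:

1. **Methylation.**  An MTase specificity is a set of core dinucleotides
   drawn from {CG, CA, CC, CT}; the methylated base is always the 5′ C of
   the dinucleotide.  Every cytosine on either strand whose 3′ neighbor
   completes a core dinucleotide is an eligible target.  Each target
   carries a weight `flank5_weight[b5] × flank3_weight[b3]`, where `b5` is
   the base 5′ of the C and `b3` the base 3′ of the dinucleotide, both read
   on the same strand.  The two strands are methylated independently —
   there is no maintenance-methylation coupling, so a hemimethylated site
   does not change the other strand's eligibility.  Deterministic mode
   marks every target with weight ≥ threshold (default 0.5); stochastic
   mode marks each target with probability `efficiency × weight`.

2. **Blocking.**  A restriction enzyme is an IUPAC motif, a cut offset and
   a list of sensitivity rules.  A rule watches specific cytosines of the
   recognition duplex — (motif position, strand) pairs — and fires either
   when any watched cytosine is 5mC (`any`) or only when all of them are
   (`both`; the shipped `both` rules watch the two strand-mates of one
   duplex cytosine, i.e. "methylated on both strands").  A site is blocked
   if any rule fires.  Deliberately, *only* the watched cytosines matter:
   5mC elsewhere inside a recognition site does not block.  This is the
   interpretive model applied to protection gels; real enzymes may have
   additional sensitivities, and the rule format permits adding them.

3. **Digestion.**  A complete digest cuts at every unblocked site.
   Fragment lengths are successive cut-coordinate differences (with
   wraparound on circles) and are exact; a circular molecule with zero
   cuts is reported as `uncut_circular`, with one cut as a single
   full-length linear fragment.  Partial bands are modeled exclusively as
   molecule-to-molecule methylation heterogeneity: population mode draws
   independent stochastic methylation states, digests each molecule, and
   aggregates DNA-mass fractions (fragment length / plasmid length), so
   band masses plus uncut mass sum to 1.  Enzyme failure is never
   simulated.

## Inference

Protection inference is exhaustive hypothesis elimination.  The default
hypothesis space is the 15 non-empty subsets of {CG, CA, CC, CT} with flat
flank weights plus an inactive baseline ("none"); flank-weighted profiles
are added only explicitly so the search stays exact.  For each candidate
and each observed digest, the predicted fragment set (deterministic
methylation + complete digest) is compared with the observed bands:
size-sorted lists matched bijectively and greedily, each observed band
within a relative tolerance of its predicted partner (default 5%,
reflecting agarose-gel size resolution; tests use 0).  An observed
"uncut" matches only a zero-cut prediction and "full-length linear" any
single-cut outcome.  Candidates consistent with *all* observations are
returned ranked by parsimony (fewest core dinucleotides, then name) —
the reading that prefers CG over CA when both explain a band.  Which
faint bands count as present on a real gel is a judgment call, so the
tolerance is a parameter, not a constant.

Selection-design auditing computes, for each site of an enzyme, the
dinucleotide context of an anchored cytosine (by default the 3′-most C of
the motif) on both strands.  A selection is suitable for a desired set of
contexts iff each desired context occurs at least once and no forbidden
context occurs.  The report also flags flank-independent ("secondary")
protection routes: watched cytosines whose core dinucleotide is completed
*inside* the motif — e.g. the inner C of GGWCC always sits in a CC
dinucleotide, so CC-specific methylation protects every GGWCC site
regardless of its flanks.  A selection can therefore be passed through a
route other than the contexts it was designed around, and the audit makes
that visible.

## Synthetic fixtures

The real assay plasmids are not publicly available, so the generators
build stand-ins that reproduce the published arithmetic exactly; they are
first-class, tested code, and every generated plasmid passes a
generator→analyzer round-trip (planted sites found, planted flanks
recovered, digest sizes as specified).  Backgrounds are seeded random
A/C/G/T scrubbed of accidental matches to the planted motifs (and of
GTGCAC/GTMKAC/GGWCC generally) by local resampling; fixtures are
byte-identical for a fixed seed.

**Protection fixture** (circular, 6421 bp): three GTGCAC sites placed so
the complete digest yields 1935/3986/500, with per-strand 3′-flank
contexts {A,G} at the 3986|500 junction, {C,C} at 1935|3986 and {C,T} at
500|1935.  The {C,C} assignment is forced: a G there would let CG
methylation protect two sites, an A would give CA methylation an extra
protected fragment, and a T would let CT methylation produce a 5921 bp
band — each contradicting one of the published protection statements
(CG/CA protect only the A/G site → 4486; CC can produce 5921/2435/6421;
CT produces only 2435; all four CN contexts represented).  The fixture
uses its own coordinates and does not claim the original plasmid's
absolute positions.

**Selection fixture** (circular, 5000 bp): three GGWCC sites whose six
terminal-C contexts cover {CA, CC, CT} and exclude CG — one site
T/A-flanked — plus one GTMKAC site flanked by A on both strands.  The
T/A-flanked site is planted as GGACC (W = A): with W = A the internal CC
of the motif reads T·CC·A on the bottom strand, which clears the
deterministic threshold under the shipped flank-weighted CC profile, so
the published internal-CC protection route is reproducible; with W = T it
would not be.

**Oligo panels**: 23-mer linear duplexes with a variable cassette centered
in a constant all-A/T backbone, so the cassette contains the only
methylatable cytosines on either strand.  The CG member of the core panel
carries one pre-placed 5mC on the bottom strand, emulating the
hemimethylated control used because asymmetric CA/CC/CT sites accept only
one methyl group per duplex.  Real substrate oligos have mixed-base
backbones; the all-A/T choice trades that realism for exact
single-target accounting in tests.

## Mutagenesis and selection

Error-prone PCR is modeled at the library level: per clone a
Poisson(mean) mutation count (default 2.5 per gene), mutated positions
drawn without replacement with probability proportional to a per-base
mutability (default A = T = 8, G = C = 1, the Mn²⁺/dITP A/T-hotspot
bias), and substitutions drawn from per-base bias rows (default 90%
transition from A/T) applied to a uniformly chosen strand and recorded in
top-strand letters (a bottom-strand A→G is a top-strand T→C).  On a gene
of roughly equal base composition this yields ≈80% A:T→G:C transitions.
Indels are excluded; codon deletions are constructed explicitly with
`make_deletion_variant`.  The estimator is the plain per-clone Hamming
mean plus a (ref→obs) substitution table, so parameter recovery is a
direct Poisson/multinomial check.

Selection is binary uncut-survival: each clone's plasmid is methylated
per the clone's phenotype (a user-supplied genotype→specificity map;
unknown genotypes are inactive) and digested with the selection enzyme;
survivors are clones whose plasmid stays an uncut circle.  Enrichment per
phenotype class is survivor frequency over input frequency.
Transformation efficiency, re-ligation and multi-round kinetics are out
of scope; rounds compose.

## Kinetics

Methyl transfer follows v = k_cat·E·S/(K_M + S) with SAM assumed
saturating.  Units are fixed: nM, min, μl, Bq, pmol.  Time courses use
the integrated rate law k_cat·E·t = P + K_M·ln(S0/(S0 − P)), solved per
time point by Brent's method; the product ceiling is S0 (one methyl group
per duplex, matching single-site substrates).  Label accounting is the
exact, invertible conversion pmol = nM × μl / 1000 times the specific
activity (default 130 Bq/pmol; 30 μl aliquots).  Fitting is unweighted
nonlinear least squares (`scipy.optimize.curve_fit`) initialized from a
double-reciprocal linear fit, with standard errors from the covariance
matrix and explicit convergence reporting; initial velocities default to
the earliest positive time point when rates are not supplied directly.
Baseline correction and weighting schemes are not applied.  Reference
parameter sets used throughout the tests: wild-type-like
K_M = 220 nM, k_cat = 0.65 min⁻¹ at E = 5 nM; evolved-mutant-like
K_M = 1450 nM, k_cat = 0.009 min⁻¹ at E = 350 nM; their k_cat/K_M ratio
is ≈476.

## Numerical and design choices

- Coordinates are 1-based, inclusive, top-strand; circular arithmetic is
  modular.  Palindromic motifs are one locus with two per-strand context
  annotations.  Fragment multisets are origin-independent.
- Deterministic threshold 0.5 separates "preferred" from "very poor"
  flanks under the shipped `quadruple_mutant_CC` profile (flank3
  A = 1.0, C = 0.6, G = T = 0.05; flank5 G = C = T = 1.0, A = 0.4).  The
  profile encodes a qualitative activity ordering reported graphically —
  the numbers are tunable configuration, not measured constants.
- Coincident cuts count once; band matching breaks ties toward the larger
  predicted fragment; a flank beyond a linear end contributes a neutral
  weight factor of 1.
- Host (Dcm) methylation of CCWGG sites is not layered on by default; the
  enzyme-rule format allows adding it.

## Problem sizes and what the tests show

Property tests run on random sequences up to ~500 bp (scan and digest
against brute-force oracles), population mode on 10⁴ molecules against an
exact binomial, mutagenesis recovery on 1000 clones × 1185 nt with a
3-standard-error acceptance band (±0.15 around 2.5), and inference
soundness across all 15 dinucleotide hypotheses on the generated
fixtures.  Because the fixtures plant exactly the published site layouts
on otherwise scrubbed backgrounds, passing tests demonstrate the engine's
arithmetic and logic on those layouts — not performance on real plasmids,
whose backgrounds contain many more overlapping sites and whose gel
readouts carry judgment calls that are only parameterized here.
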