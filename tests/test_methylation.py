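"""MTase specificity hypotheses and 5mC mark application."""

import pytest
from hypothesis import given, settings, strategies as st

from mtasekit.methylation import (MethylationState, MTaseSpecificity,
                                  QUADRUPLE_MUTANT_CC, apply_methylation,
                                  build_oligo_duplex, list_target_sites)
from mtasekit.sequence import CIRCULAR, LINEAR, DuplexSequence

dna = st.text(alphabet="ACGT", min_size=4, max_size=120)


def oracle_dinucleotide_scan(seq: DuplexSequence, cores: set) -> set:
    """Brute-force enumeration of (strand, position) for every core C."""
    out = set()
    L = len(seq)
    for pos in range(1, L + 1):
        t, nxt = seq.top_base(pos), seq.top_base(pos + 1)
        if t == "C" and nxt is not None and "C" + nxt in cores:
            out.add(("top", pos))
        b, bnxt = seq.bottom_base(pos), seq.bottom_base(pos - 1)
        if b == "C" and bnxt is not None and "C" + bnxt in cores:
            out.add(("bottom", pos))
    return out


class TestSpecificity:
    def test_rejects_foreign_dinucleotide(self):
        with pytest.raises(ValueError):
            MTaseSpecificity.simple({"GG"})

    def test_rejects_out_of_range_weight(self):
        with pytest.raises(ValueError):
            MTaseSpecificity("bad", frozenset({"CG"}), flank3_weights={"A": 1.5})


class TestListTargetSites:
    def test_palindromic_cg_listed_on_both_strands(self):
        seq = DuplexSequence("ACGA", LINEAR)
        sites = list_target_sites(seq, MTaseSpecificity.simple({"CG"}))
        assert {(s.strand, s.position) for s in sites} == {("top", 2), ("bottom", 3)}

    def test_inner_c_of_eco47i_site_is_a_cc_target(self):
        seq = DuplexSequence("TTGGACCTTT", CIRCULAR)
        sites = list_target_sites(seq, MTaseSpecificity.simple({"CC"}))
        # GGACC spans 3..7; the inner C (motif position 4) sits at 6
        assert ("top", 6) in {(s.strand, s.position) for s in sites}

    def test_internal_ca_of_alw44i_site_on_both_strands(self):
        # dinucleotides of GTGCAC: GT,TG,GC,CA,AC -> one CA per strand
        seq = DuplexSequence("TTGTGCACTT", CIRCULAR)
        sites = list_target_sites(seq, MTaseSpecificity.simple({"CA"}))
        ca = {(s.strand, s.position) for s in sites if s.core == "CA"}
        assert ("top", 6) in ca            # the C of CA at motif position 4
        assert len([s for s in sites if s.strand == "bottom"]) >= 1

    @given(s=dna, cores=st.sets(st.sampled_from(["CG", "CA", "CC", "CT"]), min_size=1))
    @settings(derandomize=True, max_examples=60)
    def test_flat_weights_equal_brute_force_scan(self, s, cores):
        seq = DuplexSequence(s, CIRCULAR)
        sites = list_target_sites(seq, MTaseSpecificity.simple(cores))
        assert {(x.strand, x.position) for x in sites} == oracle_dinucleotide_scan(seq, cores)

    @given(s=dna)
    @settings(derandomize=True, max_examples=40)
    def test_cg_marks_are_strand_symmetric(self, s):
        seq = DuplexSequence(s, CIRCULAR)
        meth = apply_methylation(seq, MTaseSpecificity.simple({"CG"}))
        tops = {p for st_, p in meth.marks if st_ == "top"}
        bottoms = {p for st_, p in meth.marks if st_ == "bottom"}
        # each top CG mark pairs with a bottom mark one base 3' (the G)
        assert bottoms == {(p % len(seq)) + 1 for p in tops}


class TestApplyMethylation:
    def test_deterministic_cg_marks_every_cg_twice(self):
        seq = DuplexSequence("ACGATTTACGTT", CIRCULAR)
        meth = apply_methylation(seq, MTaseSpecificity.simple({"CG"}))
        n_loci = seq.residues.count("CG")
        assert len(meth) == 2 * n_loci

    def test_poor_flank_not_marked_under_mutant_profile(self):
        # CC followed by G is a very poor substrate
        seq = DuplexSequence("TTTCCGTTTT", CIRCULAR)
        meth = apply_methylation(seq, QUADRUPLE_MUTANT_CC)
        assert ("top", 4) not in meth.marks

    def test_stochastic_zero_efficiency_is_empty(self):
        seq = DuplexSequence("ACGACGACGA", CIRCULAR)
        spec = MTaseSpecificity.simple({"CG"}, efficiency=0.0)
        meth = apply_methylation(seq, spec, mode="stochastic", seed=1)
        assert len(meth) == 0

    def test_threshold_out_of_range_rejected(self):
        seq = DuplexSequence("ACGA", LINEAR)
        with pytest.raises(ValueError):
            apply_methylation(seq, MTaseSpecificity.simple({"CG"}), threshold=1.5)

    def test_stochastic_requires_seed(self):
        seq = DuplexSequence("ACGA", LINEAR)
        with pytest.raises(ValueError):
            apply_methylation(seq, MTaseSpecificity.simple({"CG"}), mode="stochastic")

    @given(s=dna, base=st.sampled_from("ACGT"),
           w=st.floats(min_value=0, max_value=1), delta=st.floats(min_value=0, max_value=1))
    @settings(derandomize=True, max_examples=40)
    def test_raising_a_flank_weight_never_removes_marks(self, s, base, w, delta):
        seq = DuplexSequence(s, CIRCULAR)
        lo = MTaseSpecificity("lo", frozenset({"CC"}), flank3_weights={base: w})
        hi = MTaseSpecificity("hi", frozenset({"CC"}), flank3_weights={base: min(1.0, w + delta)})
        marks_lo = apply_methylation(seq, lo).marks
        marks_hi = apply_methylation(seq, hi).marks
        assert marks_lo <= marks_hi


class TestMethylationState:
    def test_mark_must_sit_on_cytosine(self):
        seq = DuplexSequence("ACGT", LINEAR)
        MethylationState(frozenset({("top", 2)})).validate(seq)
        with pytest.raises(ValueError, match="not C"):
            MethylationState(frozenset({("top", 1)})).validate(seq)
        # bottom-strand C pairs with a top-strand G
        MethylationState(frozenset({("bottom", 3)})).validate(seq)


class TestOligoDuplex:
    def test_axxa_cassettes_differ_only_in_cassette(self):
        oligos = [build_oligo_duplex("A", core, "A")[0] for core in ("CG", "CA", "CC", "CT")]
        assert all(len(o) == 23 for o in oligos)
        assert len({o.residues for o in oligos}) == 4
        backbones = {o.residues[:9] + o.residues[13:] for o in oligos}
        assert len(backbones) == 1

    def test_hemimethylated_cg_control_has_single_bottom_mark(self):
        seq, state = build_oligo_duplex("A", "CG", "A", premeth=("bottom", "CG"))
        assert len(state) == 1
        (strand, pos), = state.marks
        assert strand == "bottom"
        state.validate(seq)
        # the top-strand target C remains unmarked
        assert not any(s == "top" for s, _ in state.marks)

    def test_backbone_carries_no_targets(self):
        seq, _ = build_oligo_duplex("A", "CC", "A")
        sites = list_target_sites(seq, MTaseSpecificity.simple({"CG", "CA", "CC", "CT"}))
        cassette_span = range(10, 15)
        assert all(s.position in cassette_span for s in sites)

    def test_16_member_flank_enumeration_is_distinct(self):
        panel = {build_oligo_duplex(f5, "CC", f3)[0].residues
                 for f5 in "ACGT" for f3 in "ACGT"}
        assert len(panel) == 16

    def test_too_short_backbone_rejected(self):
        with pytest.raises(ValueError):
            build_oligo_duplex("A", "CC", "A", length=5)
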