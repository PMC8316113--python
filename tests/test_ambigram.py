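"""Genome-level analytics: reverse-stop codons, six-frame ORF scanning,
overlap fraction, codon avoidance, mutation design, ends characterization."""

import numpy as np
import pytest

from ambiribo.ambigram import (
    HANDLE,
    STOP_CODONS,
    MutationPlan,
    Segment,
    ambigram_overlap_fraction,
    characterize_ends,
    codon_avoidance_stats,
    design_opposing_mutations,
    revcomp,
    reverse_stop_codons,
    scan_orfs_both_strands,
    translate,
)
from ambiribo.synthetic import ALLOWED_CODONS, make_ambigram_genome


class TestReverseStopCodons:
    def test_exactly_the_three_known_codons(self):
        assert reverse_stop_codons() == {"TTA", "CTA", "TCA"}

    def test_reverse_complements_are_stops(self):
        for codon in reverse_stop_codons():
            assert revcomp(codon) in STOP_CODONS

    def test_exhaustive_codon_scan_finds_no_others(self):
        # independent brute force over all 64 codons
        found = {
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if revcomp(a + b + c) in STOP_CODONS
        }
        assert found == reverse_stop_codons()

    def test_disjoint_from_forward_stops(self):
        assert reverse_stop_codons() & STOP_CODONS == set()


def brute_force_orfs(seq, min_len):
    """Independent six-frame oracle: translate each frame, take the run
    from the FIRST Met of each stop-free stretch to the stretch end, then
    project reverse-strand coordinates onto the forward sequence."""
    out = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            prot = translate(s[frame:])
            k = 0
            while k < len(prot):
                if prot[k] == "*":
                    k += 1
                    continue
                j = k  # stop-free stretch [k, j)
                while j < len(prot) and prot[j] != "*":
                    j += 1
                ms = [i for i in range(k, j) if prot[i] == "M"]
                if ms:
                    st, en = frame + 3 * ms[0], frame + 3 * j
                    if en - st >= min_len:
                        if strand == "-":
                            st, en = L - en, L - st
                        out.add((strand, frame, st, en))
                k = j
    return out


class TestScanOrfs:
    def test_agrees_with_six_frame_oracle_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            got = {
                (o.strand, o.frame, o.start, o.end)
                for o in scan_orfs_both_strands(seq, min_len=30)
                if o.has_start
            }
            assert got == brute_force_orfs(seq, 30)

    def test_dual_strand_orfs_span_generated_ambigram(self, rdrp_segment):
        orfs = scan_orfs_both_strands(rdrp_segment.sequence, min_len=600)
        fwd = [o for o in orfs if o.strand == "+" and o.has_start]
        rev = [o for o in orfs if o.strand == "-" and o.has_start]
        assert max(o.length for o in fwd) > 0.95 * len(rdrp_segment)
        assert max(o.length for o in rev) > 0.95 * len(rdrp_segment)

    def test_tta_truncates_reverse_orf(self):
        rng = np.random.default_rng(3)
        codons = list(rng.choice(ALLOWED_CODONS, size=40))
        codons[0] = "ATG"
        codons[-1] = "CAT"
        clean = "".join(codons)
        broken = "".join(codons[:20] + ["TTA"] + codons[21:])
        rev_clean = max(
            (o for o in scan_orfs_both_strands(clean, 30) if o.strand == "-"),
            key=lambda o: o.length,
        )
        rev_broken = max(
            (o for o in scan_orfs_both_strands(broken, 30) if o.strand == "-"),
            key=lambda o: o.length,
        )
        assert rev_broken.length < rev_clean.length

    def test_all_stop_sequence_yields_no_started_orf(self):
        # frames 1/2 contain stop-free (AAT)n runs but no ATG anywhere, so
        # nothing qualifies as an ORF (flagged no-start stretches only)
        assert not [
            o for o in scan_orfs_both_strands("TAATAATAA", min_len=3) if o.has_start
        ]

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError):
            scan_orfs_both_strands("AT", 3)


class TestOverlapFraction:
    def _segment(self, L, fwd, rev_proj):
        # build a Segment with given forward interval and reverse interval
        # expressed by its forward projection
        rs, re = L - rev_proj[1], L - rev_proj[0]
        frame = (L - fwd[1]) % 3
        return Segment(
            "s", "A" * L, fwd_orf=(*fwd, 0), rev_orf=(rs, re, frame)
        )

    def test_example_arithmetic(self):
        # fwd [0,3000), rev projects to [60,3060), length 3171
        L = 3171
        rs, re = L - 3060, L - 60
        seg = Segment("s", "A" * L, fwd_orf=(0, 3000, 0), rev_orf=(rs, re, (L - 3000) % 3))
        assert ambigram_overlap_fraction(seg) == pytest.approx(2940 / 3171)

    def test_identical_full_length_projection_is_one(self):
        L = 300
        seg = Segment("s", "A" * L, fwd_orf=(0, L, 0), rev_orf=(0, L, 0))
        assert ambigram_overlap_fraction(seg) == 1.0

    def test_disjoint_orfs_give_zero(self):
        L = 300
        # rev ORF projects to [150,300) -> rev coords [0,150)
        seg = Segment("s", "A" * L, fwd_orf=(0, 150, 0), rev_orf=(0, 150, 0))
        assert ambigram_overlap_fraction(seg) == 0.0

    def test_missing_orf_raises(self):
        seg = Segment("s", "A" * 30, fwd_orf=(0, 30, 0))
        with pytest.raises(ValueError):
            ambigram_overlap_fraction(seg)

    def test_invariant_under_revcomp_with_roles_swapped(self, rdrp_segment):
        seg = rdrp_segment
        L = len(seg)
        flipped = Segment(
            "flip",
            revcomp(seg.sequence),
            fwd_orf=(seg.rev_orf[0], seg.rev_orf[1], seg.rev_orf[2]),
            rev_orf=(seg.fwd_orf[0], seg.fwd_orf[1], (L - seg.rev_orf[1]) % 3),
        )
        assert ambigram_overlap_fraction(flipped) == pytest.approx(
            ambigram_overlap_fraction(seg)
        )


class TestCodonAvoidance:
    def test_generated_genome_has_zero_counts(self, rdrp_segment):
        assert codon_avoidance_stats(rdrp_segment) == {"CTA": 0, "TCA": 0, "TTA": 0}

    def test_explicit_counts(self):
        seg = Segment("s", "TTACTATCA", fwd_orf=(0, 9, 0))
        assert codon_avoidance_stats(seg) == {"CTA": 1, "TCA": 1, "TTA": 1}

    def test_random_sequence_counts_match_multinomial_expectation(self):
        rng = np.random.default_rng(7)
        n_codons = 30000
        seq = "".join(rng.choice(list("ACGT"), size=3 * n_codons))
        seg = Segment("s", seq, fwd_orf=(0, 3 * n_codons, 0))
        counts = codon_avoidance_stats(seg)
        # uniform base composition: each codon expected n/64
        expected = n_codons / 64
        for c, n in counts.items():
            assert abs(n - expected) < 5 * np.sqrt(expected)


class TestMutationDesign:
    @pytest.mark.parametrize("n_codons", [1, 7])
    def test_stop_reverse_oracle(self, n_codons):
        # independent check over freshly generated genomes
        for seed in range(10):
            seg = make_ambigram_genome(3200, seed=seed)
            plan = design_opposing_mutations(seg, "stop_reverse", n_codons)
            mutant = plan.apply(seg.sequence)
            fs, fe, _ = seg.fwd_orf
            assert translate(mutant[fs:fe]) == translate(seg.sequence[fs:fe])
            rs, re, _ = seg.rev_orf
            before = translate(revcomp(seg.sequence)[rs:re])
            after = translate(revcomp(mutant)[rs:re])
            assert after.count("*") - before.count("*") == n_codons

    def test_nonsyn_reverse_same_positions_no_stops(self):
        for seed in range(5):
            seg = make_ambigram_genome(3200, seed=seed)
            st = design_opposing_mutations(seg, "stop_reverse", 7)
            ns = design_opposing_mutations(seg, "nonsyn_reverse", 7)
            assert [s[0] for s in st.sites] == [s[0] for s in ns.sites]
            mutant = ns.apply(seg.sequence)
            rs, re, _ = seg.rev_orf
            before = translate(revcomp(seg.sequence)[rs:re])
            after = translate(revcomp(mutant)[rs:re])
            assert after.count("*") == before.count("*")
            assert sum(a != b for a, b in zip(before, after)) == 7

    def test_stop_forward_begins_at_codon_14_and_preserves_reverse(self):
        for seed in range(5):
            seg = make_ambigram_genome(3200, seed=seed)
            plan = design_opposing_mutations(seg, "stop_forward", 1)
            fs, fe, _ = seg.fwd_orf
            assert (plan.sites[0][0] - fs) // 3 == 14
            mutant = plan.apply(seg.sequence)
            rs, re, _ = seg.rev_orf
            assert translate(revcomp(mutant)[rs:re]) == translate(
                revcomp(seg.sequence)[rs:re]
            )
            assert translate(mutant[fs:fe]).count("*") == 1

    def test_eligible_donor_set_matches_codon_table_scan(self):
        # every Leu/Ser donor admitting a same-position stop substitution
        donors = {"CTT", "CTC", "CTG", "TCT", "TCC", "TCG"}
        rng = np.random.default_rng(11)
        codons = list(rng.choice(sorted(set(ALLOWED_CODONS) - donors), size=60))
        codons[0] = "ATG"
        codons[30] = "CTT"
        codons[-1] = "CAT"
        seq = "".join(codons)
        L = len(seq)
        seg = Segment("s", seq, fwd_orf=(0, L, 0), rev_orf=(0, L, 0))
        plan = design_opposing_mutations(seg, "stop_reverse", 1)
        assert plan.sites[0][0] == 3 * 30 + 2
        assert plan.sites[0][2] == "A"  # CTT -> CTA

    def test_requesting_too_many_codons_reports_achievable(self):
        seg = make_ambigram_genome(600, seed=2)
        with pytest.raises(ValueError, match="eligible"):
            design_opposing_mutations(seg, "stop_reverse", 10_000)

    def test_reference_mismatch_caught_on_apply(self):
        plan = MutationPlan("stop_reverse", [(0, "G", "A")], 1)
        with pytest.raises(ValueError, match="mismatch"):
            plan.apply("TTTT")


class TestCharacterizeEnds:
    def _ends_reads(self, insert, n, seed=0, lead_max=6):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            lead = "".join(rng.choice(list("ACGT"), rng.integers(0, lead_max)))
            out.append(lead + HANDLE + insert)
        return out

    def test_handle_trimming(self):
        rep = characterize_ends(["NNTGCATAGGGGACGTAAAA"])
        assert rep.consensus5 == "GGGGACGT"
        assert rep.n_dropped == 0

    def test_synthetic_library_recovers_gggg_cccc(self, robin_segment):
        seq = robin_segment.sequence
        reads5 = self._ends_reads(seq[:50], 200, seed=1)
        rep = characterize_ends(reads5)
        assert rep.consensus5 is not None and rep.consensus5.startswith("GGGG")
        reads3 = self._ends_reads(seq[-50:], 200, seed=2)
        rep3 = characterize_ends(reads3)
        assert rep3.consensus3 is not None and rep3.consensus3.endswith("CCCC")

    def test_handleless_reads_dropped_and_counted(self):
        rep = characterize_ends(["ACGTACGTACGTACGT"] * 3 + ["TGCATA" + "G" * 20])
        assert rep.n_dropped == 3
        assert rep.n_reads == 1

    def test_fifty_fifty_start_is_ambiguous_not_forced(self):
        reads = ["TGCATA" + "GGGGACGTAAGG"] * 50 + ["TGCATA" + "GGGACGTAAGGT"] * 50
        rep = characterize_ends(reads)
        assert rep.ambiguous5
        assert rep.consensus5 is None
        top = sorted(rep.kmer5_freqs.values(), reverse=True)[:2]
        assert top[0] == pytest.approx(0.5) and top[1] == pytest.approx(0.5)
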