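"""Allele alignment, window normalization and outcome classification."""

import numpy as np
import pytest

from crisprtox.amplicon import (AmpliconSpec, Deletion, Insertion, PegSpec,
                                Substitution, align_read, apply_events,
                                classify_be_allele, classify_pe_allele,
                                classify_reads, indel_profile,
                                normalize_allele, per_base_conversion_table,
                                revcomp, summarize_outcomes)
from crisprtox.simulate import SimConfig, gen_amplicon_reads

# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


class TestAlignRead:
    def test_identical_read_has_no_events(self, cbe_spec):
        aln = align_read(cbe_spec.reference, cbe_spec)
        assert aln.events == ()
        assert aln.identity == 1.0

    def test_reverse_complement_detected(self, cbe_spec):
        fwd = align_read(cbe_spec.reference, cbe_spec)
        rev = align_read(revcomp(cbe_spec.reference), cbe_spec)
        assert rev.events == fwd.events
        assert rev.strand == "-"

    def test_two_nt_deletion_at_cut_recovered(self, cbe_spec):
        cut = cbe_spec.cut
        read = cbe_spec.reference[:cut - 1] + cbe_spec.reference[cut + 1:]
        aln = align_read(read, cbe_spec)
        dels = [e for e in aln.events if isinstance(e, Deletion)]
        assert len(dels) == 1 and dels[0].length == 2
        # same sequence regardless of reported placement
        assert apply_events(cbe_spec.reference, aln.events) == read

    def test_exhaustive_single_deletions_on_toy_amplicon(self):
        """Every unambiguous interior 1–3-nt deletion on a ≤60-nt amplicon is
        recovered exactly (exhaustive oracle over placements).  Placements
        within a few nt of the amplicon ends are excluded: with free
        reference end-gaps they are legitimately explained as a shifted
        end instead of an internal deletion."""
        rng = np.random.default_rng(7)
        ref = "".join(rng.choice(list("ACGT"), size=56))
        spec = AmpliconSpec(reference=ref, protospacer_start=18,
                            conversion=None)
        for length in (1, 2, 3):
            for s in range(10, len(ref) - length - 10):
                e = s + length
                if s > 0 and ref[s - 1] == ref[e - 1]:
                    continue  # placement ambiguous: skip non-canonical event
                read = ref[:s] + ref[e:]
                aln = align_read(read, spec, min_identity=0.5)
                assert aln.events == (Deletion(s, e),), (s, e)

    def test_low_identity_read_is_unalignable(self, cbe_spec):
        rng = np.random.default_rng(3)
        junk = "".join(rng.choice(list("ACGT"), size=150))
        assert align_read(junk, cbe_spec) is None

    def test_short_read_rejected(self, cbe_spec):
        with pytest.raises(ValueError):
            align_read("ACGT" * 5, cbe_spec)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


class TestNormalizeAllele:
    def test_distal_substitution_reverted_to_wt(self, cbe_spec):
        # 50 nt from the protospacer: outside the ±10-nt belief region
        pos = cbe_spec.protospacer_start - 50
        ev = (Substitution(pos, cbe_spec.reference[pos], "A"
                           if cbe_spec.reference[pos] != "A" else "C"),)
        assert normalize_allele(ev, cbe_spec) == ()
        assert classify_be_allele(normalize_allele(ev, cbe_spec),
                                  cbe_spec) == "WT"

    def test_window_edit_kept_distal_error_dropped(self, cbe_spec):
        edit = cbe_spec.expected_substitution(cbe_spec.editable_coords[0])
        far = cbe_spec.protospacer_start - 40
        err = Substitution(far, cbe_spec.reference[far],
                           "G" if cbe_spec.reference[far] != "G" else "T")
        assert normalize_allele((err, edit), cbe_spec) == (edit,)

    def test_distal_indel_retained(self, cbe_spec):
        d = Deletion(5, 8)
        assert normalize_allele((d,), cbe_spec) == (d,)

    def test_idempotent(self, cbe_spec):
        events = (Substitution(95, cbe_spec.reference[95], "T"
                               if cbe_spec.reference[95] != "T" else "A"),
                  Deletion(106, 108))
        once = normalize_allele(events, cbe_spec)
        assert normalize_allele(once, cbe_spec) == once


# ---------------------------------------------------------------------------
# BE / Cas9 classification
# ---------------------------------------------------------------------------


class TestClassifyBE:
    def test_reference_allele_is_wt(self, cbe_spec):
        assert classify_be_allele((), cbe_spec) == "WT"

    def test_expected_conversion_in_window(self, cbe_spec):
        c = cbe_spec.editable_coords[0]
        assert classify_be_allele((cbe_spec.expected_substitution(c),),
                                  cbe_spec) == "expected_edit"

    def test_wrong_transversion_in_window_is_other(self, cbe_spec):
        c = cbe_spec.editable_coords[0]
        assert cbe_spec.reference[c] == "C"
        assert classify_be_allele((Substitution(c, "C", "G"),),
                                  cbe_spec) == "other_SNV"

    def test_indel_takes_precedence_over_edit(self, cbe_spec):
        c = cbe_spec.editable_coords[0]
        events = (cbe_spec.expected_substitution(c),
                  Deletion(cbe_spec.cut - 1, cbe_spec.cut + 1))
        assert classify_be_allele(events, cbe_spec) == "indel"

    def test_indel_outside_window_does_not_trigger_indel_class(self, cbe_spec):
        d = Deletion(cbe_spec.cut + 10, cbe_spec.cut + 12)
        assert classify_be_allele((d,), cbe_spec) == "WT"

    def test_insertion_at_cut_is_indel(self, cbe_spec):
        assert classify_be_allele((Insertion(cbe_spec.cut, "TTA"),),
                                  cbe_spec) == "indel"

    def test_agrees_with_literal_rule_oracle_on_toy_amplicon(self):
        """Full align→normalize→classify agrees with a brute-force oracle
        applying the decision rules to every unambiguous single-event allele
        of a toy amplicon."""
        rng = np.random.default_rng(42)
        ref = "".join(rng.choice(list("ACGT"), size=60))
        # ensure ≥1 editable C in the window by splicing the fixture guide
        ref = ref[:20] + "GATCCACTGATGTCAATGGA" + "AGG" + ref[43:]
        spec = AmpliconSpec(reference=ref, protospacer_start=20,
                            conversion=("C", "T"))

        def oracle(events):
            lo, hi = spec.indel_window()
            for e in events:
                if isinstance(e, Deletion) and e.start <= hi and e.end - 1 >= lo:
                    return "indel"
                if isinstance(e, Insertion) and lo <= e.pos <= hi + 1:
                    return "indel"
            rlo, rhi = spec.substitution_region
            expected = {spec.expected_substitution(c)
                        for c in spec.editable_coords}
            subs = [e for e in events if isinstance(e, Substitution)
                    and rlo <= e.pos < rhi]
            if any(s not in expected for s in subs):
                return "other_SNV"
            return "expected_edit" if subs else "WT"

        alleles = []
        for pos in range(4, len(ref) - 4):
            for alt in "ACGT":
                if alt != ref[pos]:
                    alleles.append((Substitution(pos, ref[pos], alt),))
        for pos in range(4, len(ref) - 6):
            for length in (1, 2):
                s, e = pos, pos + length
                if ref[s - 1] == ref[e - 1] or ref[s] == ref[e]:
                    continue  # placement-ambiguous deletion
                alleles.append((Deletion(s, e),))
        for pos in range(4, len(ref) - 4):
            for ins in ("T", "GG"):
                if ref[pos - 1] == ins[-1] or ref[pos] == ins[0]:
                    continue  # placement-ambiguous insertion
                alleles.append((Insertion(pos, ins),))

        mismatches = []
        for events in alleles:
            read = apply_events(ref, events)
            aln = align_read(read, spec, min_identity=0.5)
            got = classify_be_allele(normalize_allele(aln.events, spec), spec)
            want = oracle(normalize_allele(events, spec))
            if got != want:
                mismatches.append((events, got, want))
        assert not mismatches, mismatches[:5]


# ---------------------------------------------------------------------------
# PE classification
# ---------------------------------------------------------------------------


class TestClassifyPE:
    def test_reference_is_wt(self, peg_spec):
        assert classify_pe_allele((), peg_spec) == "WT"

    def test_intended_edit_only_is_precise(self, peg_spec):
        assert classify_pe_allele(peg_spec.intended_events(),
                                  peg_spec) == "precise_PE"

    def test_edit_plus_scaffold_insertion_is_imprecise(self, peg_spec):
        ins = Insertion(peg_spec.peg_nick, peg_spec.scaffold_prefix[:4])
        events = peg_spec.intended_events() + (ins,)
        assert classify_pe_allele(events, peg_spec) == "imprecise_PE"

    def test_edit_plus_deletion_at_second_nick_is_imprecise(self, peg_spec):
        nick2 = peg_spec.nick_gRNA.cut
        events = peg_spec.intended_events() + (Deletion(nick2 - 1, nick2 + 1),)
        assert classify_pe_allele(events, peg_spec) == "imprecise_PE"

    def test_unedited_deletion_at_pe3_nick_is_other(self, peg_spec):
        nick2 = peg_spec.nick_gRNA.cut
        assert classify_pe_allele((Deletion(nick2 - 1, nick2 + 1),),
                                  peg_spec) == "other"

    def test_edit_plus_distal_indel_is_other(self, peg_spec):
        far = Deletion(5, 7)
        events = peg_spec.intended_events() + (far,)
        assert classify_pe_allele(events, peg_spec) == "other"

    def test_short_insertion_not_matching_scaffold_still_indel(self, peg_spec):
        # a non-scaffold insertion at the nick is still an indel at a nick
        ins = Insertion(peg_spec.peg_nick, "TTT")
        assert peg_spec.scaffold_prefix[:3] != "TTT"
        events = peg_spec.intended_events() + (ins,)
        assert classify_pe_allele(events, peg_spec) == "imprecise_PE"


# ---------------------------------------------------------------------------
# summaries, profiles, conversion tables
# ---------------------------------------------------------------------------


class TestSummaries:
    def test_pure_wt_summary(self, cbe_spec):
        table = classify_reads([cbe_spec.reference] * 100, cbe_spec)
        s = summarize_outcomes(table)
        assert s.fractions["WT"] == 1.0
        assert s.total_reads == 100

    def test_fractions_from_counts(self, cbe_spec):
        c = cbe_spec.editable_coords[0]
        edited = apply_events(cbe_spec.reference,
                              (cbe_spec.expected_substitution(c),))
        cut = cbe_spec.cut
        deleted = cbe_spec.reference[:cut - 1] + cbe_spec.reference[cut + 1:]
        table = classify_reads([edited] * 60 + [deleted] * 40, cbe_spec)
        s = summarize_outcomes(table)
        assert s.fractions["expected_edit"] == pytest.approx(0.6)
        assert s.fractions["indel"] == pytest.approx(0.4)
        assert sum(s.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_table_rejected(self, cbe_spec):
        table = classify_reads([], cbe_spec)
        with pytest.raises(ValueError):
            summarize_outcomes(table)

    def test_classified_plus_unalignable_equals_input(self, cbe_spec):
        rng = np.random.default_rng(5)
        junk = "".join(rng.choice(list("ACGT"), size=150))
        reads = [cbe_spec.reference] * 10 + [junk] * 3 + ["ACGT" * 10]
        table = classify_reads(reads, cbe_spec)
        assert table.total_classified + table.unalignable + table.too_short \
            == len(reads)

    def test_strand_symmetric_summaries(self, cbe_spec):
        """A − strand spec on the reverse-complemented reference classifies
        the same reads identically."""
        cfg = SimConfig(seed=9, n_reads=400, per_base_error_rate=0.0,
                        outcome_mixture={"WT": 0.4, "expected_edit": 0.3,
                                         "other_SNV": 0.1, "indel": 0.2})
        reads, _ = gen_amplicon_reads(cbe_spec, cfg)
        minus = AmpliconSpec(
            reference=revcomp(cbe_spec.reference),
            protospacer_start=(len(cbe_spec.reference)
                               - cbe_spec.protospacer_start
                               - cbe_spec.protospacer_length),
            protospacer_strand="-", conversion=cbe_spec.conversion)
        assert minus.protospacer == cbe_spec.protospacer
        plus_summary = summarize_outcomes(
            classify_reads(reads["sequence"], cbe_spec))
        minus_summary = summarize_outcomes(
            classify_reads(reads["sequence"], minus))
        for k, v in plus_summary.fractions.items():
            assert minus_summary.fractions[k] == pytest.approx(v, abs=1e-12)


class TestIndelProfile:
    def test_single_deletion_profile(self, cas9_spec):
        read = cas9_spec.reference[:100] + cas9_spec.reference[104:]
        table = classify_reads([read], cas9_spec)
        prof = indel_profile(table)
        assert prof.n_indel_reads == 1
        dels = [e for e in table.records.iloc[0]["events"]
                if isinstance(e, Deletion)]
        assert dels[0].center == pytest.approx((dels[0].start
                                                + dels[0].end - 1) / 2)
        np.testing.assert_allclose(
            prof.deletion_frequency[dels[0].start:dels[0].end], 1.0)

    def test_cas9_deletion_centers_mode_near_cut(self, cas9_spec):
        cfg = SimConfig(seed=21, n_reads=3000, per_base_error_rate=0.0,
                        outcome_mixture={"indel": 1.0})
        reads, _ = gen_amplicon_reads(cas9_spec, cfg)
        table = classify_reads(reads["sequence"], cas9_spec)
        prof = indel_profile(table)
        mode = prof.center_histogram.idxmax()
        assert abs(mode - cas9_spec.cut) <= 1

    def test_cbe_deletion_centers_between_window_and_nick(self, cbe_spec):
        cfg = SimConfig(seed=22, n_reads=3000, per_base_error_rate=0.0,
                        outcome_mixture={"indel": 1.0})
        reads, _ = gen_amplicon_reads(cbe_spec, cfg)
        table = classify_reads(reads["sequence"], cbe_spec)
        prof = indel_profile(table)
        lo = min(cbe_spec.window_coords) - 1
        hi = max(max(cbe_spec.window_coords), cbe_spec.cut) + 1
        inside = prof.center_histogram[
            (prof.center_histogram.index >= lo)
            & (prof.center_histogram.index <= hi)].sum()
        assert inside / prof.center_histogram.sum() >= 0.8


class TestConversionTable:
    def test_all_wt_composition(self, cbe_spec):
        table = classify_reads([cbe_spec.reference] * 5, cbe_spec)
        comp = per_base_conversion_table(table)
        for p in range(1, 21):
            assert comp.at[p, cbe_spec.protospacer[p - 1]] == 1.0

    def test_partial_conversion_fraction(self, cbe_spec):
        c = cbe_spec.editable_coords[0]
        pos = [p for p in range(1, 21) if cbe_spec.ref_coord(p) == c][0]
        edited = apply_events(cbe_spec.reference,
                              (cbe_spec.expected_substitution(c),))
        table = classify_reads([edited] * 3 + [cbe_spec.reference] * 7,
                               cbe_spec)
        comp = per_base_conversion_table(table)
        assert comp.at[pos, "T"] == pytest.approx(0.30)
        assert comp.at[pos, "C"] == pytest.approx(0.70)


class TestSpecValidation:
    def test_protospacer_must_fit(self):
        with pytest.raises(ValueError):
            AmpliconSpec(reference="ACGT" * 10, protospacer_start=35)

    def test_window_within_protospacer(self, reference):
        with pytest.raises(ValueError):
            AmpliconSpec(reference=reference, protospacer_start=90,
                         editing_window=(0, 8))

    def test_conversion_bases_must_differ(self, reference):
        with pytest.raises(ValueError):
            AmpliconSpec(reference=reference, protospacer_start=90,
                         conversion=("C", "C"))

    def test_pegspec_requires_scaffold(self, cas9_spec):
        with pytest.raises(ValueError):
            PegSpec(base=cas9_spec, intended_edit=(100, 102, "AA"),
                    scaffold_prefix="GC")
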