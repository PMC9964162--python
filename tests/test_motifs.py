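import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gh51kit.errors import DataError
from gh51kit.io import AA20, Msa, ProteinRecord
from gh51kit.motifs import (
    CatalyticStatus,
    Evidence,
    FailureReason,
    classify_catalytic,
    compile_pattern,
    filter_set,
    locate_conserved_motif,
    scan_sequence,
    validate_gh51,
)
from gh51kit.simulate import SimParams, generate_family

from .oracles import brute_force_motif_starts


def rec(seq, rid="r1"):
    return ProteinRecord(rid, seq)


class TestCompilePattern:
    def test_alternation(self):
        pat = compile_pattern("G-N-E/Q")
        assert len(pat) == 3
        assert pat.tokens[0] == frozenset("G")
        assert pat.tokens[1] == frozenset("N")
        assert pat.tokens[2] == frozenset("EQ")

    def test_wildcards(self):
        pat = compile_pattern("S-x-x-P")
        assert pat.tokens == (frozenset("S"), None, None, frozenset("P"))

    def test_empty_token_rejected(self):
        with pytest.raises(DataError):
            compile_pattern("G--N")

    def test_single_token_rejected(self):
        with pytest.raises(DataError):
            compile_pattern("G")

    def test_illegal_residue_rejected(self):
        with pytest.raises(DataError):
            compile_pattern("G-1-E")

    def test_text_round_trip(self):
        for text in ("G-N-E/Q", "S-E-Y-x-V", "L-x-V-D", "S-x-x-P",
                     "G-x-x-F-E-x-I-x-x-x-G-x-G-G"):
            assert str(compile_pattern(text)) == text


class TestScanSequence:
    def test_simple_hit(self):
        hits = scan_sequence(compile_pattern("S-E-Y-x-V"), rec("ASEYKVA"))
        assert len(hits) == 1
        assert hits[0].start == 1
        assert hits[0].matched == "SEYKV"

    def test_double_hit_resolutions(self):
        hits = scan_sequence(compile_pattern("G-N-E/Q"), rec("GNQGNE"))
        assert [(h.start, h.resolutions) for h in hits] == [(0, ("Q",)), (3, ("E",))]

    def test_overlapping_hits(self):
        hits = scan_sequence(compile_pattern("A-x-A"), rec("AAAAA"))
        assert [h.start for h in hits] == [0, 1, 2]

    def test_wildcard_matches_x_fixed_does_not(self):
        assert scan_sequence(compile_pattern("A-x-A"), rec("AXA"))
        assert not scan_sequence(compile_pattern("A-C-A"), rec("AXA"))

    def test_no_match_empty_list(self):
        assert scan_sequence(compile_pattern("W-W-W"), rec("ACDEF")) == []

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_brute_force(self, data):
        seq = data.draw(st.text(alphabet=AA20 + "X", min_size=1, max_size=50))
        n_tok = data.draw(st.integers(2, 5))
        tokens = []
        for _ in range(n_tok):
            kind = data.draw(st.sampled_from(["fixed", "alt", "wild"]))
            if kind == "wild":
                tokens.append("x")
            elif kind == "fixed":
                tokens.append(data.draw(st.sampled_from(AA20)))
            else:
                pair = data.draw(st.sets(st.sampled_from(AA20), min_size=2, max_size=3))
                tokens.append("/".join(sorted(pair)))
        pat = compile_pattern("-".join(tokens))
        got = [h.start for h in scan_sequence(pat, rec(seq if seq else "A"))]
        assert got == brute_force_motif_starts(pat, seq if seq else "A")


class TestValidate:
    BASE = "GNE" + "A" * 300 + "SEYKV"  # 308 residues with both motifs

    def pad(self, n):
        return self.BASE + "W" * (n - len(self.BASE))

    def test_boundary_349_too_short(self):
        result = validate_gh51(rec(self.pad(349)))
        assert not result.passed
        assert result.reasons == (FailureReason.TOO_SHORT,)

    def test_boundary_350_passes(self):
        assert validate_gh51(rec(self.pad(350))).passed

    def test_missing_nucleophile(self):
        seq = "GNE" + "A" * 400
        result = validate_gh51(rec(seq))
        assert result.reasons == (FailureReason.MISSING_SEYXV,)

    def test_missing_acid_base(self):
        seq = "A" * 400 + "SEYKV"
        result = validate_gh51(rec(seq))
        assert result.reasons == (FailureReason.MISSING_GNEQ,)

    def test_all_reasons(self):
        result = validate_gh51(rec("W" * 100))
        assert set(result.reasons) == {
            FailureReason.TOO_SHORT,
            FailureReason.MISSING_GNEQ,
            FailureReason.MISSING_SEYXV,
        }

    def test_relaxed_accepts_gnd_and_gsn(self):
        for site in ("GND", "GSN"):
            seq = site + "A" * 350 + "SEYKV"
            assert not validate_gh51(rec(seq)).passed
            assert validate_gh51(rec(seq), relaxed=True).passed

    def test_monotone_in_min_len(self):
        rng = random.Random(0)
        for _ in range(20):
            seq = "".join(rng.choice(AA20) for _ in range(rng.randint(300, 400)))
            r = rec(seq)
            for lo, hi in [(200, 300), (300, 350), (350, 400)]:
                if validate_gh51(r, min_len=hi).passed:
                    assert validate_gh51(r, min_len=lo).passed


class TestFilterSet:
    def test_empty(self):
        assert filter_set([]) == ([], [])

    def test_partition_law(self, family_bundle):
        _, records, _, _ = family_bundle
        kept, excluded = filter_set(records)
        assert len(kept) + len(excluded) == len(records)
        assert {r.id for r in kept} | {e.seq_id for e in excluded} == {r.id for r in records}
        assert {r.id for r in kept} & {e.seq_id for e in excluded} == set()

    def test_duplicate_ids_rejected(self):
        r = rec("GNE" + "A" * 350 + "SEYKV")
        with pytest.raises(DataError):
            filter_set([r, r])

    def test_planted_156_minus_17(self):
        """156 clean sequences, 17 deliberately broken -> 139 kept."""
        records, _, truth = generate_family(SimParams(seed=11, n=156))
        assert all(row.passes_filter for row in truth.rows)
        broken = []
        for i, r in enumerate(records):
            if i < 10:  # too short
                broken.append(ProteinRecord(r.id, r.sequence[:349]))
            elif i < 17:  # knock out the nucleophile motif
                hit = scan_sequence(compile_pattern("S-E-Y-x-V"), r)[0]
                seq = r.sequence[: hit.start] + "A" + r.sequence[hit.start + 1 :]
                assert not scan_sequence(compile_pattern("S-E-Y-x-V"), ProteinRecord(r.id, seq))
                broken.append(ProteinRecord(r.id, seq))
            else:
                broken.append(r)
        kept, excluded = filter_set(broken)
        assert len(kept) == 139
        assert len(excluded) == 17


class TestLocateConservedMotif:
    def test_perfectly_conserved(self):
        row = "GG" * 5 + "LAVD" + "GG" * 3
        msa = Msa([(f"s{i}", row) for i in range(4)])
        assert locate_conserved_motif(msa, compile_pattern("L-x-V-D")) == (10, 14)

    def test_below_threshold_none(self):
        msa = Msa([("a", "LAVDGG"), ("b", "GGGGGG"), ("c", "GGGGGG"), ("d", "GGGGGG")])
        assert locate_conserved_motif(msa, compile_pattern("L-x-V-D"), 0.5) is None

    def test_gapped_rows_do_not_match(self):
        msa = Msa([("a", "LA-VD"), ("b", "LAVD-")])
        # only row b has an intact gap-free window at columns 0-3
        assert locate_conserved_motif(msa, compile_pattern("L-x-V-D"), 0.5) == (0, 4)

    def test_pattern_longer_than_alignment(self):
        with pytest.raises(DataError):
            locate_conserved_motif(Msa([("a", "LA")]), compile_pattern("L-x-V-D"))

    def test_matches_window_oracle(self):
        rng = random.Random(5)
        pat = compile_pattern("L-x-V-D")
        for _ in range(50):
            n_rows = rng.randint(2, 6)
            n_cols = rng.randint(4, 20)
            rows = []
            for i in range(n_rows):
                rows.append(
                    (f"s{i}", "".join(rng.choice(AA20 + "-") for _ in range(n_cols)))
                )
            msa = Msa(rows)
            # oracle: evaluate every window fraction directly
            best, best_frac = None, 0.0
            for c in range(n_cols - 4 + 1):
                n_match = sum(
                    1
                    for _, s in msa.rows
                    if "-" not in s[c : c + 4]
                    and brute_force_motif_starts(pat, s[c : c + 4]) == [0]
                )
                frac = n_match / n_rows
                if frac >= 0.5 and frac > best_frac:
                    best, best_frac = (c, c + 4), frac
            assert locate_conserved_motif(msa, pat, 0.5) == best


class TestClassifyCatalytic:
    def test_canonical(self):
        call = classify_catalytic(rec("AAGNEAA"))
        assert call.status is CatalyticStatus.CANONICAL_E
        assert call.motif_start == 2
        assert call.evidence is Evidence.DIRECT_SCAN

    def test_substituted_q(self):
        assert classify_catalytic(rec("AAGNQAA")).status is CatalyticStatus.SUBSTITUTED_Q

    def test_substituted_d(self):
        assert classify_catalytic(rec("GNDAA")).status is CatalyticStatus.SUBSTITUTED_D

    def test_variant_gsn(self):
        assert classify_catalytic(rec("GSNAA")).status is CatalyticStatus.VARIANT_GSN

    def test_precedence_gne_over_gnq(self):
        assert classify_catalytic(rec("GNQAAGNE")).status is CatalyticStatus.CANONICAL_E

    def test_undetermined(self):
        call = classify_catalytic(rec("AAAAA"))
        assert call.status is CatalyticStatus.UNDETERMINED
        assert call.motif_start is None

    def test_alignment_column_fallback(self):
        msa = Msa([("r1", "AAGN-DAA"), ("r2", "AAGNXEAA")])
        call = classify_catalytic(rec("AAGNDAA"), msa=msa, ref_column=5)
        assert call.status is CatalyticStatus.SUBSTITUTED_D
        assert call.evidence is Evidence.ALIGNMENT_COLUMN

    def test_alignment_column_gap_undetermined(self):
        msa = Msa([("r1", "AAGN-DAA")])
        call = classify_catalytic(rec("AAGNDAA"), msa=msa, ref_column=4)
        assert call.status is CatalyticStatus.UNDETERMINED

    def test_zero_noise_family_agrees_with_truth(self):
        params = SimParams(
            seed=3,
            n=60,
            catalytic_composition={
                CatalyticStatus.CANONICAL_E: 0.4,
                CatalyticStatus.SUBSTITUTED_Q: 0.3,
                CatalyticStatus.SUBSTITUTED_D: 0.2,
                CatalyticStatus.VARIANT_GSN: 0.1,
            },
        )
        records, _, truth = generate_family(params)
        by_id = truth.by_id()
        for record in records:
            assert classify_catalytic(record).status is by_id[record.id].catalytic_status
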