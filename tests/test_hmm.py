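import math
import random
import shutil
import subprocess

import numpy as np
import pytest

from gh51kit.errors import DataError
from gh51kit.hmm import (
    build_profile,
    forward_bits,
    load_profile,
    save_profile,
    scan,
    select_match_columns,
    viterbi,
)
from gh51kit.io import AA20, Msa, ProteinRecord, write_alignment

from .oracles import enumerate_hmm_scores


def random_msa(rng, n_rows, n_cols, gap_p=0.2):
    rows = []
    for i in range(n_rows):
        row = "".join(
            "-" if rng.random() < gap_p else rng.choice(AA20) for _ in range(n_cols)
        )
        if set(row) == {"-"}:
            row = rng.choice(AA20) + row[1:]
        rows.append((f"s{i}", row))
    return Msa(rows)


def random_profile(rng, max_cols=4):
    n_cols = rng.randint(1, max_cols)
    msa = random_msa(rng, rng.randint(1, 4), n_cols, gap_p=0.25)
    return build_profile(msa, max_gap_fraction=1.0)  # keep every column


class TestSelectMatchColumns:
    def test_gap_free_all_match(self):
        msa = Msa([("a", "ACDE"), ("b", "ACDE")])
        assert select_match_columns(msa) == [True] * 4

    def test_mostly_gapped_column_excluded(self):
        msa = Msa([("a", "A-"), ("b", "A-"), ("c", "A-"), ("d", "AC")])
        assert select_match_columns(msa) == [True, False]

    def test_no_match_columns_error(self):
        msa = Msa([("a", "A-"), ("b", "-C")])
        with pytest.raises(DataError, match="no match columns"):
            select_match_columns(msa, max_gap_fraction=0.4)

    def test_counting_oracle(self):
        rng = random.Random(1)
        for _ in range(30):
            msa = random_msa(rng, rng.randint(1, 6), rng.randint(1, 10))
            flags = select_match_columns(msa, max_gap_fraction=1.0)
            for c, flag in enumerate(flags):
                gaps = sum(1 for _, s in msa.rows if s[c] == "-")
                assert flag == (gaps / msa.n_rows <= 1.0)


class TestBuildProfile:
    def test_single_sequence_modal_residues(self):
        profile = build_profile(Msa([("a", "ACD")]))
        assert profile.M == 3
        for k, aa in zip((1, 2, 3), "ACD"):
            assert AA20[int(np.argmax(profile.mat[k]))] == aa

    def test_duplicate_rows_do_not_change_profile(self):
        one = build_profile(Msa([("a", "AC-E")]))
        two = build_profile(Msa([("a", "AC-E"), ("b", "AC-E")]))
        assert np.allclose(one.mat, two.mat)
        M = one.M
        for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            assert np.allclose(getattr(one, name)[1:M], getattr(two, name)[1:M])

    def test_hand_computed_fixture(self):
        # rows ACDE / AC-E / GCDE, uniform background 1/20, pseudocount 1,
        # per-row weight 1/3
        profile = build_profile(Msa([("a", "ACDE"), ("b", "AC-E"), ("c", "GCDE")]))
        assert profile.M == 4
        iA, iG, iD = AA20.index("A"), AA20.index("G"), AA20.index("D")
        # state 1: counts A=2/3, G=1/3, total 1: (2/3 + 0.05) / 2
        assert profile.mat[1, iA] == pytest.approx((2 / 3 + 0.05) / 2)
        assert profile.mat[1, iG] == pytest.approx((1 / 3 + 0.05) / 2)
        assert profile.mat[1, AA20.index("C")] == pytest.approx(0.05 / 2)
        # state 3: counts D=2/3 (one row deleted), total 2/3
        assert profile.mat[3, iD] == pytest.approx((2 / 3 + 0.05) / (2 / 3 + 1))
        # transitions out of position 2: two M->M, one M->D
        assert profile.t_mm[2] == pytest.approx((2 / 3 + 1 / 3) / 2)
        assert profile.t_mi[2] == pytest.approx((0 + 1 / 3) / 2)
        assert profile.t_md[2] == pytest.approx((1 / 3 + 1 / 3) / 2)

    def test_distributions_sum_to_one(self, family_profile):
        profile = family_profile
        assert np.allclose(profile.mat[1:].sum(axis=1), 1.0)
        M = profile.M
        assert np.allclose(
            (profile.t_mm + profile.t_mi + profile.t_md)[1:M], 1.0
        )
        assert np.allclose((profile.t_im + profile.t_ii)[1:M], 1.0)
        assert np.allclose((profile.t_dm + profile.t_dd)[1:M], 1.0)

    def test_empty_pseudocount_rejected(self):
        with pytest.raises(DataError):
            build_profile(Msa([("a", "ACD")]), pseudocount=0.0)


class TestScoring:
    def test_self_hit_positive(self):
        profile = build_profile(Msa([("a", "ACDEFGHIKL")]))
        assert forward_bits(profile, ProteinRecord("a", "ACDEFGHIKL")) > 0

    def test_viterbi_path_and_interval(self):
        profile = build_profile(Msa([("a", "ACD")]))
        result = viterbi(profile, ProteinRecord("q", "ACD"))
        assert result.path == ("M1", "M2", "M3")
        assert result.interval == (0, 3)

    def test_viterbi_interval_with_flanks(self):
        profile = build_profile(Msa([("a", "ACDEFGHIKL")]))
        result = viterbi(profile, ProteinRecord("q", "WWWACDEFGHIKLWW"))
        assert result.interval == (3, 13)

    @pytest.mark.parametrize("mode", ["local", "glocal"])
    def test_matches_enumeration_oracle(self, mode):
        rng = random.Random(42)
        for _ in range(60):
            profile = random_profile(rng)
            L = rng.randint(1, 6)
            seq = "".join(rng.choice(AA20 + "X") for _ in range(L))
            fwd_oracle, vit_oracle = enumerate_hmm_scores(profile, seq, mode)
            record = ProteinRecord("q", seq)
            assert forward_bits(profile, record, mode) == pytest.approx(
                fwd_oracle, abs=1e-9
            )
            assert viterbi(profile, record, mode).bits == pytest.approx(
                vit_oracle, abs=1e-9
            )

    def test_viterbi_le_forward_random(self):
        rng = random.Random(9)
        for _ in range(200):
            profile = random_profile(rng, max_cols=6)
            seq = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 12)))
            record = ProteinRecord("q", seq)
            assert viterbi(profile, record).bits <= forward_bits(profile, record) + 1e-9

    def test_flanking_residues_nearly_free(self):
        """Local-mode score changes by at most a small bound when
        unrelated flanks are appended (per-residue flank cost is 0)."""
        rng = random.Random(3)
        core = "".join(rng.choice(AA20) for _ in range(30))
        profile = build_profile(Msa([("a", core)]))
        base = forward_bits(profile, ProteinRecord("q", core))
        junk = "".join(rng.choice(AA20) for _ in range(50))
        extended = forward_bits(profile, ProteinRecord("q", junk + core + junk))
        assert extended >= base - 1e-9  # old paths all survive at equal weight
        assert extended - base < 0.5  # new junk paths contribute little

class TestScan:
    def test_short_sequences_skipped(self, family_profile):
        records = [ProteinRecord("short", "ACDEFGHIKL" * 15)]  # 150 residues
        hits, skipped = scan(family_profile, records)
        assert hits == []
        assert skipped == ["short"]

    def test_boundary_exactly_min_len_skipped(self, family_profile):
        records = [ProteinRecord("edge", "ACDEFGHIKL" * 20)]  # 200 residues
        hits, skipped = scan(family_profile, records)
        assert skipped == ["edge"]

    def test_empty_input(self, family_profile):
        assert scan(family_profile, []) == ([], [])

    def test_positive_decoy_separation(self, family_bundle, family_profile):
        _, records, _, truth = family_bundle
        hits, _ = scan(family_profile, records)
        by_id = truth.by_id()
        pos = [h.bit_score for h in hits if by_id[h.seq_id].has_domain]
        neg = [h.bit_score for h in hits if not by_id[h.seq_id].has_domain]
        assert pos and neg
        assert min(pos) > max(neg)
        # default 0-bit threshold separates them
        for h in hits:
            assert h.passed == by_id[h.seq_id].has_domain

    def test_viterbi_interval_covers_planted_domain(self, family_bundle, family_profile):
        _, records, _, truth = family_bundle
        by_id = truth.by_id()
        positives = [r for r in records if by_id[r.id].has_domain][:5]
        hits, _ = scan(family_profile, positives)
        for h in hits:
            row = by_id[h.seq_id]
            overlap = min(h.end, row.domain_end) - max(h.start, row.domain_start)
            assert overlap / (row.domain_end - row.domain_start) > 0.8


class TestSerialization:
    def test_round_trip_scores_identical(self, family_profile, tmp_path):
        path = tmp_path / "profile.txt"
        save_profile(path, family_profile)
        loaded = load_profile(path)
        record = ProteinRecord("q", "ACDEFGHIKLMNPQRSTVWY" * 3)
        assert forward_bits(loaded, record) == forward_bits(family_profile, record)

    def test_bad_magic(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("HMMER3/f\n")
        with pytest.raises(DataError):
            load_profile(path)


@pytest.mark.skipif(shutil.which("hmmbuild") is None, reason="HMMER not installed")
class TestHmmerCrossCheck:
    """Optional dual-route check against the external HMMER engine.

    Bit scores are not comparable model-for-model, so the check uses a
    graded-degradation series: one true domain carrier progressively
    mutated inside its domain.  Both engines must rank the series the
    same way (strong rank correlation).
    """

    def test_rank_correlation(self, family_bundle, family_profile, tmp_path):
        from scipy.stats import spearmanr

        from gh51kit.domains import excise_domain_alignment
        from gh51kit.motifs import compile_pattern

        _, records, msa, truth = family_bundle
        excised, _, all_gap = excise_domain_alignment(
            msa, compile_pattern("L-x-V-D"), compile_pattern("S-x-x-P")
        )
        train = excised.take_rows([r for r in excised.ids if r not in set(all_gap)])
        sto = tmp_path / "train.sto"
        write_alignment(sto, train, "stockholm")
        hmm = tmp_path / "ref.hmm"
        subprocess.run(
            ["hmmbuild", "--amino", str(hmm), str(sto)],
            check=True, capture_output=True,
        )

        # degradation series from one domain-carrying family member
        by_id = truth.by_id()
        base = next(r for r in records if by_id[r.id].has_domain)
        dom_s, dom_e = by_id[base.id].domain_start, by_id[base.id].domain_end
        rng = random.Random(0)
        series = [ProteinRecord("step00", base.sequence)]
        chars = list(base.sequence)
        for step in range(1, 16):
            for _ in range(4):  # 4 more domain mutations per step
                pos = rng.randrange(dom_s, dom_e)
                chars[pos] = rng.choice([aa for aa in AA20 if aa != chars[pos]])
            series.append(ProteinRecord(f"step{step:02d}", "".join(chars)))

        fasta = tmp_path / "series.fa"
        with open(fasta, "w") as fh:
            for r in series:
                fh.write(f">{r.id}\n{r.sequence}\n")
        subprocess.run(
            ["hmmsearch", "--max", "-T", "-1000", "--tblout", str(tmp_path / "tbl.txt"),
             str(hmm), str(fasta)],
            check=True, capture_output=True, text=True,
        )
        hmmer_scores = {}
        for line in (tmp_path / "tbl.txt").read_text().splitlines():
            if line.startswith("#"):
                continue
            fields = line.split()
            hmmer_scores[fields[0]] = float(fields[5])
        our_hits, _ = scan(family_profile, series, compute_interval=False)
        pairs = [
            (h.bit_score, hmmer_scores[h.seq_id])
            for h in our_hits
            if h.seq_id in hmmer_scores
        ]
        assert len(pairs) >= 10
        rho = spearmanr(*zip(*pairs)).statistic
        assert rho >= 0.95
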