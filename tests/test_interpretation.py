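"""Attention-profile averaging, AAindex1 parsing, correlation screening."""

import numpy as np
import pytest

from attnms1.interpretation import (AttentionProfile, PropertyIndex,
                                    mean_attention_per_aa, net_charge,
                                    parse_aaindex1, pearson_with_p,
                                    peptide_descriptors, rank_significant)

# A synthetic record in AAindex1 flat-file layout (values invented for the
# test; the accession is not a real database entry).
SYNTH_AAINDEX = """\
H TEST000001
D Synthetic hydrophobicity-like scale (test fixture)
R PMID:0000000
A Nobody, A.
T A synthetic index for parser tests
J None (2024)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.610   0.600   0.060   0.460   1.070   0.       0.470   0.070   0.610   2.220
    1.530   1.150   1.180   2.020   1.950   0.050   0.050   2.650   1.880   1.320
//
H TEST000002
D Synthetic scale with missing values
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.0     NA      0.5     0.1     0.2     0.3     0.4     0.6     0.7     0.8
    0.9     1.1     NA      1.2     1.3     1.4     1.5     1.6     1.7     1.8
//
"""


class TestParseAaindex1:
    def test_single_record_fixture(self, tmp_path):
        p = tmp_path / "aaindex1"
        p.write_text(SYNTH_AAINDEX)
        indices = parse_aaindex1(p)
        assert len(indices) == 2
        first = indices[0]
        assert first.accession == "TEST000001"
        assert "hydrophobicity" in first.description
        assert len(first.values) == 20
        assert first.values["A"] == pytest.approx(0.610)
        assert first.values["V"] == pytest.approx(1.320)
        assert first.values["Q"] == pytest.approx(0.0)  # '0.' parses

    def test_na_entries_become_missing(self, tmp_path):
        p = tmp_path / "aaindex1"
        p.write_text(SYNTH_AAINDEX)
        second = parse_aaindex1(p)[1]
        assert len(second.values) == 18
        assert "R" not in second.values and "M" not in second.values

    def test_malformed_value_block_names_accession(self, tmp_path):
        p = tmp_path / "aaindex1"
        p.write_text("H BAD0000001\nD broken\nI  A/L\n    0.1 0.2\n//\n")
        with pytest.raises(ValueError, match="BAD0000001"):
            parse_aaindex1(p)


class TestMeanAttentionPerAa:
    def test_within_sequence_average(self):
        profile = mean_attention_per_aa(["AAC"], [np.array([0.5, 0.3, 0.2])])
        assert profile.mean_weight["A"] == pytest.approx(0.4)
        assert profile.mean_weight["C"] == pytest.approx(0.2)

    def test_across_sequences_conditioned_on_presence(self):
        profile = mean_attention_per_aa(
            ["AAC", "C"], [np.array([0.5, 0.3, 0.2]), np.array([1.0])])
        assert profile.mean_weight["C"] == pytest.approx(0.6)
        assert profile.mean_weight["A"] == pytest.approx(0.4)
        assert profile.n_sequences_containing == {"A": 1, "C": 2}

    def test_unconditioned_average_divides_by_total(self):
        profile = mean_attention_per_aa(
            ["AAC", "C"], [np.array([0.5, 0.3, 0.2]), np.array([1.0])],
            condition_on_presence=False)
        assert profile.mean_weight["A"] == pytest.approx(0.2)

    def test_unobserved_residue_absent(self):
        profile = mean_attention_per_aa(["AC"], [np.array([0.6, 0.4])])
        assert "W" not in profile.mean_weight

    def test_pad_positions_ignored(self):
        # weights beyond the sequence length (pad slots) must not contribute
        profile = mean_attention_per_aa(["AC"], [np.array([0.3, 0.3, 0.4])])
        assert profile.mean_weight["A"] == pytest.approx(0.3)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            mean_attention_per_aa(["ACDK"], [np.array([0.5, 0.5])])

    def test_matches_brute_force_two_level_groupby(self, rng):
        residues = "ACDEFG"
        seqs = ["".join(rng.choice(list(residues), size=rng.integers(1, 8)))
                for _ in range(25)]
        alphas = [rng.dirichlet(np.ones(10))[: len(s) + 2] for s in seqs]
        profile = mean_attention_per_aa(seqs, alphas)
        for aa in set("".join(seqs)):
            per_seq = []
            for s, al in zip(seqs, alphas):
                hits = [al[t] for t, x in enumerate(s) if x == aa]
                if hits:
                    per_seq.append(np.mean(hits))
            assert profile.mean_weight[aa] == pytest.approx(np.mean(per_seq))


class TestPearsonWithP:
    def test_perfect_correlation(self):
        x = np.arange(20.0)
        r, _ = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_r_point7_at_n20_is_significant(self):
        # a 20-point pair constructed to have r ~= 0.7: the analytic
        # two-sided p from t = r sqrt((n-2)/(1-r^2)), df 18, is ~5.8e-4
        rng = np.random.default_rng(5)
        for _ in range(200):
            x = rng.standard_normal(20)
            y = 0.7 * (x - x.mean()) / x.std() + np.sqrt(1 - 0.49) * rng.standard_normal(20)
            r, p = pearson_with_p(x, y)
            if abs(r - 0.7) < 5e-3:
                break
        else:
            pytest.fail("could not construct a pair with r ~= 0.7")
        from scipy import stats
        t = r * np.sqrt(18 / (1 - r ** 2))
        expected = 2 * stats.t.sf(abs(t), df=18)
        assert p == pytest.approx(expected, rel=1e-6)
        assert p < 1e-3

    def test_symmetry_and_affine_invariance(self, rng):
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        r_xy, p_xy = pearson_with_p(x, y)
        r_yx, p_yx = pearson_with_p(y, x)
        assert (r_xy, p_xy) == (r_yx, p_yx)
        r_scaled, _ = pearson_with_p(3.0 * x - 7.0, y)
        assert r_scaled == pytest.approx(r_xy, abs=1e-12)

    def test_pairwise_deletion_of_missing(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        r, _ = pearson_with_p(x, y)
        assert r == pytest.approx(1.0)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError):
            pearson_with_p(np.arange(5.0), np.ones(5))

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError):
            pearson_with_p(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


def _profile_from_values(values: dict) -> AttentionProfile:
    return AttentionProfile(mean_weight=dict(values),
                            n_sequences_containing={k: 10 for k in values})


class TestRankSignificant:
    AAS = "ACDEFGHIKLMNPQRSTVWY"

    def test_proportional_index_ranks_first(self, rng):
        weights = {aa: float(w) for aa, w in
                   zip(self.AAS, rng.uniform(0.01, 0.1, 20))}
        profile = _profile_from_values(weights)
        exact = PropertyIndex("EXACT00001", "proportional",
                              {aa: 5.0 * w for aa, w in weights.items()})
        flipped = PropertyIndex("FLIP000001", "anti-proportional",
                                {aa: -w for aa, w in weights.items()})
        noise = PropertyIndex("NOISE00001", "noise",
                              {aa: float(v) for aa, v in
                               zip(self.AAS, rng.standard_normal(20))})
        results = rank_significant(profile, [noise, flipped, exact])
        assert results[0].accession == "EXACT00001"
        assert results[0].pcc == pytest.approx(1.0)
        assert any(r.accession == "FLIP000001" and r.pcc == pytest.approx(-1.0)
                   for r in results)
        assert all(abs(r.pcc) >= 0.7 for r in results)

    def test_boundary_is_inclusive(self):
        profile = _profile_from_values({"A": 1.0, "C": 2.0, "D": 3.0, "E": 5.0})
        # construct an index with |pcc| very close to 0.7 and check the
        # inclusive comparison via threshold equal to the achieved value
        index = PropertyIndex("NEAR000001", "near",
                              {"A": 1.0, "C": 3.0, "D": 2.0, "E": 4.0})
        (result,) = rank_significant(profile, [index], threshold=0.0)
        assert rank_significant(profile, [index], threshold=abs(result.pcc))

    def test_noisy_recovery_of_seed_index(self, rng):
        base = {aa: float(v) for aa, v in
                zip(self.AAS, rng.uniform(-2, 2, 20))}
        target = PropertyIndex("TRUE000001", "source", base)
        sd = np.std(list(base.values()))
        noisy = {aa: v + rng.normal(0, 0.1 * sd) for aa, v in base.items()}
        profile = _profile_from_values(noisy)
        decoys = [PropertyIndex(f"DEC{i:07d}", "decoy",
                                {aa: float(v) for aa, v in
                                 zip(self.AAS, rng.standard_normal(20))})
                  for i in range(30)]
        results = rank_significant(profile, decoys + [target], threshold=0.0)
        assert results[0].accession == "TRUE000001"

    def test_noisy_recovery_rate_across_repetitions(self):
        # profile = index + Gaussian noise (sigma = 10% of index SD) must
        # put the source index on top in >= 95/100 seeded repetitions
        rng = np.random.default_rng(77)
        base = {aa: float(v) for aa, v in
                zip(self.AAS, rng.uniform(-2, 2, 20))}
        target = PropertyIndex("TRUE000001", "source", base)
        sd = np.std(list(base.values()))
        decoys = [PropertyIndex(f"DEC{i:07d}", "decoy",
                                {aa: float(v) for aa, v in
                                 zip(self.AAS, rng.standard_normal(20))})
                  for i in range(50)]
        hits = 0
        for _ in range(100):
            noisy = {aa: v + rng.normal(0, 0.1 * sd) for aa, v in base.items()}
            results = rank_significant(_profile_from_values(noisy),
                                       decoys + [target], threshold=0.0)
            hits += results[0].accession == "TRUE000001"
        assert hits >= 95


class TestPeptideDescriptors:
    def test_positive_count(self):
        d = peptide_descriptors("KRHA")
        assert d.n_positive == 3
        assert d.n_positive_per_length == pytest.approx(0.75)

    def test_gg_net_charge_near_zero_at_ph7(self):
        # N-term (pKa 9.0) ~ +0.99, C-term (pKa 2.0) ~ -1.00
        d = peptide_descriptors("GG", pH=7.0)
        assert d.net_charge == pytest.approx(-0.01, abs=0.005)

    def test_index_sum_and_mean(self):
        index = PropertyIndex("T", "t", {"A": 0.5})
        d = peptide_descriptors("AA", index=index)
        assert d.index_sum == pytest.approx(1.0)
        assert d.index_mean == pytest.approx(0.5)

    def test_missing_residue_marks_descriptor_missing(self):
        index = PropertyIndex("T", "t", {"A": 0.5})
        d = peptide_descriptors("AC", index=index)
        assert d.index_sum is None and d.index_mean is None

    def test_tryptic_peptide_positive_at_acidic_ph(self):
        d = peptide_descriptors("LGEHNIDVLEGNEQFINAAK", pH=3.0)
        assert d.net_charge > 0

    def test_nonstandard_sequence_is_error(self):
        with pytest.raises(ValueError):
            peptide_descriptors("ACBX")


def test_net_charge_monotone_decreasing_in_ph():
    charges = [net_charge("ACDKRH", ph) for ph in (1.0, 3.0, 5.0, 7.0, 9.0, 12.0)]
    assert all(a > b for a, b in zip(charges, charges[1:]))

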