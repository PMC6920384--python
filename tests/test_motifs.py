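"""Degenerate motif matching, positional scanning and enrichment."""

import itertools
import math
import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sortramp import motifs as mot
from sortramp.errors import ConfigurationError, PatternError


class TestMatchAt:
    def test_d_accepts_a_but_excludes_c(self):
        assert mot.match_at("AAATATGGG", mot.AADTAT, 1)
        assert not mot.match_at("AACTATGGG", mot.AADTAT, 1)

    def test_v_excludes_t(self):
        assert mot.match_at("AAAATTGGG", mot.AAVATT, 1)
        assert not mot.match_at("AATATTGGG", mot.AAVATT, 1)

    def test_peptide_motif_matches_lys_ile(self):
        assert mot.match_at("AAAATTCAT", mot.KNYI, 3)  # K-I-H
        assert not mot.match_at("AAAATTCAT", mot.KNYI, 4)  # I-H

    def test_stop_windows_never_match_peptide_motifs(self):
        assert not mot.match_at("AAATATTAA", mot.KNYI, 3)  # K-Y-*

    def test_rna_pattern_and_window_are_normalized(self):
        pat = mot.MotifPattern.nucleotide("AADUAU")
        assert mot.match_at("AAAUAUGGG", pat, 1)

    def test_invalid_iupac_rejected(self):
        with pytest.raises(PatternError):
            mot.MotifPattern.nucleotide("AAXTAT")

    def test_out_of_window_offset_rejected(self):
        with pytest.raises(PatternError):
            mot.match_at("AAATATGGG", mot.AADTAT, 5)

    def test_agrees_with_regex_oracle_on_random_triples(self):
        rng = np.random.default_rng(11)
        iupac = list(mot.IUPAC_CODES)
        for _ in range(2000):
            window = "".join(rng.choice(list("ACGT"), 9))
            length = int(rng.integers(1, 10))
            pattern = "".join(rng.choice(iupac, length))
            offset = int(rng.integers(1, 9 - length + 2))
            regex = "".join(
                "[" + "".join(sorted(mot.IUPAC_CODES[c])) + "]" for c in pattern
            )
            oracle = re.match(regex, window[offset - 1 :]) is not None
            got = mot.match_at(
                window, mot.MotifPattern.nucleotide(pattern, (offset,)), offset
            )
            assert got == oracle


class TestScanPositions:
    def test_finds_all_offsets_by_exhaustive_comparison(self):
        window = "AAATATAAT"
        got = mot.scan_positions(window, mot.AADTAT)
        brute = tuple(
            off
            for off in range(1, 5)
            if all(
                window[off - 1 + i] in mot.IUPAC_CODES[p]
                for i, p in enumerate("AADTAT")
            )
        )
        assert got == brute == (1,)

    def test_pattern_longer_than_window_matches_nowhere(self):
        pat = mot.MotifPattern.nucleotide("A" * 12, anchor_offsets=(1,))
        assert mot.scan_positions("AAAAAAAAA", pat) == ()

    def test_hexamer_offset1_match_count_by_enumeration(self):
        # over all 4^6 hexamer prefixes: D has 3 options, others fixed
        n = sum(
            all(h[i] in mot.IUPAC_CODES[p] for i, p in enumerate("AADTAT"))
            for h in ("".join(c) for c in itertools.product("ACGT", repeat=6))
        )
        assert n == 3  # times 4^3 free tail positions = 192 windows


class TestStratify:
    def test_threshold_semantics(self):
        table = pd.DataFrame(
            {"variant": ["A", "B", "C", "D"],
             "gfp_score": [4.31, 3.5, 1.0, 4.0]}
        )
        high, low = mot.stratify_scores(table)
        assert list(high["variant"]) == ["A"]  # strictly above four
        assert list(low["variant"]) == ["C"]  # strictly below three

    def test_overlapping_thresholds_rejected(self):
        table = pd.DataFrame({"variant": ["A"], "gfp_score": [2.0]})
        with pytest.raises(ConfigurationError):
            mot.stratify_scores(table, high_min=2.0, low_max=3.0)


class TestEnrichment:
    pattern = mot.MotifPattern.nucleotide("A", anchor_offsets=(1,))

    @staticmethod
    def strata(ph, ah, pl, al):
        def encode(i):  # unique ACGT 7-mer per index
            return "".join("ACGT"[(i >> (2 * k)) & 3] for k in range(7))

        def block(n, first, score, tag):
            return pd.DataFrame(
                {
                    "variant": [first + tag + encode(i) for i in range(n)],
                    "gfp_score": score,
                }
            )

        high = pd.concat(
            [block(ph, "A", 4.5, "C"), block(ah, "C", 4.5, "C")], ignore_index=True
        )
        low = pd.concat(
            [block(pl, "A", 1.5, "G"), block(al, "C", 1.5, "G")], ignore_index=True
        )
        return high, low

    def test_identical_fractions_give_ratio_one(self):
        high, low = self.strata(5, 5, 5, 5)
        res = mot.enrichment(self.pattern, high, low, 1)
        assert res.enrichment_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_by_two_table_matches_exact_hypergeometric_oracle(self):
        high, low = self.strata(8, 2, 1, 9)
        res = mot.enrichment(self.pattern, high, low, 1)
        assert (res.n_high_with, res.n_high_without) == (8, 2)
        assert (res.n_low_with, res.n_low_without) == (1, 9)
        # oracle: two-sided exact p by enumerating the hypergeometric
        # distribution with fixed margins (N=20, K=9 carriers, n=10 high)
        hg = stats.hypergeom(20, 9, 10)
        p_obs = hg.pmf(8)
        oracle = sum(hg.pmf(k) for k in range(10) if hg.pmf(k) <= p_obs + 1e-12)
        assert res.p_value == pytest.approx(oracle, rel=1e-9)
        assert res.enrichment_ratio == pytest.approx((8 / 10) / (1 / 10))

    def test_zero_low_fraction_reports_infinite_ratio_with_exact_p(self):
        high, low = self.strata(6, 4, 0, 10)
        res = mot.enrichment(self.pattern, high, low, 1)
        assert math.isinf(res.enrichment_ratio)
        assert 0 < res.p_value < 1

    def test_mean_scores_computed_over_full_table(self):
        high, low = self.strata(3, 3, 3, 3)
        full = pd.concat([high, low], ignore_index=True)
        res = mot.enrichment(self.pattern, high, low, 1, full)
        assert res.mean_score_present == pytest.approx(3.0)
        assert res.mean_score_absent == pytest.approx(3.0)

    def test_planted_motif_recovered_from_default_simulation(self, default_scores):
        scores = default_scores[0]
        high, low = mot.stratify_scores(scores)
        for pattern in (mot.AADTAT, mot.KNYI):
            res = mot.enrichment(pattern, high, low, "pooled", scores)
            assert res.enrichment_ratio > 1
            assert res.p_value < 0.01
            assert res.mean_score_present > res.mean_score_absent


class TestPositionalProfile:
    def test_unmatched_pattern_is_flagged_empty(self):
        table = pd.DataFrame(
            {"variant": ["CCCCCCCCC", "GGGGGGGGG"], "gfp_score": [2.0, 3.0]}
        )
        prof = mot.positional_profile(mot.AADTAT, table)
        assert (prof["n_present"] == 0).all()
        assert prof["mean_present"].isna().all()

    def test_present_absent_partition_covers_table_at_each_offset(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {
                "variant": ["".join(rng.choice(list("ACGT"), 9)) for _ in range(200)],
                "gfp_score": rng.uniform(1, 5, 200),
            }
        )
        prof = mot.positional_profile(mot.MotifPattern.nucleotide("AAV"), table)
        assert ((prof["n_present"] + prof["n_absent"]) == 200).all()

    def test_offset_specific_effect_shows_up_at_its_offset(self):
        from sortramp import scoring, synthetic as syn

        pattern = mot.MotifPattern.nucleotide("AADTAT", anchor_offsets=(1,))
        model = syn.ExpressionModel(
            motif_effects=[(pattern, 0.9)], au_effect_per_nt=0.0
        )
        sim = syn.SimConfig(
            n_variants=4000,
            cells_per_library=200_000,
            reads_per_bin=(200_000,) * 5,
            replicate_count=1,
            seed=17,
        )
        exp = syn.simulate_experiment(sim, model=model)
        scores = scoring.score_pipeline(exp.replicates[0])
        prof = mot.positional_profile(mot.AADTAT, scores).set_index("offset")
        others = prof.loc[[2, 3], "mean_present"].dropna()
        assert prof.loc[1, "mean_present"] > others.max()


class TestCodonVariantProfile:
    def test_groups_partition_the_matching_set(self):
        rng = np.random.default_rng(5)
        windows = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(500)]
        table = pd.DataFrame(
            {"variant": windows, "gfp_score": rng.uniform(1, 5, 500)}
        )
        prof = mot.codon_variant_profile(mot.KNYI, table, offset=3)
        n_match = prof.attrs["n_match"]
        slot1 = prof[prof["residue_slot"] == 1]
        assert slot1["n"].sum() == n_match
        assert set(slot1["amino_acid"]) <= {"K", "N"}
        assert set(prof.loc[prof["residue_slot"] == 2, "amino_acid"]) <= {"Y", "I"}

    def test_lysine_codons_partition_k_matches(self):
        table = pd.DataFrame(
            {
                "variant": ["AAAATTCAT", "AAGATTCAT", "AAATACCAT"],
                "gfp_score": [4.0, 4.2, 4.4],
            }
        )
        prof = mot.codon_variant_profile(mot.KNYI, table, offset=3)
        slot1 = prof[prof["residue_slot"] == 1].set_index("codon")
        assert slot1.loc["AAA", "n"] == 2
        assert slot1.loc["AAG", "n"] == 1

    def test_codon_neutral_model_gives_equal_codon_means(self):
        """Under a generative model keyed on the amino-acid motif only,
        synonymous codon groups share the same expected score."""
        from sortramp import scoring, synthetic as syn

        sim = syn.SimConfig(
            n_variants=6000,
            cells_per_library=300_000,
            reads_per_bin=(300_000,) * 5,
            replicate_count=1,
            seed=23,
        )
        exp = syn.simulate_experiment(
            sim, model=syn.ExpressionModel(au_effect_per_nt=0.0)
        )
        scores = scoring.score_pipeline(exp.replicates[0])
        prof = mot.codon_variant_profile(mot.KNYI, scores, offset=3)
        slot1 = prof[(prof["residue_slot"] == 1) & (prof["n"] >= 5)]
        spread = slot1["mean_score"].max() - slot1["mean_score"].min()
        pooled_se = (slot1["sd_score"] / np.sqrt(slot1["n"])).max()
        assert spread < 6 * pooled_se + 0.1


class TestPermutationNull:
    def test_null_pvalues_do_not_flag_signal(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(
            {
                "variant": ["".join(rng.choice(list("ACGT"), 9)) for _ in range(800)],
                "gfp_score": rng.uniform(1, 5, 800),
            }
        )
        pat = mot.MotifPattern.nucleotide("W", anchor_offsets=(1,))
        ps = mot.permutation_null_pvalues(pat, table, 400, 50, 1, seed=0)
        assert (ps > 1e-4).all()
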