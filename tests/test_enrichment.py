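"""NNK library read extraction, frequency tallies and enrichment ratios."""

import numpy as np
import pytest

from splitkin import (
    LibraryDesign,
    aa_frequencies,
    enrichment_ratio,
    extract_variable_codons,
    gen_nnk_reads,
)
from splitkin.synth import AA_ALPHABET

# 10 codons; codons 4 and 5 randomized
TEMPLATE = "ATGGCTAAACCTGGTTGGACTGATGAAGCT"
DESIGN = LibraryDesign(template=TEMPLATE, randomized_codons=[4, 5])


class TestExtraction:
    def test_template_like_read_yields_codons(self):
        read = TEMPLATE[:12] + "GGT" + "TGG" + TEMPLATE[18:]
        codons, reason = extract_variable_codons(read, DESIGN)
        assert reason is None and codons == ["GGT", "TGG"]

    def test_length_mismatch_discarded(self):
        codons, reason = extract_variable_codons(TEMPLATE[:-3], DESIGN)
        assert codons is None and reason == "length_mismatch"

    def test_ambiguous_base_in_randomized_codon(self):
        read = TEMPLATE[:12] + "GNT" + "TGG" + TEMPLATE[18:]
        codons, reason = extract_variable_codons(read, DESIGN)
        assert reason == "ambiguous"

    def test_low_identity_discarded(self):
        read = "T" * len(TEMPLATE)
        codons, reason = extract_variable_codons(read, DESIGN)
        assert reason == "identity"

    def test_low_substitution_error_mostly_passes(self):
        """0.1% per-base substitutions: >= 99% of reads pass the 90% gate."""
        rng = np.random.default_rng(12)
        reads = gen_nnk_reads(TEMPLATE, [4, 5], [{"G": 1.0}, {"W": 1.0}], n=1000, seed=12)
        passed = 0
        for _, seq, _ in reads:
            arr = list(seq)
            for i in range(len(arr)):
                if rng.random() < 0.001:
                    arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
            codons, reason = extract_variable_codons("".join(arr), DESIGN)
            passed += reason is None
        assert passed >= 990


class TestFrequencies:
    def test_hand_counted_fixture(self):
        """10 reads: 7x GGT (Gly) and 3x TGG (Trp) at codon 4."""
        reads = []
        for i in range(10):
            codon = "GGT" if i < 7 else "TGG"
            reads.append(TEMPLATE[:12] + codon + TEMPLATE[15:])
        table = aa_frequencies(reads, DESIGN, round_label="r1")
        assert table.freq.loc[(4, "G"), "r1"] == pytest.approx(0.7)
        assert table.freq.loc[(4, "W"), "r1"] == pytest.approx(0.3)
        assert table.freq.loc[(5, "W"), "r1"] == pytest.approx(1.0)  # template TGG
        assert table.read_counts["r1"] == (10, 10, 0)

    def test_identical_reads_concentrate_frequency(self):
        reads = [TEMPLATE] * 5
        table = aa_frequencies(reads, DESIGN)
        assert table.freq.loc[(4, "G"), "r0"] == 1.0

    def test_counts_partition_total(self):
        reads = [TEMPLATE, TEMPLATE[:-3], TEMPLATE, "A" * len(TEMPLATE)]
        table = aa_frequencies(reads, DESIGN)
        total, used, discarded = table.read_counts["r0"]
        assert total == 4 and used + discarded == total

    def test_frequencies_normalize_per_position(self):
        reads = gen_nnk_reads(TEMPLATE, [4, 5],
                              [{"G": 0.4, "W": 0.3, "K": 0.3}, {"R": 0.5, "S": 0.5}],
                              n=2000, seed=8)
        table = aa_frequencies(reads, DESIGN)
        sums = table.freq.groupby(level="position").sum()
        assert np.allclose(sums.to_numpy(), 1.0, atol=1e-9)

    def test_sampled_frequencies_match_profile(self):
        """Generator-to-counter consistency within 3 binomial SEs at n = 50,000."""
        n = 50_000
        profile = {4: {"G": 0.5, "W": 0.2, "K": 0.2, "*": 0.1}}
        reads = gen_nnk_reads(TEMPLATE, [4], profile, n=n, seed=21)
        table = aa_frequencies(reads, LibraryDesign(TEMPLATE, [4]))
        for aa, p in profile[4].items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(table.freq.loc[(4, aa), "r0"] - p) < 3 * se

    def test_zero_usable_reads_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            aa_frequencies([TEMPLATE[:-3]], DESIGN)


class TestEnrichment:
    def rounds(self, profiles, n=3000, seed=4):
        tables = []
        for i, prof in enumerate(profiles):
            reads = gen_nnk_reads(TEMPLATE, [4, 5], prof, n=n, seed=seed + i)
            tables.append(aa_frequencies(reads, DESIGN, round_label=f"r{i}"))
        return tables

    def test_identical_rounds_give_unit_ratio(self):
        reads = [TEMPLATE] * 20
        t0 = aa_frequencies(reads, DESIGN, "r0")
        t1 = aa_frequencies(reads, DESIGN, "r1")
        ratios = enrichment_ratio([t0, t1])
        assert np.allclose(ratios["r1"], 1.0)

    def test_absent_then_abundant_is_finite(self):
        flat = [{"G": 1.0}, {"W": 1.0}]
        half = [{"G": 0.5, "K": 0.5}, {"W": 1.0}]
        t0 = aa_frequencies([TEMPLATE[:12] + "GGT" + "TGG" + TEMPLATE[18:]] * 10, DESIGN, "r0")
        reads1 = ([TEMPLATE[:12] + "GGT" + "TGG" + TEMPLATE[18:]] * 5
                  + [TEMPLATE[:12] + "AAG" + "TGG" + TEMPLATE[18:]] * 5)
        t1 = aa_frequencies(reads1, DESIGN, "r1")
        ratios = enrichment_ratio([t0, t1], pseudo=1e-3)
        r = ratios.loc[(4, "K"), "r1"]
        assert np.isfinite(r)
        assert r == pytest.approx((0.5 + 1e-3) / 1e-3, rel=1e-9)

    def test_depth_invariance(self):
        """Ratios depend on frequencies, not read counts."""
        prof0 = [{"G": 0.7, "K": 0.3}, {"W": 1.0}]
        prof1 = [{"G": 0.3, "K": 0.7}, {"W": 1.0}]
        r_small = enrichment_ratio(self.rounds([prof0, prof1], n=2000, seed=50))
        r_large = enrichment_ratio(self.rounds([prof0, prof1], n=8000, seed=50))
        a = r_small.loc[(4, "K"), "r1"]
        b = r_large.loc[(4, "K"), "r1"]
        assert a == pytest.approx(b, rel=0.15)  # sampling noise only

    def test_planted_winner_ranks_first(self):
        """A residue driven to dominance ranks first at every planted position."""
        uniform = {aa: 1.0 for aa in AA_ALPHABET if aa != "*"}
        profiles = [
            [dict(uniform), dict(uniform)],
            [{**uniform, "R": 40.0}, {**uniform, "L": 40.0}],
            [{"R": 1.0}, {"L": 1.0}],
        ]
        tables = self.rounds(profiles, n=4000, seed=77)
        ratios = enrichment_ratio(tables)
        for pos, winner in [(4, "R"), (5, "L")]:
            sub = ratios.xs(pos, level="position")["last_over_first"]
            assert sub.idxmax() == winner

    def test_mismatched_designs_rejected(self):
        other = LibraryDesign(template=TEMPLATE, randomized_codons=[3, 5])
        t0 = aa_frequencies([TEMPLATE] * 5, DESIGN, "r0")
        t1 = aa_frequencies([TEMPLATE] * 5, other, "r1")
        with pytest.raises(ValueError, match="design"):
            enrichment_ratio([t0, t1])

    def test_single_round_rejected(self):
        t0 = aa_frequencies([TEMPLATE] * 5, DESIGN, "r0")
        with pytest.raises(ValueError):
            enrichment_ratio(t0)
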