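import numpy as np
import pytest

from erodescan import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AgeModel,
    GenomeLayout,
    ROHParams,
    ROHSegment,
    age_of_length,
    call_roh,
    froh,
    length_of_age,
    window_hit_fractions,
)

from oracles import roh_segments_bruteforce, window_fractions_bruteforce

SMALL = ROHParams(window_snp=20, window_het_max=1, window_missing_max=2,
                  seg_min_snp=10, seg_min_kb=5, density_kb_per_snp=5,
                  gap_max_kb=50)


def random_vector(rng, n_max=500, params=SMALL):
    """Genotypes with planted homozygous stretches, het clusters and gaps."""
    n = int(rng.integers(params.window_snp // 2, n_max))
    calls = rng.choice([HOM_REF, HOM_ALT, HET, MISSING], size=n,
                       p=[0.45, 0.25, 0.25, 0.05]).astype(np.int8)
    for _ in range(rng.integers(0, 4)):  # plant homozygous stretches
        a = int(rng.integers(0, n))
        b = min(n, a + int(rng.integers(10, 200)))
        calls[a:b] = rng.choice([HOM_REF, HOM_ALT], size=b - a)
    gaps = rng.choice([200, 900, 80_000], size=n, p=[0.88, 0.10, 0.02])
    positions = np.cumsum(gaps) + 1
    return calls, positions.astype(np.int64)


class TestWindowHitFractions:
    def test_all_homozygous_gives_fraction_one(self):
        frac = window_hit_fractions(np.full(300, HOM_REF), ROHParams())
        assert np.all(frac == 1.0)

    def test_all_heterozygous_gives_fraction_zero(self):
        frac = window_hit_fractions(np.full(300, HET), ROHParams())
        assert np.all(frac == 0.0)

    def test_short_scaffold_uses_single_truncated_window(self):
        calls = np.full(50, HOM_REF, dtype=np.int8)
        assert np.all(window_hit_fractions(calls, ROHParams()) == 1.0)
        calls[:4] = HET  # 4 hets > window_het_max of 3
        assert np.all(window_hit_fractions(calls, ROHParams()) == 0.0)

    def test_fractions_match_bruteforce_on_fuzzed_vectors(self, rng):
        for _ in range(40):
            calls, _ = random_vector(rng)
            np.testing.assert_allclose(
                window_hit_fractions(calls, SMALL),
                window_fractions_bruteforce(calls, SMALL))


class TestCallRoh:
    def test_all_het_scaffold_yields_no_segments(self):
        pos = np.arange(1, 301) * 750
        assert call_roh(np.full(300, HET), pos, "s") == []

    def test_uniform_homozygous_run_is_one_segment(self):
        # 200 HOM SNPs spanning ~150 kb at 750 bp spacing
        pos = np.arange(1, 201) * 750
        segs = call_roh(np.full(200, HOM_REF), pos, "s", "ind", ROHParams())
        assert len(segs) == 1
        seg = segs[0]
        assert seg.n_snps == 200
        assert seg.length == pos[-1] - pos[0] + 1
        assert 149_000 <= seg.length <= 150_000

    def test_segments_match_direct_scan_oracle_on_fuzzed_vectors(self, rng):
        for _ in range(60):
            calls, pos = random_vector(rng, n_max=800)
            got = [(s.start, s.end, s.n_snps)
                   for s in call_roh(calls, pos, "s", "i", SMALL)]
            assert got == roh_segments_bruteforce(calls, pos, SMALL)

    def test_allele_label_swap_invariance(self, rng):
        for _ in range(20):
            calls, pos = random_vector(rng)
            swapped = calls.copy()
            flip = rng.random(calls.size) < 0.5
            swapped[flip & (calls == HOM_REF)] = HOM_ALT
            swapped[flip & (calls == HOM_ALT)] = HOM_REF
            assert (call_roh(calls, pos, "s", "i", SMALL)
                    == call_roh(swapped, pos, "s", "i", SMALL))

    def test_flipping_hom_to_het_never_extends_roh(self, rng):
        for _ in range(20):
            calls, pos = random_vector(rng)
            total = sum(s.length for s in call_roh(calls, pos, "s", "i", SMALL))
            worse = calls.copy()
            hom_idx = np.flatnonzero((worse == HOM_REF) | (worse == HOM_ALT))
            if hom_idx.size == 0:
                continue
            worse[rng.choice(hom_idx)] = HET
            total2 = sum(s.length for s in call_roh(worse, pos, "s", "i", SMALL))
            assert total2 <= total

    def test_wide_gap_splits_run(self):
        pos = np.concatenate([np.arange(1, 201) * 750,
                              200 * 750 + 2_000_000 + np.arange(1, 201) * 750])
        segs = call_roh(np.full(400, HOM_REF), pos, "s", "i", ROHParams())
        assert len(segs) == 2


class TestAgeOfLength:
    def test_hundred_kb_roh_dates_to_about_850_generations(self):
        assert age_of_length(0.1, 0.6) == pytest.approx(833.333, abs=1e-3)
        assert round(age_of_length(0.1, 0.6) / 50) * 50 == 850

    def test_eight_mb_roh_dates_to_about_10_generations(self):
        assert age_of_length(8, 0.6) == pytest.approx(10.4167, abs=1e-3)
        assert round(age_of_length(8, 0.6) / 5) * 5 == 10

    def test_algebraic_identity_2rl_100(self):
        for r, L in [(0.5, 100), (1.0, 50), (2.5, 20)]:
            assert age_of_length(L, r) == pytest.approx(1.0)

    def test_inverse_relation(self):
        assert length_of_age(age_of_length(3.7, 0.6), 0.6) == pytest.approx(3.7)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            age_of_length(0, 0.6)
        with pytest.raises(ValueError):
            age_of_length(1, -1)


class TestFroh:
    def layout(self):
        return GenomeLayout(scaffolds=(("s", 200_000_000),))

    def test_no_segments_gives_zero(self):
        res = froh([], self.layout(), individual="x")
        assert res.total == 0 and all(v == 0 for v in res.per_bin.values())

    def test_single_recent_segment_arithmetic(self):
        seg = ROHSegment("x", "s", 0, 50_000_000, 60_000)
        res = froh([seg], self.layout())
        assert res.total == pytest.approx(0.25)
        assert res.per_bin["recent"] == pytest.approx(0.25)
        assert res.per_bin["historical"] == 0

    def test_bins_partition_total_exactly(self):
        segs = [ROHSegment("x", "s", 0, 500_000, 600),
                ROHSegment("x", "s", 1_000_000, 4_000_000, 3_000),
                ROHSegment("x", "s", 10_000_000, 20_000_000, 11_000)]
        res = froh(segs, self.layout())
        assert res.total == sum(res.per_bin.values())
        assert res.per_bin["historical"] > 0
        assert res.per_bin["intermediate"] > 0
        assert res.per_bin["recent"] > 0

    def test_zero_analyzable_length_is_configuration_error(self):
        empty = GenomeLayout(scaffolds=(("tiny", 10_000),))
        with pytest.raises(ValueError):
            froh([], empty)


def test_bin_edges_map_to_published_generation_scale():
    am = AgeModel()
    oldest = [am.bin_age_range(i)[1] for i in range(am.n_bins)]
    assert oldest[0] == pytest.approx(833.33, abs=0.01)   # ~850 after rounding
    assert oldest[1] == pytest.approx(41.67, abs=0.01)    # ~45 after rounding
    assert oldest[2] == pytest.approx(10.42, abs=0.01)    # ~10 after rounding
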