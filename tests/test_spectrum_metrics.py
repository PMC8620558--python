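"""Count/frequency metrics, spectra, strand correction, rolling scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from mtspectrum import (
    classify_variants,
    codon_position_metrics,
    genome_scan,
    mutation_count,
    mutation_frequency,
    region_metrics,
    strand_bias_correction,
    substitution_spectrum,
)
from mtspectrum.spectrum_metrics import (
    circular_rolling_mean,
    correction_factors,
    reference_composition_factors,
)
from mtspectrum.variant_io import DepthProfile


def naive_count(variants, length):
    flags = [False] * length
    for v in variants:
        flags[v.pos - 1] = True
    return sum(flags) / length


def naive_frequency(variants, length):
    acc = [0.0] * length
    for v in variants:
        acc[v.pos - 1] += v.allele_fraction
    return sum(acc) / length


class TestCoreMetrics:
    def test_zero_case(self):
        assert mutation_count([], 100) == 0
        assert mutation_frequency([], 100) == 0

    def test_count_distinct_bases(self, call_factory):
        variants = [call_factory(p) for p in (3, 8, 40)]
        assert mutation_count(variants, 100) == pytest.approx(0.03)

    def test_two_alts_at_one_base_count_once(self, call_factory):
        variants = [call_factory(5, "C", "T"), call_factory(5, "C", "A")]
        assert mutation_count(variants, 100) == pytest.approx(0.01)
        assert mutation_count(variants, 100, mode="unique") == pytest.approx(0.02)

    def test_frequency_arithmetic(self, call_factory):
        assert mutation_frequency([call_factory(2, af=0.5)], 4) == pytest.approx(0.125)

    def test_saturated_frequency_equals_count(self, call_factory):
        variants = [call_factory(p, af=1.0) for p in (1, 5, 9)]
        assert mutation_frequency(variants, 20) == mutation_count(variants, 20)

    def test_invalid_length(self, call_factory):
        with pytest.raises(ValueError):
            mutation_count([call_factory(1)], 0)

    def test_matches_naive_oracle_on_random_fixtures(self, call_factory):
        rng = np.random.default_rng(17)
        for _ in range(50):
            length = int(rng.integers(50, 400))
            n = int(rng.integers(0, 120))
            variants = [
                call_factory(int(rng.integers(1, length + 1)),
                             af=round(float(rng.uniform(0.001, 1.0)), 6))
                for _ in range(n)
            ]
            assert abs(mutation_count(variants, length)
                       - naive_count(variants, length)) < 1e-12
            assert abs(mutation_frequency(variants, length)
                       - naive_frequency(variants, length)) < 1e-12

    def test_germline_somatic_frequency_additivity(self, toy_ref, call_factory):
        brain = [call_factory(p, toy_ref.base(p),
                              "T" if toy_ref.base(p) != "T" else "A",
                              af=0.25, tissue="brain") for p in (3, 10, 50, 99)]
        liver = [call_factory(p, toy_ref.base(p),
                              "T" if toy_ref.base(p) != "T" else "A",
                              af=0.4) for p in (10, 50, 200)]
        classified = classify_variants(brain, liver, toy_ref)
        liver_vars = [v for v in classified if v.tissue == "liver"]
        total = mutation_frequency(liver_vars, toy_ref.length)
        parts = sum(
            mutation_frequency([v for v in liver_vars if v.inheritance == lab],
                               toy_ref.length)
            for lab in ("germline", "somatic"))
        assert total == pytest.approx(parts, abs=1e-15)


class TestGroupedMetrics:
    def test_region_denominator(self, toy_ref, call_factory):
        # two SNVs in the 80-bp D-loop (positions 510..589)
        variants = classify_variants(
            [], [call_factory(p, toy_ref.base(p),
                              "A" if toy_ref.base(p) != "A" else "C")
                 for p in (520, 560)], toy_ref)
        row = next(s for s in region_metrics(variants, toy_ref) if s.group == "D-loop")
        assert row.count_metric == pytest.approx(2 / 80)
        empty = next(s for s in region_metrics(variants, toy_ref) if s.group == "rRNA")
        assert empty.count_metric == 0 and empty.frequency_metric == 0

    def test_region_totals_recombine_to_genome_metric(self, toy_ref, call_factory):
        rng = np.random.default_rng(29)
        liver = []
        for _ in range(60):
            pos = int(rng.integers(1, toy_ref.length + 1))
            b = toy_ref.base(pos)
            liver.append(call_factory(pos, b, "A" if b != "A" else "G",
                                      af=round(float(rng.uniform(0.01, 1)), 4)))
        classified = classify_variants([], liver, toy_ref)
        rows = region_metrics(classified, toy_ref)
        lengths = toy_ref.region_lengths()
        recombined = sum(r.count_metric * lengths[r.group] for r in rows)
        assert recombined / toy_ref.length == pytest.approx(
            mutation_count(classified, toy_ref.length), abs=1e-12)

    def test_codon_position_zero_cells(self, toy_ref, call_factory):
        gene = next(f for f in toy_ref.features if f.name == "toyA")
        # third positions of the first two codons: start+2, start+5
        liver = [call_factory(gene.start + off, toy_ref.base(gene.start + off),
                              "A" if toy_ref.base(gene.start + off) != "A" else "G")
                 for off in (2, 5)]
        classified = classify_variants([], liver, toy_ref)
        rows = {s.group: s for s in codon_position_metrics(classified, toy_ref)}
        assert rows["1"].count_metric == 0 and rows["2"].count_metric == 0
        assert rows["3"].n_variants == 2

    def test_spectrum_one_variant_per_class(self, call_factory):
        pairs = [("C", "T"), ("T", "C"), ("C", "A"), ("T", "A"), ("C", "G"), ("T", "G")]
        liver = [call_factory(i + 1, r, a) for i, (r, a) in enumerate(pairs)]
        from mtspectrum import MtReference
        ref = MtReference(name="m", sequence="CTCTCTCTCT", features=[])
        classified = classify_variants([], liver, ref)
        rows = [s for s in substitution_spectrum(classified, 10)
                if s.grouping == "collapsed_class"]
        assert all(s.n_variants == 1 for s in rows)
        assert sum(s.n_variants for s in rows) == 6

    def test_spectrum_conservation(self, toy_ref, call_factory):
        rng = np.random.default_rng(31)
        liver = []
        for _ in range(40):
            pos = int(rng.integers(1, toy_ref.length + 1))
            b = toy_ref.base(pos)
            alt = rng.choice([x for x in "ACGT" if x != b])
            liver.append(call_factory(pos, b, str(alt)))
        classified = classify_variants([], liver, toy_ref)
        rows = [s for s in substitution_spectrum(classified, toy_ref.length)
                if s.grouping == "collapsed_class"]
        assert sum(s.n_variants for s in rows) == 40


class TestStrandCorrection:
    def _uniform_profile(self, ref, depth=100.0):
        return DepthProfile.from_array("A", "liver", np.full(ref.length, depth), ref)

    def test_equal_totals_identity(self):
        profile = DepthProfile("A", "liver", np.array([]),
                               {b: 1000.0 for b in "ACGT"})
        raw = {"C>T": 30.0, "G>A": 30.0, "T>C": 10.0}
        assert strand_bias_correction(raw, depth=profile) == raw

    def test_c_twice_g_doubles_g_sourced_counts(self):
        profile = DepthProfile("A", "liver", np.array([]),
                               {"A": 500.0, "C": 800.0, "G": 400.0, "T": 500.0})
        corrected = strand_bias_correction({"G>A": 10.0, "C>T": 10.0}, depth=profile)
        assert corrected["G>A"] == pytest.approx(20.0)
        assert corrected["C>T"] == pytest.approx(10.0)

    def test_cytosine_factor_exactly_one(self, toy_ref):
        factors = correction_factors(self._uniform_profile(toy_ref))
        assert factors["C"] == 1.0
        assert reference_composition_factors(toy_ref)["C"] == 1.0

    def test_uniform_depth_factors_match_composition(self, toy_ref):
        depth_factors = correction_factors(self._uniform_profile(toy_ref))
        comp_factors = reference_composition_factors(toy_ref)
        for base in "ACGT":
            assert depth_factors[base] == pytest.approx(comp_factors[base])

    def test_zero_depth_base_errors(self):
        profile = DepthProfile("A", "liver", np.array([]),
                               {"A": 10.0, "C": 10.0, "G": 0.0, "T": 10.0})
        with pytest.raises(ValueError, match="G"):
            strand_bias_correction({"G>A": 5.0}, depth=profile)


class TestGenomeScan:
    def test_per_base_averaging_of_multiple_alts(self, toy_ref, call_factory):
        variants = [call_factory(5, "C", "T", af=0.2), call_factory(5, "C", "A", af=0.4)]
        scan = genome_scan(variants, toy_ref, window_bp=1)
        assert scan.frequency[4] == pytest.approx(0.3)
        assert scan.count[4] == 1.0

    def test_normalized_track_max_is_one(self, toy_ref, call_factory):
        scan = genome_scan([call_factory(100, "C", "T", af=0.8)], toy_ref,
                           window_bp=25)
        assert scan.frequency_normalized.max() == pytest.approx(1.0)
        assert scan.count_normalized.max() == pytest.approx(1.0)

    def test_empty_scan_stays_zero(self, toy_ref):
        scan = genome_scan([], toy_ref, window_bp=25)
        assert scan.frequency_normalized.max() == 0.0

    def test_rolling_mean_matches_naive_circular_oracle(self):
        rng = np.random.default_rng(41)
        values = rng.uniform(0, 1, 173)
        for window in (1, 2, 5, 25):
            rolled = circular_rolling_mean(values, window)
            left = window // 2
            n = len(values)
            naive = np.array([
                np.mean([values[(i - left + j) % n] for j in range(window)])
                for i in range(n)
            ])
            assert np.max(np.abs(rolled - naive)) < 1e-12

    def test_window_larger_than_genome_rejected(self):
        with pytest.raises(ValueError):
            circular_rolling_mean(np.zeros(10), 11)

    def test_bedgraph_output(self, toy_ref, call_factory, tmp_path):
        scan = genome_scan([call_factory(10, "C", "T", af=0.5)], toy_ref, window_bp=5)
        path = tmp_path / "scan.bedgraph"
        from mtspectrum.spectrum_metrics import write_bedgraph
        write_bedgraph(scan, "toy_mt", path)
        lines = path.read_text().splitlines()
        assert len(lines) == toy_ref.length
        assert lines[0].split("\t")[:3] == ["toy_mt", "0", "1"]


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    n=hst.integers(10, 60),
    window=hst.integers(1, 10),
    seed=hst.integers(0, 1000),
)
def test_rolling_mean_preserves_total_mass(n, window, seed):
    rng = np.random.default_rng(seed)
    values = rng.uniform(0, 1, n)
    rolled = circular_rolling_mean(values, window)
    # circular smoothing redistributes but conserves the mean
    assert np.mean(rolled) == pytest.approx(np.mean(values), abs=1e-12)
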