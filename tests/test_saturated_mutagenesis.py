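import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edscan.genomic_io import Genome, GenomicInterval
from edscan.saturated_mutagenesis import (
    EDProfile,
    EDRegion,
    call_ed_regions,
    correlate_ed_with_annotation,
    rank_regions_by_mean_ed,
    saturated_mutagenesis,
    write_profile,
    write_regions_bed,
)

MOTIF = "ACGTACGT"


def motif_oracle(seq: str) -> float:
    """Analytic oracle: high probability iff the window contains MOTIF."""
    return 0.9 if MOTIF in seq else 0.1


def random_background_without_motif(seed0: int, length: int = 2000) -> str:
    """Random sequence free of accidental MOTIF copies (rejection sampled)."""
    bases = np.array(list("ACGT"))
    for seed in range(seed0, seed0 + 50):
        seq = "".join(np.random.default_rng(seed).choice(bases, size=length))
        if MOTIF not in seq:
            return seq
    raise AssertionError("could not sample a motif-free background")


@pytest.fixture(scope="module")
def motif_genome():
    seq = random_background_without_motif(123)
    seq = seq[:996] + MOTIF + seq[1004:]
    assert seq.count(MOTIF) == 1
    return Genome({"c": seq})


def brute_force_profile(oracle, seq):
    """Independent enumeration of all 3L substitutions."""
    p_ref = oracle(seq)
    ed = np.zeros(len(seq))
    for i, ref in enumerate(seq):
        alts = [b for b in "ACGT" if b != ref]
        vals = [oracle(seq[:i] + b + seq[i + 1 :]) for b in alts]
        ed[i] = p_ref - float(np.mean(vals))
    return p_ref, ed


class TestOracleEquivalence:
    def test_exact_match_with_brute_force(self, motif_genome):
        window = GenomicInterval("c", 0, 2000)
        profile = saturated_mutagenesis(motif_oracle, motif_genome, window)
        p_ref, ed = brute_force_profile(motif_oracle, motif_genome["c"])
        assert profile.p_ref == p_ref
        assert np.max(np.abs(profile.ed - ed)) <= 1e-12

    def test_motif_positions_have_expected_ed(self, motif_genome):
        window = GenomicInterval("c", 0, 2000)
        profile = saturated_mutagenesis(motif_oracle, motif_genome, window)
        inside = profile.ed[996:1004]
        # destroying the only copy at any of its 8 positions: ed = 0.8
        assert np.allclose(inside, 0.8, atol=1e-12)
        outside = np.concatenate([profile.ed[:996], profile.ed[1004:]])
        assert np.allclose(outside, 0.0, atol=1e-12)

    def test_constant_oracle_zero_profile(self, motif_genome):
        profile = saturated_mutagenesis(
            lambda s: 0.42, motif_genome, GenomicInterval("c", 0, 2000)
        )
        assert np.all(profile.ed == 0.0)

    def test_out_of_range_oracle_rejected(self, motif_genome):
        with pytest.raises(ValueError):
            saturated_mutagenesis(
                lambda s: 1.5, motif_genome, GenomicInterval("c", 0, 2000)
            )

    def test_n_positions_masked(self):
        genome = Genome({"c": "N" * 4 + "ACGT" * 499})
        profile = saturated_mutagenesis(
            lambda s: 0.5, genome, GenomicInterval("c", 0, 2000)
        )
        assert profile.mask[:4].all() and not profile.mask[4:].any()
        assert np.all(profile.ed[:4] == 0.0)


def _profile_from(ed, chrom="c", start=0):
    ed = np.asarray(ed, dtype=float)
    return EDProfile(
        interval=GenomicInterval(chrom, start, start + len(ed)),
        ref_sequence="A" * len(ed),
        p_ref=0.5,
        alt_probs=np.full((len(ed), 3), 0.5),
        ed=ed,
        mask=np.zeros(len(ed), dtype=bool),
    )


class TestCallRegions:
    def test_single_run(self):
        ed = [0.0] * 5 + [2.0, 2.0, 2.0] + [0.0] * 5
        regions = call_ed_regions(_profile_from(ed), tau_sd=1.0, sigma_mode="full")
        assert len(regions) == 1
        r = regions[0]
        assert r.kind == "EDR" and (r.interval.start, r.interval.end) == (5, 8)
        assert r.mean_ed == pytest.approx(2.0) and r.length == 3

    def test_min_length_three(self):
        ed = [0.0] * 6 + [2.0, 2.0] + [0.0] * 6
        assert call_ed_regions(_profile_from(ed), tau_sd=1.0, sigma_mode="full") == []

    def test_negation_swaps_kinds(self, rng):
        ed = rng.standard_normal(500)
        a = call_ed_regions(_profile_from(ed), tau_sd=1.5)
        b = call_ed_regions(_profile_from(-ed), tau_sd=1.5)
        flip = {"EDR": "ESR", "ESR": "EDR"}
        assert [(r.interval.start, r.interval.end, flip[r.kind]) for r in a] == [
            (r.interval.start, r.interval.end, r.kind) for r in b
        ]

    def test_zero_variance_profile(self):
        assert call_ed_regions(_profile_from([0.0] * 100)) == []

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_region_invariants_random_profiles(self, seed):
        r = np.random.default_rng(seed)
        ed = r.standard_normal(r.integers(20, 400))
        regions = call_ed_regions(_profile_from(ed), tau_sd=1.0)
        for reg in regions:
            assert reg.length >= 3
            assert (reg.mean_ed > 0) == (reg.kind == "EDR")
        # same-kind regions disjoint and sorted
        for kind in ("EDR", "ESR"):
            ks = [reg for reg in regions if reg.kind == kind]
            for a, b in zip(ks, ks[1:]):
                assert a.interval.end <= b.interval.start

    def test_gap_merging_option(self):
        ed = [0.0] * 5 + [3.0] * 3 + [0.0] + [3.0] * 3 + [0.0] * 5
        merged = call_ed_regions(_profile_from(ed), tau_sd=1.0, gap=1, sigma_mode="full")
        assert len(merged) == 1 and merged[0].length == 7


class TestRanking:
    def _regions(self, n):
        out = []
        for i in range(n):
            out.append(
                EDRegion(
                    interval=GenomicInterval("c", 10 * i, 10 * i + 5),
                    kind="EDR", mean_ed=float(i + 1), peak_ed=float(i + 1), length=5,
                )
            )
        return out

    def test_even_bins(self):
        bins = rank_regions_by_mean_ed(self._regions(10), n_bins=5)
        assert [len(b) for b in bins] == [2] * 5
        assert bins[0][0].mean_ed == 10.0  # strongest first

    def test_tie_broken_by_coordinate(self):
        regions = self._regions(4)
        for r in regions:
            object.__setattr__(r, "mean_ed", 1.0)
        bins = rank_regions_by_mean_ed(regions, n_bins=2)
        starts = [r.interval.start for b in bins for r in b]
        assert starts == sorted(starts)

    def test_top_percent(self):
        top = rank_regions_by_mean_ed(self._regions(1000), top_percent=2.0)
        assert len(top) == 20

    def test_too_few_regions(self):
        with pytest.raises(ValueError):
            rank_regions_by_mean_ed(self._regions(3), n_bins=5)


class TestCorrelation:
    class _Inst:
        def __init__(self, interval):
            self.interval = interval

    def test_identical_annotation_rho_one(self):
        ed = np.abs(np.random.default_rng(0).standard_normal(50))
        profile = _profile_from(ed)
        inst = self._Inst(GenomicInterval("c", 10, 20))
        rhos = correlate_ed_with_annotation(
            [profile], [inst], lambda m: ed[10:20]
        )
        assert rhos == [pytest.approx(1.0)]

    def test_reversed_annotation_rho_minus_one(self):
        ed = np.arange(50, dtype=float)
        profile = _profile_from(ed)
        inst = self._Inst(GenomicInterval("c", 5, 15))
        rhos = correlate_ed_with_annotation(
            [profile], [inst], lambda m: -ed[5:15]
        )
        assert rhos == [pytest.approx(-1.0)]

    def test_short_motif_skipped(self):
        profile = _profile_from(np.arange(50, dtype=float))
        inst = self._Inst(GenomicInterval("c", 5, 7))
        assert correlate_ed_with_annotation([profile], [inst], lambda m: [1, 2]) == []


def test_profile_serialization(tmp_path):
    profile = _profile_from(np.linspace(-1, 1, 10), chrom="chr1", start=100)
    write_profile(profile, tmp_path / "p")
    lines = (tmp_path / "p.bedgraph").read_text().splitlines()
    assert len(lines) == 10
    chrom, s, e, v = lines[0].split("\t")
    assert (chrom, int(s), int(e)) == ("chr1", 100, 101)
    assert float(v) == pytest.approx(-1.0)

    regions = call_ed_regions(profile, tau_sd=1.0)
    write_regions_bed(regions, tmp_path / "r.bed")
    assert (tmp_path / "r.bed").exists()
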