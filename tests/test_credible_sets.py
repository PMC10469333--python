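import math

import numpy as np
import pytest
from scipy import stats as sps

from edscan.credible_set_prioritization import (
    CredibleSet,
    calibrate_ratio_threshold,
    credible_vs_ld_enrichment,
    ed_overlap_enrichment,
    iep_ratio,
    prioritize,
    read_credible_sets,
)
from edscan.genomic_io import GenomicInterval, SNPRecord
from edscan.saturated_mutagenesis import EDRegion


def _snp(i, pos=None):
    import zlib

    if pos is None:
        pos = 1000 + zlib.crc32(str(i).encode()) % 10**6
    return SNPRecord(f"rs{i}", "chr1", pos, "A", "C")


def _set(signal_id, scores, trait="t"):
    entries = [(_snp(f"{signal_id}_{i}"), 0.1) for i in range(len(scores))]
    table = {e[0].id: s for e, s in zip(entries, scores)}
    return CredibleSet(signal_id, trait, entries), table


class TestIepRatio:
    def test_arithmetic(self):
        cs, table = _set("s1", [0.50, 0.02, 0.01])
        res = iep_ratio(cs, table)
        assert res.iep_ratio_1_2 == pytest.approx(25.0)
        assert table[res.top_snp.id] == 0.50

    def test_single_snp_sentinel(self):
        cs, table = _set("s1", [0.5])
        res = iep_ratio(cs, table)
        assert math.isinf(res.iep_ratio_1_2) and res.flag == "single-SNP set"

    def test_tie_gives_one(self):
        cs, table = _set("s1", [0.4, 0.4, 0.1])
        res = iep_ratio(cs, table)
        assert res.iep_ratio_1_2 == 1.0

    def test_negligible_runner_up(self):
        cs, table = _set("s1", [0.5, 1e-12])
        res = iep_ratio(cs, table)
        assert math.isinf(res.iep_ratio_1_2) and res.flag == "negligible runner-up"

    def test_unscored_snp_named(self):
        cs, table = _set("s1", [0.5, 0.1])
        del table["rss1_1"]
        with pytest.raises(KeyError, match="rss1_1"):
            iep_ratio(cs, table)


class TestPrioritize:
    def test_summary_counts(self):
        cs1, t1 = _set("s1", [0.30, 0.01])         # ratio 30 -> resolved
        cs2, t2 = _set("s2", [0.10, 0.01])         # ratio 10 -> not
        cs3, t3 = _set("s3", [0.50])               # single-SNP
        table = {**t1, **t2, **t3}
        results, summary = prioritize([cs1, cs2, cs3], table, ratio_threshold=24)
        assert summary["n_newly_resolved"] == 1
        assert summary["n_single_snp_before"] == 1
        assert summary["n_signals"] == 3

    def test_shared_top_snp_deduplicated(self):
        shared = _snp("shared", pos=5000)
        def mk(sid, trait):
            entries = [(shared, 0.5), (_snp(f"{sid}_b", pos=6000 + len(sid)), 0.5)]
            return CredibleSet(sid, trait, entries)
        table = {"rsshared": 0.9, "rss1_b": 0.01, "rss2_b": 0.01}
        _, summary = prioritize([mk("s1", "t1"), mk("s2", "t2")], table, 24)
        assert summary["n_newly_resolved"] == 2
        assert summary["n_unique_resolved_snps"] == 1

    def test_order_invariance(self):
        entries = [(_snp("a", 10_000), 0.3), (_snp("b", 20_000), 0.3), (_snp("c", 30_000), 0.4)]
        table = {"rsa": 0.5, "rsb": 0.01, "rsc": 0.02}
        r1 = iep_ratio(CredibleSet("s", "t", entries), table)
        r2 = iep_ratio(CredibleSet("s", "t", entries[::-1]), table)
        assert r1.top_snp == r2.top_snp
        assert r1.iep_ratio_1_2 == r2.iep_ratio_1_2

    def test_resolved_count_monotone_in_threshold(self):
        sets, table = [], {}
        for i, r in enumerate([2, 5, 10, 30, 100]):
            cs, t = _set(f"s{i}", [r * 0.001, 0.001])
            sets.append(cs); table.update(t)
        counts = []
        for thr in (2, 4, 8, 16, 32):
            _, summary = prioritize(sets, table, ratio_threshold=thr)
            counts.append(summary["n_newly_resolved"])
        assert counts == sorted(counts, reverse=True)

    def test_threshold_must_exceed_one(self):
        cs, table = _set("s1", [0.5, 0.1])
        with pytest.raises(ValueError):
            prioritize([cs], table, ratio_threshold=1.0)


class TestCalibration:
    def test_perfect_truth_small_p(self):
        """10 sets of size 10, truth always top: p matches brute force."""
        sets, table, truth = [], {}, {}
        for i in range(10):
            scores = [0.5] + [0.001 * (j + 1) for j in range(9)]
            cs, t = _set(f"s{i}", scores)
            sets.append(cs); table.update(t)
            truth[f"s{i}"] = f"rss{i}_0"
        thr, scan = calibrate_ratio_threshold(sets, truth, table, grid=[2.0, 4.0])
        assert thr == 2.0
        row = scan[scan.threshold == 2.0].iloc[0]
        # brute-force hypergeometric tail: N=100, K=10, n=10, k=10
        expected = sps.hypergeom.sf(9, 100, 10, 10)
        assert row.p == pytest.approx(expected, rel=1e-9)
        assert row.n_correct == 10

    def test_truth_never_matched(self):
        sets, table, truth = [], {}, {}
        for i in range(5):
            cs, t = _set(f"s{i}", [0.5, 0.001])
            sets.append(cs); table.update(t)
            truth[f"s{i}"] = f"rss{i}_1"  # the low-score SNP
        thr, scan = calibrate_ratio_threshold(sets, truth, table, grid=[2.0])
        assert thr is None
        assert (scan.n_correct == 0).all()

    def test_empty_truth_rejected(self):
        cs, table = _set("s1", [0.5, 0.1])
        with pytest.raises(ValueError):
            calibrate_ratio_threshold([cs], {}, table)


class TestEdOverlapEnrichment:
    def _region(self, start, end):
        return EDRegion(GenomicInterval("chr1", start, end), "EDR", 1.0, 1.0, end - start)

    def test_closed_form_binomial(self):
        regions = [self._region(0, 100_000)]  # covers candidates only
        candidates = [_snp(f"c{i}", pos=1000 + i) for i in range(20)]
        background = [_snp(f"b{i}", pos=200_000 + i) for i in range(300)]
        background += candidates[:5]  # give background a small overlap rate
        res = ed_overlap_enrichment(candidates, background, regions, n_draws=5000, seed=0)
        assert res["candidate_rate"] == 1.0
        assert res["fold"] == pytest.approx(1.0 / res["background_rate"])
        expected_p = sps.binom.sf(19, 20, res["background_rate"])
        assert res["p_binomial"] == pytest.approx(expected_p, rel=1e-9)

    def test_equal_rates_fold_one(self):
        regions = [self._region(0, 1_000_000)]
        candidates = [_snp(f"c{i}", pos=1000 + i) for i in range(10)]
        background = [_snp(f"b{i}", pos=5000 + i) for i in range(100)]
        res = ed_overlap_enrichment(candidates, background, regions, n_draws=1000, seed=0)
        assert res["fold"] == pytest.approx(1.0)
        assert res["p_binomial"] > 0.5

    def test_small_background_rejected(self):
        candidates = [_snp(f"c{i}") for i in range(10)]
        with pytest.raises(ValueError):
            ed_overlap_enrichment(candidates, candidates, [], seed=0)


class TestCredibleVsLd:
    def test_separated_groups_rank_mode(self):
        cred = [f"c{i}" for i in range(50)]
        ld = [f"l{i}" for i in range(50)]
        table = {**{c: 1.0 + i for i, c in enumerate(cred)},
                 **{l: 0.001 * (i + 1) for i, l in enumerate(ld)}}
        res = credible_vs_ld_enrichment(cred, ld, table, mode="rank", n_boot=20, seed=0)
        assert res["wilcoxon_p"] < 1e-6
        assert res["rank_auc"] == 1.0

    def test_identical_distributions_threshold_mode(self):
        cred = [f"c{i}" for i in range(200)]
        ld = [f"l{i}" for i in range(200)]
        rng = np.random.default_rng(0)
        vals = rng.random(400)
        table = {**dict(zip(cred, vals[:200])), **dict(zip(ld, vals[200:]))}
        res = credible_vs_ld_enrichment(
            cred, ld, table, mode="threshold", cutoffs=[0.25, 0.5], n_boot=100, seed=1
        )
        for c in res["curves"]:
            assert abs(c["fold"] - 1.0) < 4 * max(c["se"], 0.05)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            credible_vs_ld_enrichment(["a"], ["a"], {"a": 1.0})


def test_read_credible_sets_round_trip(tmp_path, tiny_regulome):
    from edscan import synthetic_regulome as sr

    cfg, genome, truth = tiny_regulome
    sr.write_snp_files(truth, tmp_path)
    sets = read_credible_sets(tmp_path / "credible_sets.tsv")
    assert len(sets) == len(truth.signals)
    by_id = {s.signal_id: s for s in sets}
    for sig in truth.signals:
        cs = by_id[sig.signal_id]
        assert sorted(s.id for s in cs.snps) == sorted(sig.snp_ids)
        for snp, ppa in cs.entries:
            assert ppa == pytest.approx(truth.ppa[sig.signal_id][snp.id], abs=1e-6)
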