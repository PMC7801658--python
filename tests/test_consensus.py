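"""Variant calling, normalization, voting, tie-breaking, application."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from popref.align import align_genomes, select_primary
from popref.consensus import (CoordinateMap, VariantRecord, apply_variants,
                              break_ties, call_variants, expected_tie_errors,
                              normalize_variant, normalize_variants,
                              split_multiallelic, support_summary,
                              vote_major_alleles, TieSite)
from popref.io import AFPanel, AFPanelSite, Assembly
from popref.simulate import random_sequence, substream

from oracles import leftmost_equivalent


def _asm(seq, name="bb"):
    return Assembly(name, {"c": seq})


def _v(pos, ref, alt, support=(), **kw):
    return VariantRecord(contig="c", pos=pos, ref=ref, alt=alt,
                         support=set(support), **kw)


class TestCallVariants:
    def _block(self, ops, tlen, backbone):
        from popref.align import AlignmentBlock
        from popref.io import GenomeInterval

        qspan = sum(n for k, n, _ in ops if k in ("match", "sub", "ins"))
        b = AlignmentBlock(
            query=GenomeInterval("q", 0, qspan),
            target=GenomeInterval("c", 0, tlen), strand="+", ops=ops)
        b.validate()
        return b

    def test_snv_from_sub(self):
        bb = _asm("ACGT")
        blk = self._block([("match", 2, None), ("sub", 1, "T"),
                           ("match", 1, None)], 4, bb)
        (v,) = call_variants([blk], bb, "hap1")
        assert (v.pos, v.ref, v.alt, v.vtype) == (3, "G", "T", "SNV")
        assert v.support == {"hap1"}

    def test_sv_threshold_boundary(self):
        # a 60-bp insertion is an SV, a 50-bp deletion is not (51-bp cut)
        seq = random_sequence(substream(0, "x"), 200)
        bb = _asm(seq)
        ins = "A" * 60
        blk = self._block([("match", 100, None), ("ins", 60, ins),
                           ("match", 100, None)], 200, bb)
        (v,) = call_variants([blk], bb, "h")
        assert v.sv and v.vtype == "INS"
        blk2 = self._block([("match", 100, None), ("del", 50, seq[100:150]),
                            ("match", 50, None)], 200, bb)
        (v2,) = call_variants([blk2], bb, "h")
        assert not v2.sv and v2.vtype == "DEL"
        blk3 = self._block([("match", 100, None), ("del", 51, seq[100:151]),
                            ("match", 49, None)], 200, bb)
        (v3,) = call_variants([blk3], bb, "h")
        assert v3.sv

    def test_del_ref_mismatch_rejected(self):
        bb = _asm("ACGTACGT")
        blk = self._block([("match", 2, None), ("del", 2, "TT"),
                           ("match", 4, None)], 8, bb)
        with pytest.raises(ValueError, match="mismatch"):
            call_variants([blk], bb, "h")


class TestNormalization:
    def test_deletion_left_aligned_in_homopolymer(self):
        bb = _asm("GCAAAAT")
        # delete one A, represented mid-run: pos 4 'AA'->'A'
        v = normalize_variant(_v(4, "AA", "A"), bb)
        assert (v.pos, v.ref, v.alt) == (2, "CA", "C")

    def test_snv_unchanged(self):
        bb = _asm("GCAAAAT")
        v = normalize_variant(_v(3, "A", "T"), bb)
        assert (v.pos, v.ref, v.alt) == (3, "A", "T")

    def test_idempotent(self):
        bb = _asm("GCAAAATTTTGGC")
        for raw in [_v(4, "AA", "A"), _v(8, "T", "TTT"), _v(12, "G", "C")]:
            once = normalize_variant(raw, bb)
            twice = normalize_variant(once, bb)
            assert once.key() == twice.key()

    def test_bruteforce_leftmost_oracle(self):
        # oracle: enumerate every anchored parsimonious (pos, ref, alt)
        # producing the same haplotype; normalization must pick the leftmost
        rng = substream(42, "norm")
        seq = random_sequence(rng, 300)
        # inject homopolymer/repeat tracts to make shifting non-trivial
        seq = seq[:50] + "AAAAAA" + seq[50:120] + "ATATATAT" + seq[120:]
        bb = _asm(seq)
        n_checked = 0
        for _ in range(300):
            pos0 = int(rng.integers(30, len(seq) - 40))
            if rng.random() < 0.5:
                ln = int(rng.integers(1, 6))
                ref = seq[pos0:pos0 + 1 + ln]
                alt = ref[0]
            else:
                ln = int(rng.integers(1, 6))
                ref = seq[pos0]
                alt = ref + random_sequence(rng, ln)
            raw = _v(pos0 + 1, ref, alt)
            got = normalize_variant(raw, bb)
            hap = seq[:pos0] + alt + seq[pos0 + len(ref):]
            oracle = leftmost_equivalent(seq, hap, pos0, len(ref), len(alt))
            assert (got.pos, got.ref, got.alt) == oracle
            n_checked += 1
        assert n_checked == 300


class TestMultiallelic:
    def test_identical_alleles_merge_support(self):
        recs, registry = split_multiallelic(
            [_v(5, "A", "G", {"a"}), _v(5, "A", "G", {"b"})])
        assert len(recs) == 1 and recs[0].support == {"a", "b"}
        assert registry == {}

    def test_distinct_alts_registered(self):
        recs, registry = split_multiallelic(
            [_v(5, "A", "G", {"a"}), _v(5, "A", "T", {"b"})])
        assert len(recs) == 2
        assert registry == {("c", 5): [("A", "G"), ("A", "T")]}

    def test_different_length_insertions_stay_distinct(self):
        # +A vs +AA at the same anchor: the normalization oracle confirms
        # they are different alleles, so both survive as separate records
        bb = _asm("GGTCCA")
        a = normalize_variant(_v(3, "T", "TA"), bb)
        b = normalize_variant(_v(3, "T", "TAA"), bb)
        assert a.key() != b.key()
        recs, registry = split_multiallelic([a, b])
        assert len(recs) == 2 and len(registry) == 1


class TestVote:
    def test_two_of_three_is_major(self):
        res = vote_major_alleles({
            "a": [_v(5, "A", "G")], "b": [_v(5, "A", "G")], "c": []},
            n_assemblies=3)
        assert len(res.major) == 1
        assert res.major[0].alt == "G" and res.major[0].support == {"a", "b"}

    def test_split_vote_is_tie_with_backbone_candidate(self):
        res = vote_major_alleles({
            "a": [_v(5, "A", "G")], "b": [_v(5, "A", "T")], "c": []},
            n_assemblies=3)
        assert not res.major and len(res.ties) == 1
        assert res.ties[0].candidates == [("A", "A"), ("A", "G"), ("A", "T")]

    def test_triallelic_three_candidates(self):
        res = vote_major_alleles({
            "a": [_v(5, "A", "G")], "b": [_v(5, "A", "T")],
            "c": [_v(5, "A", "C")]}, n_assemblies=3)
        assert len(res.ties) == 1
        assert res.ties[0].candidates == [("A", "C"), ("A", "G"), ("A", "T")]

    def test_singleton_keeps_backbone(self):
        res = vote_major_alleles({
            "a": [_v(5, "A", "G")], "b": [], "c": []}, n_assemblies=3)
        assert not res.major and not res.ties and len(res.dropped) == 1

    def test_min_share_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            vote_major_alleles({"a": []}, n_assemblies=1, min_share=2)

    def test_vote_order_invariant(self):
        sets = {"a": [_v(5, "A", "G"), _v(9, "T", "C")],
                "b": [_v(5, "A", "G")], "c": [_v(9, "T", "C")]}
        r1 = vote_major_alleles(dict(sets), n_assemblies=3)
        r2 = vote_major_alleles(dict(reversed(list(sets.items()))),
                                n_assemblies=3)
        assert [v.key() for v in r1.major] == [v.key() for v in r2.major]


class TestBreakTies:
    def _sites(self, n):
        return [TieSite("c", i + 1, [("A", "G"), ("A", "T"), ("A", "C")], {})
                for i in range(n)]

    def test_same_seed_same_output(self):
        s = self._sites(50)
        c1, log1 = break_ties(s, seed=7)
        c2, log2 = break_ties(s, seed=7)
        assert [v.key() for v in c1] == [v.key() for v in c2]
        assert log1.equals(log2)

    def test_uniform_over_candidates(self):
        # 10,000 draws over a 3-candidate site; chi-square at alpha=0.01
        counts = {"C": 0, "G": 0, "T": 0}
        for seed in range(10_000):
            chosen, _ = break_ties(self._sites(1), seed=seed)
            counts[chosen[0].alt] += 1
        stat, p = sps.chisquare(list(counts.values()))
        assert p > 0.01

    def test_single_candidate_still_flagged(self):
        site = TieSite("c", 1, [("A", "G")], {})
        chosen, log = break_ties([site], seed=0)
        assert chosen[0].tie and chosen[0].alt == "G"

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            break_ties([TieSite("c", 1, [], {})], seed=0)

    def test_seed_required(self):
        with pytest.raises(ValueError):
            break_ties(self._sites(1), seed=None)


class TestApplyVariants:
    def test_snv_substitution(self):
        bb = _asm("AAAA")
        cons, cmap, dropped = apply_variants(bb, [_v(2, "A", "G")])
        assert cons.sequences["c"] == "AGAA"
        assert dropped.empty

    def test_insertion_shifts_coordinates(self):
        seq = random_sequence(substream(1, "y"), 40)
        bb = _asm(seq)
        v = _v(10, seq[9], seq[9] + "GG")
        cons, cmap, _ = apply_variants(bb, [v])
        assert len(cons.sequences["c"]) == 42
        for pos in (10, 20, 39):  # 0-based positions at/after the insertion
            assert cmap.map_point("c", pos) == pos + 2
        assert cmap.map_point("c", 5) == 5

    def test_overlap_first_wins_with_report(self):
        bb = _asm("ACGTACGT")
        d = _v(2, "CGT", "C")      # deletion at pos 2
        s = _v(3, "G", "T")        # SNV inside the deleted span
        cons, cmap, dropped = apply_variants(bb, [d, s])
        assert cons.sequences["c"] == "ACACGT"
        assert len(dropped) == 1 and dropped.iloc[0]["reason"] == "overlaps_previous"

    def test_length_budget(self, tiny_truth, tiny_haploids):
        _, car = tiny_haploids["hap_c"]
        variants = [e.variant for e in car]
        cons, cmap, _ = apply_variants(tiny_truth.ancestral, variants)
        delta = sum(len(v.alt) - len(v.ref) for v in variants)
        assert cons.total_length() - tiny_truth.ancestral.total_length() == delta

    def test_roundtrip_recovers_applied_set(self, tiny_truth, tiny_haploids):
        # the module's central oracle at tiny scale
        _, car = tiny_haploids["hap_b"]
        applied = [e.variant for e in car]
        cons, _, _ = apply_variants(tiny_truth.ancestral, applied)
        blocks = select_primary(align_genomes(cons, tiny_truth.ancestral))
        called = normalize_variants(
            call_variants(blocks, tiny_truth.ancestral, "cons"),
            tiny_truth.ancestral)
        assert sorted(v.key() for v in called) == sorted(v.key() for v in applied)


class TestSupportSummary:
    def test_share_percentages_from_counts(self):
        # published SNV support counts: 1,176,922 of 2,501,575 in all three
        # donors (47%), 1,204,762 in two (48%)
        counts = {3: 1_176_922, 2: 1_204_762,
                  1: 2_501_575 - 1_176_922 - 1_204_762}
        df = support_summary(counts, n_assemblies=3)
        assert round(float(df.loc[df.support == 3, "pct"].iloc[0])) == 47
        assert round(float(df.loc[df.support == 2, "pct"].iloc[0])) == 48

    def test_all_support_three(self):
        df = support_summary({3: 10}, n_assemblies=3)
        assert float(df.loc[df.support == 3, "pct"].iloc[0]) == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            support_summary({}, n_assemblies=3)


class TestExpectedTieErrors:
    def _panel(self):
        return AFPanel([AFPanelSite("c", 1, "A", "G", 0.9),
                        AFPanelSite("c", 2, "A", "G", 0.1)])

    def test_panel_major_among_candidates(self):
        site = TieSite("c", 1, [("A", "G"), ("A", "T"), ("A", "C")], {})
        total, df = expected_tie_errors([site], self._panel())
        assert total == pytest.approx(2 / 3)

    def test_panel_major_absent(self):
        # af 0.1 means the panel-major allele is the ref A; candidates
        # lacking A give p_err = 1
        site = TieSite("c", 2, [("A", "G"), ("A", "T")], {})
        total, _ = expected_tie_errors([site], self._panel())
        assert total == 1.0

    def test_absent_site_excluded(self):
        site = TieSite("c", 99, [("A", "G")], {})
        total, df = expected_tie_errors([site], self._panel())
        assert total == 0.0 and df.attrs["n_absent"] == 1

    def test_monte_carlo_agreement(self):
        # replay the seeded tie-break 10,000x; observed error count within
        # 3 SE of the analytic expectation
        panel = self._panel()
        sites = [TieSite("c", 1, [("A", "G"), ("A", "T"), ("A", "C")], {})]
        expect, _ = expected_tie_errors(sites, panel)
        errs = 0
        for seed in range(10_000):
            chosen, _ = break_ties(sites, seed=seed)
            if chosen and chosen[0].alt != "G":
                errs += 1
        p = expect  # single site: p_err == expected errors per replay
        se = np.sqrt(p * (1 - p) * 10_000)
        assert abs(errs - 10_000 * p) <= 3 * se


class TestMajorityRecoveryLaw:
    def test_vote_matches_binomial_law(self):
        # P(consensus == population-major) = p^3 + 3 p^2 (1-p)
        rng = substream(77, "law")
        n_sites = 4000
        q = rng.uniform(0.05, 0.95, size=n_sites)  # alt AF per site
        draws = rng.random((3, n_sites)) < q
        sets = {}
        for a in range(3):
            sets[f"h{a}"] = [
                _v(i + 1, "A", "G") for i in range(n_sites) if draws[a, i]]
        res = vote_major_alleles(sets, n_assemblies=3)
        has_major = {v.pos - 1 for v in res.major}
        agree = 0
        expect = 0.0
        for i in range(n_sites):
            p = max(q[i], 1 - q[i])
            expect += p ** 3 + 3 * p ** 2 * (1 - p)
            major_is_alt = q[i] > 0.5
            consensus_alt = i in has_major
            if consensus_alt == major_is_alt:
                agree += 1
        se = np.sqrt(n_sites) / 2  # conservative binomial SE bound
        assert abs(agree - expect) <= 3 * se
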