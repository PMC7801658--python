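"""In-silico PCR, chimera flagging, anchoring, pseudo-molecule building."""

import itertools

import numpy as np
import pandas as pd
import pytest

from popref.epcr import (AnchorPlan, EpcrParams, MarkerHit, assign_chromosome,
                         build_pseudomolecules, colinearity,
                         drop_multi_scaffold_markers, epcr_scan,
                         flag_chimeric_scaffolds, mask_intervals, order_orient,
                         resize_gaps, rotate_circular, _weighted_pearson)
from popref.io import Assembly, GenomeInterval, MarkerRecord, revcomp
from popref.simulate import random_sequence, substream

from oracles import brute_force_epcr


def _marker(mid="m1", map_id="gen1", map_type="genetic", lg="chr1", pos=10.0,
            fwd="ACGTACGTACGTACGTACGT", rev="TTGGCCAATTGGCCAATTGG", size=None):
    return MarkerRecord(mid, map_id, map_type, lg, pos, fwd, rev, size)


class TestEpcrScan:
    def test_exact_primers_flanking_insert(self):
        rng = substream(1, "e")
        fwd = random_sequence(rng, 20)
        rev_site = random_sequence(rng, 20)
        insert = random_sequence(rng, 460)
        seq = random_sequence(rng, 100) + fwd + insert + rev_site + \
            random_sequence(rng, 100)
        m = _marker(fwd=fwd, rev=revcomp(rev_site))
        hits = epcr_scan([m], Assembly("a", {"s1": seq}))
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "+"
        assert len(h.amplicon) == 460 + 20 + 20

    def test_reverse_strand_hit(self):
        rng = substream(2, "e")
        fwd = random_sequence(rng, 20)
        rev_site = random_sequence(rng, 20)
        amplicon = fwd + random_sequence(rng, 200) + rev_site
        seq = random_sequence(rng, 80) + revcomp(amplicon) + \
            random_sequence(rng, 80)
        m = _marker(fwd=fwd, rev=revcomp(rev_site))
        hits = epcr_scan([m], Assembly("a", {"s1": seq}))
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_three_prime_mismatch_rejected(self):
        rng = substream(3, "e")
        fwd = random_sequence(rng, 20)
        rev_site = random_sequence(rng, 20)
        seq = random_sequence(rng, 50) + fwd + random_sequence(rng, 100) + \
            rev_site + random_sequence(rng, 50)
        # mutate the 3'-terminal base of the forward primer as given
        bad_last = "A" if fwd[-1] != "A" else "C"
        m = _marker(fwd=fwd[:-1] + bad_last, rev=revcomp(rev_site))
        assert epcr_scan([m], Assembly("a", {"s1": seq})) == []

    def test_one_internal_mismatch_tolerated(self):
        rng = substream(4, "e")
        fwd = random_sequence(rng, 20)
        rev_site = random_sequence(rng, 20)
        seq = random_sequence(rng, 50) + fwd + random_sequence(rng, 100) + \
            rev_site + random_sequence(rng, 50)
        mutated = list(fwd)
        mutated[5] = "A" if fwd[5] != "A" else "C"
        m = _marker(fwd="".join(mutated), rev=revcomp(rev_site))
        hits = epcr_scan([m], Assembly("a", {"s1": seq}))
        assert len(hits) == 1 and hits[0].mismatches_fwd == 1

    def test_size_window_enforced(self):
        rng = substream(5, "e")
        fwd = random_sequence(rng, 20)
        rev_site = random_sequence(rng, 20)
        seq = fwd + random_sequence(rng, 400) + rev_site
        m = _marker(fwd=fwd, rev=revcomp(rev_site), size=(100, 120))
        # amplicon 440 vs expected 100-120 (+50% tolerance -> max 180)
        assert epcr_scan([m], Assembly("a", {"s1": seq})) == []

    def test_equivalence_with_bruteforce_scan(self, tiny_truth):
        # oracle: exhaustive all-positions scan on a few-kb sequence
        from popref.simulate import simulate_marker_maps, MapSpec

        rng = substream(6, "e")
        seq = tiny_truth.ancestral.sequences["chr1"][:5000]
        asm = Assembly("sub", {"s1": seq})
        specs = (MapSpec("g", "genetic", 100.0, 0.0, 6),)
        markers = [m for m in simulate_marker_maps(tiny_truth, specs, seed=6)
                   if m.linkage_group == "chr1"][:6]
        # add mutated copies to exercise the mismatch path
        extra = []
        for m in markers[:3]:
            fl = list(m.primer_fwd)
            fl[4] = "A" if fl[4] != "A" else "G"
            extra.append(MarkerRecord(m.marker_id + "_mut", m.map_id,
                                      m.map_type, m.linkage_group,
                                      m.map_position, "".join(fl),
                                      m.primer_rev, m.expected_size))
        markers = markers + extra
        p = EpcrParams()
        fast = sorted((h.marker_id, h.scaffold, h.amplicon.start,
                       h.amplicon.end, h.strand, h.mismatches_fwd,
                       h.mismatches_rev) for h in epcr_scan(markers, asm, p))
        assert fast == brute_force_epcr(markers, asm, p)


class TestChimeraAndAssignment:
    def _hits(self, spec):
        # spec: list of (marker_id, scaffold)
        return [MarkerHit(mid, scaf, GenomeInterval(scaf, 0, 100), "+", 0, 0)
                for mid, scaf in spec]

    def test_chimera_flagged_on_two_strong_groups(self):
        markers = [_marker(f"c1_{i}", lg="chr1") for i in range(3)] + \
                  [_marker(f"c5_{i}", lg="chr5") for i in range(2)]
        hits = self._hits([(m.marker_id, "s1") for m in markers])
        df = flag_chimeric_scaffolds(hits, markers)
        assert bool(df.loc[df.scaffold == "s1", "flagged"].iloc[0])

    def test_singleton_group_tolerated(self):
        markers = [_marker(f"c1_{i}", lg="chr1") for i in range(5)] + \
                  [_marker("c5_0", lg="chr5")]
        hits = self._hits([(m.marker_id, "s1") for m in markers])
        df = flag_chimeric_scaffolds(hits, markers)
        assert not bool(df.loc[df.scaffold == "s1", "flagged"].iloc[0])

    def test_no_hits_not_flagged(self):
        df = flag_chimeric_scaffolds([], [_marker()])
        assert df.empty

    def test_genetic_weight_beats_rh_count(self):
        # 2 genetic chr1 hits (2x5=10) vs 3 RH chr2 hits (3x1=3)
        markers = ([_marker(f"g{i}", "gen1", "genetic", "chr1")
                    for i in range(2)] +
                   [_marker(f"r{i}", "rh1", "RH", "chr2") for i in range(3)])
        hits = self._hits([(m.marker_id, "s1") for m in markers])
        assignment, unplaced = assign_chromosome(hits, markers)
        assert assignment == {"s1": "chr1"} and not unplaced

    def test_exact_tie_unplaced(self):
        markers = [_marker("g1", "gen1", "genetic", "chr1"),
                   _marker("g2", "gen2", "genetic", "chr2")]
        hits = self._hits([("g1", "s1"), ("g2", "s1")])
        assignment, unplaced = assign_chromosome(hits, markers)
        assert not assignment and unplaced == ["s1"]

    def test_no_hits_unplaced(self):
        assignment, unplaced = assign_chromosome([], [_marker()])
        assert not assignment and not unplaced

    def test_multi_scaffold_markers_dropped(self):
        hits = self._hits([("m1", "s1"), ("m1", "s2"), ("m2", "s1")])
        kept, ambiguous = drop_multi_scaffold_markers(hits)
        assert ambiguous == ["m1"]
        assert {h.marker_id for h in kept} == {"m2"}


class TestOrderOrient:
    def test_noiseless_recovery(self, tiny_truth, tiny_markers,
                                tiny_scaffolds):
        scaffolds, placements = tiny_scaffolds
        hits, _ = drop_multi_scaffold_markers(
            epcr_scan(tiny_markers, scaffolds))
        assignment, _ = assign_chromosome(hits, tiny_markers)
        plan = order_orient(assignment, hits, tiny_markers, gap_size=100)
        truth = {s: (c, st, strand) for s, c, st, e, strand in placements}
        minfo = {m.marker_id: m for m in tiny_markers}
        per_map = {}
        for h in hits:
            key = (h.scaffold, minfo[h.marker_id].map_id)
            per_map[key] = per_map.get(key, 0) + 1
        determinable = {s for (s, _), c in per_map.items() if c >= 2}
        for chrom, entries in plan.chromosomes.items():
            starts = [truth[s][1] for s, _, _ in entries]
            assert starts == sorted(starts)  # Kendall tau == 1
            # orientation is identifiable only where one map has >= 2 markers
            assert all(truth[s][2] == o for s, o, _ in entries
                       if s in determinable)
        per_map, summary = colinearity(plan, hits, tiny_markers, scaffolds,
                                       gap_size=100)
        assert (per_map["r"] > 0.999).all()

    def test_descending_map_positions_orient_minus(self):
        markers = [_marker(f"m{i}", pos=50.0 - i * 10) for i in range(3)]
        hits = [MarkerHit(f"m{i}", "s1",
                          GenomeInterval("s1", 100 + i * 500, 200 + i * 500),
                          "+", 0, 0) for i in range(3)]
        plan = order_orient({"s1": "chr1"}, hits, markers)
        (entry,) = plan.chromosomes["chr1"]
        assert entry[1] == "-"

    def test_heuristic_matches_exhaustive_permutation_oracle(self):
        # 5 scaffolds, noisy maps: heuristic order must equal the
        # permutation maximizing the weighted sum of per-map Pearson r
        rng = substream(9, "perm")
        n_scaf = 5
        markers, hits = [], []
        weights = {"genetic": 5, "RH": 1}
        for map_id, map_type, sd in (("g1", "genetic", 0.5), ("r1", "RH", 6.0)):
            for s in range(n_scaf):
                for j in range(2):
                    true_pos = s * 20 + j * 8 + 2
                    mid = f"{map_id}_s{s}_{j}"
                    markers.append(_marker(
                        mid, map_id, map_type, "chr1",
                        max(0.0, true_pos + float(rng.normal(0, sd)))))
                    hits.append(MarkerHit(
                        mid, f"sc{s}",
                        GenomeInterval(f"sc{s}", 100 + j * 800, 200 + j * 800),
                        "+", 0, 0))
        assignment = {f"sc{s}": "chr1" for s in range(n_scaf)}
        plan = order_orient(assignment, hits, markers, weights)
        got_order = [s for s, _, _ in plan.chromosomes["chr1"]]

        lengths = {f"sc{s}": 1000 for s in range(n_scaf)}
        by_marker = {m.marker_id: m for m in markers}

        def objective(perm):
            offsets = {}
            cur = 0
            for s in perm:
                offsets[s] = cur
                cur += lengths[s] + 100
            pts = {}
            for h in hits:
                m = by_marker[h.marker_id]
                pts.setdefault((m.map_id, m.map_type), []).append(
                    (offsets[h.scaffold] + h.amplicon.start, m.map_position))
            total = 0.0
            for (map_id, map_type), xy in pts.items():
                x, y = np.array([p[0] for p in xy]), np.array([p[1] for p in xy])
                r = np.corrcoef(x, y)[0, 1]
                total += weights[map_type] * r
            return total

        best = max(itertools.permutations(assignment), key=objective)
        assert got_order == list(best)


class TestColinearitySummary:
    def test_perfect_and_reversed(self):
        x = [0, 10, 20, 30]
        assert _weighted_pearson(x, [1, 2, 3, 4], [1] * 4) == pytest.approx(1.0)
        assert _weighted_pearson(x, [4, 3, 2, 1], [1] * 4) == pytest.approx(-1.0)

    def test_summary_mean_sd(self):
        vals = pd.Series([1.0, 0.98, 0.96])
        assert vals.mean() == pytest.approx(0.98)
        assert vals.std() == pytest.approx(0.02)


class TestPseudomolecules:
    def test_gap_arithmetic(self):
        asm = Assembly("a", {"s1": "A" * 1000, "s2": "C" * 2000})
        plan = AnchorPlan(chromosomes={"chr1": [("s1", "+", 0.0),
                                                ("s2", "+", 1.0)]},
                          gap_size=10_000)
        chroms, agp = build_pseudomolecules(plan, asm)
        assert chroms.contig_length("chr1") == 13_000
        assert [row[4] for row in agp] == ["W", "N", "W"]

    def test_single_scaffold_no_gap(self):
        asm = Assembly("a", {"s1": "A" * 500})
        plan = AnchorPlan(chromosomes={"chr1": [("s1", "+", 0.0)]})
        chroms, agp = build_pseudomolecules(plan, asm)
        assert chroms.contig_length("chr1") == 500 and len(agp) == 1

    def test_minus_scaffold_reverse_complemented(self):
        asm = Assembly("a", {"s1": "AACG"})
        plan = AnchorPlan(chromosomes={"chr1": [("s1", "-", 0.0)]})
        chroms, _ = build_pseudomolecules(plan, asm)
        assert chroms.sequences["chr1"] == "CGTT"

    def test_missing_scaffold_rejected(self):
        plan = AnchorPlan(chromosomes={"chr1": [("ghost", "+", 0.0)]})
        with pytest.raises(KeyError):
            build_pseudomolecules(plan, Assembly("a", {"s1": "ACGT"}))

    def test_agp_fasta_consistency(self, tiny_markers, tiny_scaffolds):
        # rebuilding chromosomes from AGP + scaffolds reproduces the FASTA
        scaffolds, _ = tiny_scaffolds
        hits, _ = drop_multi_scaffold_markers(
            epcr_scan(tiny_markers, scaffolds))
        assignment, _ = assign_chromosome(hits, tiny_markers)
        plan = order_orient(assignment, hits, tiny_markers, gap_size=500)
        chroms, agp = build_pseudomolecules(plan, scaffolds)
        rebuilt = {}
        for row in agp:
            obj = row[0]
            if row[4] == "W":
                seq = scaffolds.sequences.get(row[5], chroms.sequences.get(row[5]))
                piece = seq if row[8] == "+" else revcomp(seq)
            else:
                piece = "N" * int(row[5])
            rebuilt[obj] = rebuilt.get(obj, "") + piece
        for contig, seq in chroms.sequences.items():
            assert rebuilt[contig] == seq


class TestFinishingEdits:
    def test_mask_replaces_with_n(self):
        asm = Assembly("a", {"s1": "ACGT" * 5})
        out = mask_intervals(asm, [GenomeInterval("s1", 0, 10)])
        assert out.sequences["s1"] == "N" * 10 + ("ACGT" * 5)[10:]
        assert out.contig_length("s1") == 20

    def test_mask_empty_identity(self):
        asm = Assembly("a", {"s1": "ACGT"})
        assert mask_intervals(asm, []).sequences == asm.sequences

    def test_mask_out_of_range_rejected(self):
        asm = Assembly("a", {"s1": "ACGT"})
        with pytest.raises(ValueError):
            mask_intervals(asm, [GenomeInterval("s1", 0, 10)])

    def test_rotate_to_anchor(self):
        assert rotate_circular("CGTA", "AC") == "ACGT"
        assert rotate_circular("ACGT", "AC") == "ACGT"  # already at start

    def test_rotate_anchor_absent_or_multiple(self):
        with pytest.raises(ValueError):
            rotate_circular("CGTA", "TT")
        with pytest.raises(ValueError):
            rotate_circular("ACAC", "AC")

    def test_resize_gap(self):
        asm = Assembly("a", {"s1": "ACGT" + "N" * 100 + "TTAA"})
        out, delta = resize_gaps(asm, {("s1", 0): 500})
        assert out.contig_length("s1") == 4 + 500 + 4 and delta == 400

    def test_resize_missing_gap_rejected(self):
        asm = Assembly("a", {"s1": "ACGT"})
        with pytest.raises(ValueError):
            resize_gaps(asm, {("s1", 0): 10})

    def test_resize_no_spec_identity(self):
        asm = Assembly("a", {"s1": "ACGTNNNNACGT"})
        out, delta = resize_gaps(asm, {})
        assert out.sequences == asm.sequences and delta == 0
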