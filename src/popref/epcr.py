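"""In-silico STS PCR and marker-map scaffold anchoring.

An STS marker amplifies on a scaffold when its forward primer and the
reverse complement of its reverse primer occur on opposite strands,
oriented toward each other, each within the mismatch tolerance and with
an exact 3'-terminal seed, and the implied amplicon size is plausible.
Hits are weighted by their map of origin (genetic maps 5, RH maps 1) to
assign scaffolds to chromosomes, order them by weighted mean map
position, and orient them by the sign of the correlation between
within-scaffold coordinate and map position. Pseudo-molecules are then
concatenations with fixed N gaps, described by an AGP file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Assembly, GenomeInterval, revcomp


@dataclass
class EpcrParams:
    max_mismatch: int = 1        # per primer
    three_prime_exact: int = 3   # 3'-terminal bases that must match exactly
    size_tolerance: float = 0.5  # amplicon within (1±tol)×expected
    max_amplicon: int = 5000     # cap when no expected size is stated


@dataclass
class MarkerHit:
    marker_id: str
    scaffold: str
    amplicon: GenomeInterval
    strand: str
    mismatches_fwd: int
    mismatches_rev: int


def _find_sites(seq: str, primer: str, max_mm: int, three_prime_exact: int,
                anchor_end: bool):
    """Positions where ``primer`` matches ``seq`` with <= max_mm mismatches
    and an exact run over its 3'-most bases.

    ``anchor_end=True`` means the primer's 3' end is its last base (forward
    orientation on this strand); False means the 3' end is its first base
    (the primer was reverse-complemented before searching).

    Pigeonhole candidate generation: with <= 1 mismatch one of the two
    primer halves matches exactly, so exact substring search on the halves
    (C speed) prunes the scan. Returns list of (pos, n_mismatch).
    """
    plen = len(primer)
    if plen > len(seq):
        return []
    # pigeonhole: split into max_mm+1 chunks; one must match exactly
    n_chunks = max_mm + 1
    bounds = [round(i * plen / n_chunks) for i in range(n_chunks + 1)]
    chunks = [(bounds[i], primer[bounds[i]:bounds[i + 1]])
              for i in range(n_chunks)]
    candidates = set()
    for off, half in chunks:
        start = seq.find(half)
        while start != -1:
            p = start - off
            if 0 <= p <= len(seq) - plen:
                candidates.add(p)
            start = seq.find(half, start + 1)
    hits = []
    for p in sorted(candidates):
        window = seq[p:p + plen]
        mm = sum(a != b for a, b in zip(window, primer))
        if mm > max_mm:
            continue
        k = three_prime_exact
        if anchor_end:
            if window[-k:] != primer[-k:]:
                continue
        else:
            if window[:k] != primer[:k]:
                continue
        hits.append((p, mm))
    return hits


def epcr_scan(markers, assembly: Assembly,
              params: EpcrParams | None = None) -> list[MarkerHit]:
    """In-silico PCR of every marker against every contig.

    A '+' hit has the forward primer at the amplicon's left edge and
    revcomp(reverse primer) at its right edge; a '-' hit is the mirror
    image (marker annealing to the reverse strand). Amplicon size must be
    within (1±size_tolerance)×expected when the marker states an expected
    size window, else <= max_amplicon.
    """
    p = params or EpcrParams()
    hits = []
    for scaffold, seq in assembly.sequences.items():
        for m in markers:
            fwd, rev = m.primer_fwd, m.primer_rev
            if m.expected_size:
                lo = int(m.expected_size[0] * (1 - p.size_tolerance))
                hi = int(np.ceil(m.expected_size[1] * (1 + p.size_tolerance)))
            else:
                lo, hi = len(fwd) + len(rev), p.max_amplicon
            # '+' orientation: fwd then revcomp(rev) downstream
            left = _find_sites(seq, fwd, p.max_mismatch, p.three_prime_exact,
                               anchor_end=True)
            right = _find_sites(seq, revcomp(rev), p.max_mismatch,
                                p.three_prime_exact, anchor_end=False)
            for lp, lmm in left:
                for rp, rmm in right:
                    size = rp + len(rev) - lp
                    if rp >= lp + len(fwd) and lo <= size <= hi:
                        hits.append(MarkerHit(
                            m.marker_id, scaffold,
                            GenomeInterval(scaffold, lp, rp + len(rev), "+"),
                            "+", lmm, rmm))
            # '-' orientation: rev primer then revcomp(fwd) downstream
            left = _find_sites(seq, rev, p.max_mismatch, p.three_prime_exact,
                               anchor_end=True)
            right = _find_sites(seq, revcomp(fwd), p.max_mismatch,
                                p.three_prime_exact, anchor_end=False)
            for lp, lmm in left:
                for rp, rmm in right:
                    size = rp + len(fwd) - lp
                    if rp >= lp + len(rev) and lo <= size <= hi:
                        hits.append(MarkerHit(
                            m.marker_id, scaffold,
                            GenomeInterval(scaffold, lp, rp + len(fwd), "-"),
                            "-", rmm, lmm))
    return hits


def drop_multi_scaffold_markers(hits):
    """Markers amplifying on more than one scaffold are ambiguous for
    anchoring; drop all their hits. Returns (kept, dropped_marker_ids)."""
    scaffolds: dict[str, set] = {}
    for h in hits:
        scaffolds.setdefault(h.marker_id, set()).add(h.scaffold)
    ambiguous = {m for m, s in scaffolds.items() if len(s) > 1}
    return [h for h in hits if h.marker_id not in ambiguous], sorted(ambiguous)


def flag_chimeric_scaffolds(hits, markers, min_markers: int = 2):
    """Scaffolds whose markers come from >= 2 distinct linkage groups,
    each represented by >= min_markers hits (singletons tolerated).

    Returns DataFrame: scaffold, linkage groups with counts, flagged.
    """
    lg = {m.marker_id: m.linkage_group for m in markers}
    counts: dict[str, dict[str, int]] = {}
    for h in hits:
        g = lg.get(h.marker_id)
        if g is None:
            continue
        counts.setdefault(h.scaffold, {}).setdefault(g, 0)
        counts[h.scaffold][g] += 1
    rows = []
    for scaffold, groups in sorted(counts.items()):
        strong = [g for g, c in groups.items() if c >= min_markers]
        rows.append({
            "scaffold": scaffold,
            "groups": ";".join(f"{g}:{c}" for g, c in sorted(groups.items())),
            "flagged": len(strong) >= 2,
        })
    return pd.DataFrame(rows)


DEFAULT_WEIGHTS = {"genetic": 5, "RH": 1}


def assign_chromosome(hits, markers, weights: dict | None = None):
    """Assign each scaffold to the linkage group with the highest summed
    hit weight (weight = the hit's map-type weight). Exact ties are left
    unplaced. Returns (assignment dict, unplaced list)."""
    w = weights or DEFAULT_WEIGHTS
    minfo = {m.marker_id: m for m in markers}
    scores: dict[str, dict[str, float]] = {}
    for h in hits:
        m = minfo.get(h.marker_id)
        if m is None:
            continue
        scores.setdefault(h.scaffold, {}).setdefault(m.linkage_group, 0.0)
        scores[h.scaffold][m.linkage_group] += w[m.map_type]
    assignment: dict[str, str] = {}
    unplaced: list[str] = []
    for scaffold, groups in scores.items():
        best = max(groups.values())
        top = [g for g, s in groups.items() if s == best]
        if len(top) == 1:
            assignment[scaffold] = top[0]
        else:
            unplaced.append(scaffold)
    return assignment, sorted(unplaced)


@dataclass
class AnchorPlan:
    """Ordered, oriented scaffolds per chromosome plus the unplaced rest."""

    chromosomes: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)
    gap_size: int = 10_000
    unplaced: list[str] = field(default_factory=list)


def _weighted_pearson(x, y, w):
    x, y, w = np.asarray(x, float), np.asarray(y, float), np.asarray(w, float)
    wsum = w.sum()
    mx, my = (w * x).sum() / wsum, (w * y).sum() / wsum
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx == 0 or vy == 0:
        return 0.0
    return cov / np.sqrt(vx * vy)


def order_orient(assignment: dict, hits, markers, weights: dict | None = None,
                 gap_size: int = 10_000, unplaced=()) -> AnchorPlan:
    """Order scaffolds within each chromosome by weighted mean map
    position; orient each by the weight-combined sign of per-map Pearson
    correlations between within-scaffold amplicon coordinate and map
    position.

    For ordering, map positions are z-scored within (map, linkage group)
    before pooling — cM and cR scales are not commensurable, and
    standardization is monotone per map, so single-map behaviour is
    unchanged while mixed-map scores stay comparable. For orientation,
    each map with >= 2 hits on the scaffold contributes its own
    correlation times its weight (markers from different maps are never
    correlated against each other: two maps agree on scale only
    approximately, so cross-map pairs carry sign noise). Scaffolds where
    no single map has >= 2 usable markers default to '+'.
    """
    w = weights or DEFAULT_WEIGHTS
    minfo = {m.marker_id: m for m in markers}

    # per (map, lg) position mean/sd for z-scoring
    stats: dict[tuple, tuple[float, float]] = {}
    groups: dict[tuple, list[float]] = {}
    for m in markers:
        groups.setdefault((m.map_id, m.linkage_group), []).append(m.map_position)
    for key, vals in groups.items():
        arr = np.asarray(vals, float)
        sd = arr.std()
        stats[key] = (arr.mean(), sd if sd > 0 else 1.0)

    per_scaffold: dict[str, list] = {}
    for h in hits:
        m = minfo.get(h.marker_id)
        if m is None:
            continue
        per_scaffold.setdefault(h.scaffold, []).append((h, m))

    plan = AnchorPlan(gap_size=gap_size, unplaced=list(unplaced))
    for scaffold, chrom in assignment.items():
        entries = [(h, m) for h, m in per_scaffold.get(scaffold, [])
                   if m.linkage_group == chrom]
        if not entries:
            plan.unplaced.append(scaffold)
            continue
        ws = [w[m.map_type] for _, m in entries]
        zpos = [(m.map_position - stats[(m.map_id, m.linkage_group)][0])
                / stats[(m.map_id, m.linkage_group)][1] for _, m in entries]
        score = float(np.average(zpos, weights=ws))
        by_map: dict[str, list] = {}
        for h, m in entries:
            by_map.setdefault(m.map_id, []).append((h, m))
        orient_score = 0.0
        for map_id, ents in by_map.items():
            if len(ents) < 2:
                continue
            coords = [h.amplicon.start for h, _ in ents]
            pos = [m.map_position for _, m in ents]
            r = _weighted_pearson(coords, pos, [1.0] * len(ents))
            orient_score += w[ents[0][1].map_type] * r
        orient = "+" if orient_score >= 0 else "-"
        plan.chromosomes.setdefault(chrom, []).append((scaffold, orient, score))
    for chrom in plan.chromosomes:
        plan.chromosomes[chrom].sort(key=lambda t: (t[2], t[0]))
    plan.unplaced.sort()
    return plan


def build_pseudomolecules(plan: AnchorPlan, assembly: Assembly,
                          gap_size: int | None = None,
                          name: str = "anchored"):
    """Concatenate ordered/oriented scaffolds with fixed N gaps.

    Returns (Assembly of chromosomes + unplaced scaffolds, AGP rows).
    Chromosome length = Σ scaffold lengths + (k-1)×gap_size.
    """
    gap = plan.gap_size if gap_size is None else gap_size
    out = Assembly(name)
    agp_rows = []
    for chrom in sorted(plan.chromosomes):
        parts = []
        cursor = 0  # 0-based
        part_no = 0
        for i, (scaffold, orient, _score) in enumerate(plan.chromosomes[chrom]):
            if scaffold not in assembly:
                raise KeyError(f"scaffold {scaffold!r} missing from assembly")
            if i > 0 and gap > 0:
                part_no += 1
                agp_rows.append((chrom, cursor + 1, cursor + gap, part_no,
                                 "N", gap, "scaffold", "yes", "map"))
                parts.append("N" * gap)
                cursor += gap
            seq = assembly.sequences[scaffold]
            if orient == "-":
                seq = revcomp(seq)
            part_no += 1
            agp_rows.append((chrom, cursor + 1, cursor + len(seq), part_no,
                             "W", scaffold, 1, len(seq), orient))
            parts.append(seq)
            cursor += len(seq)
        out.add_contig(chrom, "".join(parts))
    for scaffold in plan.unplaced:
        if scaffold in assembly:
            out.add_contig(scaffold, assembly.sequences[scaffold])
            agp_rows.append((scaffold, 1, assembly.contig_length(scaffold), 1,
                             "W", scaffold, 1, assembly.contig_length(scaffold), "+"))
    return out, agp_rows


def pseudomolecule_coords(plan: AnchorPlan, assembly: Assembly,
                          gap_size: int | None = None):
    """Map scaffold -> (chrom, offset, orient, length) under the plan."""
    gap = plan.gap_size if gap_size is None else gap_size
    coords = {}
    for chrom, entries in plan.chromosomes.items():
        cursor = 0
        for i, (scaffold, orient, _s) in enumerate(entries):
            if i > 0:
                cursor += gap
            ln = assembly.contig_length(scaffold)
            coords[scaffold] = (chrom, cursor, orient, ln)
            cursor += ln
    return coords


def colinearity(plan: AnchorPlan, hits, markers, assembly: Assembly,
                gap_size: int | None = None):
    """Pearson r between pseudo-molecule coordinate and map position, per
    (map, chromosome); summary mean ± SD by map type.

    |r| is reported (orientation already applied when building the
    pseudo-molecule); pairs with < 2 markers are excluded.
    Returns (per-map DataFrame, summary DataFrame).
    """
    minfo = {m.marker_id: m for m in markers}
    coords = pseudomolecule_coords(plan, assembly, gap_size)
    points: dict[tuple, list] = {}
    for h in hits:
        m = minfo.get(h.marker_id)
        if m is None or h.scaffold not in coords:
            continue
        chrom, offset, orient, ln = coords[h.scaffold]
        if m.linkage_group != chrom:
            continue
        within = h.amplicon.start
        if orient == "-":
            within = ln - h.amplicon.end
        points.setdefault((m.map_id, m.map_type, chrom), []).append(
            (offset + within, m.map_position))
    rows = []
    for (map_id, map_type, chrom), pts in sorted(points.items()):
        if len(pts) < 2:
            continue
        x, y = zip(*pts)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"map_id": map_id, "map_type": map_type, "chrom": chrom,
                     "r": abs(r), "n_markers": len(pts)})
    per_map = pd.DataFrame(rows)
    if len(per_map):
        summary = (per_map.groupby("map_type")["r"]
                   .agg(["mean", "std", "count"]).reset_index())
    else:
        summary = pd.DataFrame(columns=["map_type", "mean", "std", "count"])
    return per_map, summary


# ---------------------------------------------------------------------------
# finishing edits
# ---------------------------------------------------------------------------


def mask_intervals(assembly: Assembly, intervals) -> Assembly:
    """Replace bases within intervals by N (length preserved)."""
    out = Assembly(assembly.name)
    todo: dict[str, list] = {}
    for iv in intervals:
        if iv.contig not in assembly:
            raise KeyError(f"contig {iv.contig!r} not in assembly")
        if iv.end > assembly.contig_length(iv.contig):
            raise ValueError(f"interval {iv.contig}:{iv.start}-{iv.end} out of range")
        todo.setdefault(iv.contig, []).append((iv.start, iv.end))
    for contig, seq in assembly.sequences.items():
        chars = list(seq)
        for s, e in todo.get(contig, []):
            chars[s:e] = "N" * (e - s)
        out.add_contig(contig, "".join(chars),
                       softmask=assembly.softmask.get(contig))
    return out


def rotate_circular(seq: str, anchor_subseq: str) -> str:
    """Rotate a circular sequence so it starts with ``anchor_subseq``.

    The anchor must occur exactly once (on the forward strand of the
    doubled sequence, excluding wrap-equivalent duplicates).
    """
    doubled = seq + seq
    first = doubled.find(anchor_subseq)
    if first == -1 or first >= len(seq):
        raise ValueError("anchor not found")
    second = doubled.find(anchor_subseq, first + 1)
    if second != -1 and second < first + len(seq):
        raise ValueError("anchor occurs more than once")
    return seq[first:] + seq[:first]


def resize_gaps(assembly: Assembly, gap_spec: dict) -> tuple[Assembly, int]:
    """Set named N-runs to specified lengths.

    ``gap_spec`` maps (contig, run_index) -> new length, run_index counting
    N-runs (of any length) left to right per contig. A spec entry naming a
    non-existent run raises. Returns (assembly, net Ns inserted).
    """
    import re

    out = Assembly(assembly.name)
    delta_total = 0
    runs_by_contig: dict[str, list] = {}
    for contig, seq in assembly.sequences.items():
        runs_by_contig[contig] = [(m.start(), m.end())
                                  for m in re.finditer("N+", seq)]
    for (contig, idx) in gap_spec:
        if contig not in runs_by_contig or idx >= len(runs_by_contig[contig]):
            raise ValueError(f"no N-run #{idx} on contig {contig!r}")
    for contig, seq in assembly.sequences.items():
        runs = runs_by_contig[contig]
        parts = []
        cursor = 0
        for i, (s, e) in enumerate(runs):
            parts.append(seq[cursor:s])
            new_len = gap_spec.get((contig, i), e - s)
            parts.append("N" * new_len)
            delta_total += new_len - (e - s)
            cursor = e
        parts.append(seq[cursor:])
        out.add_contig(contig, "".join(parts))
    return out, delta_total
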