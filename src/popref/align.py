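"""Lightweight whole-assembly pairwise alignment.

Anchor-chain-extend at desk scale: unique exact k-mer anchors, a longest
co-linear chain per (query contig, target contig, strand), and banded
affine-gap (Gotoh) dynamic programming across inter-anchor gaps. The
result plays the role that an asm5-preset whole-genome aligner plays at
production scale: co-linear AlignmentBlocks whose op lists drive variant
calling and chain generation. Precomputed PAF (+cs) can be imported as a
bypass via :func:`paf_to_blocks`.

Conventions
-----------
* Query intervals are always reported in forward-query coordinates.
* For '-' strand blocks the ops walk the target left to right against the
  reverse-complemented query, so downstream variant calling never needs
  strand handling: alt bases are already in target orientation.
* Runs of >= ``n_split`` Ns split a contig into independently aligned
  segments; variants are never called across such gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Assembly, GenomeInterval, PafRecord, revcomp

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def _encode(seq: str) -> np.ndarray:
    """2-bit encode an uppercase sequence; N and friends become 255."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """uint64 k-mer codes per position; positions whose window contains a
    non-ACGT base get the sentinel ``2**63``."""
    codes = _encode(seq).astype(np.uint64)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = codes == 255
    out = np.zeros(n, dtype=np.uint64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        out = (out << np.uint64(2)) | (codes[j:j + n] & np.uint64(3))
        invalid |= bad[j:j + n]
    out[invalid] = np.uint64(1) << np.uint64(63)
    return out


@dataclass
class AlignmentBlock:
    """A co-linear aligned segment between one query and one target contig.

    ``ops`` is an ordered list of (kind, length, alt) with kind in
    {match, sub, ins, del}; alt holds query bases for sub/ins and deleted
    target bases for del. Span accounting invariants are enforced by
    :meth:`validate`.
    """

    query: GenomeInterval
    target: GenomeInterval
    strand: str
    ops: list = field(default_factory=list)
    score: int = 0

    def validate(self) -> None:
        tspan = sum(n for k, n, _ in self.ops if k in ("match", "sub", "del"))
        qspan = sum(n for k, n, _ in self.ops if k in ("match", "sub", "ins"))
        if tspan != len(self.target):
            raise ValueError(f"target span {tspan} != interval {len(self.target)}")
        if qspan != len(self.query):
            raise ValueError(f"query span {qspan} != interval {len(self.query)}")
        for (k1, _, _), (k2, _, _) in zip(self.ops, self.ops[1:]):
            if k1 == k2 and k1 != "sub":
                raise ValueError(f"adjacent same-kind ops ({k1})")

    @property
    def identity(self) -> float:
        matched = sum(n for k, n, _ in self.ops if k == "match")
        total = sum(n for k, n, _ in self.ops)
        return matched / total if total else 0.0


@dataclass
class AlignParams:
    """Aligner knobs; score constants mimic asm5-like behaviour on
    >=95%-identity pairs (cost-minimizing: match 0, mismatch 4,
    gap open 4, gap extend 2)."""

    k: int = 19
    mismatch: int = 4
    gap_open: int = 4
    gap_extend: int = 2
    band: int = 64
    band_limit: int = 4096
    max_gap: int = 50_000
    min_chain_anchors: int = 4
    n_split: int = 10


# ---------------------------------------------------------------------------
# anchors and chaining
# ---------------------------------------------------------------------------


def find_anchors(query_seq: str, target_seq: str, k: int = 19):
    """Exact-match anchors (qpos, tpos, strand) between two sequences.

    Only k-mers that occur exactly once in the target are used; k-mers
    containing N are skipped. For '-' anchors qpos refers to the position
    in the reverse-complemented query (so chains ascend on both axes).
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if k > min(len(query_seq), len(target_seq)):
        raise ValueError("k exceeds sequence length")
    sentinel = np.uint64(1) << np.uint64(63)
    tcodes = _kmer_codes(target_seq, k)
    order = np.argsort(tcodes, kind="stable")
    scodes = tcodes[order]
    # unique-in-target filter
    uniq_mask = np.ones(len(scodes), dtype=bool)
    dup = scodes[1:] == scodes[:-1]
    uniq_mask[1:] &= ~dup
    uniq_mask[:-1] &= ~dup
    uniq_mask &= scodes != sentinel
    ucodes = scodes[uniq_mask]
    upos = order[uniq_mask]

    anchors = []
    if len(ucodes) == 0:
        return anchors
    for strand, qseq in (("+", query_seq), ("-", revcomp(query_seq))):
        qcodes = _kmer_codes(qseq, k)
        if len(qcodes) == 0:
            continue
        idx = np.searchsorted(ucodes, qcodes)
        idx[idx >= len(ucodes)] = len(ucodes) - 1
        hit = (ucodes[idx] == qcodes) & (qcodes != sentinel)
        qpos = np.flatnonzero(hit)
        tpos = upos[idx[hit]]
        anchors.extend(zip(qpos.tolist(), tpos.tolist(), [strand] * len(qpos)))
    return anchors


def chain_anchors(anchors):
    """Best strictly co-linear chain (max anchor count) for one
    (query, target, strand) anchor set — an unweighted LIS in O(n log n).

    Ties are resolved toward smaller target coordinate (the chain found
    first among equals under the stable sort), making output deterministic.
    """
    if not anchors:
        return []
    # sort by target, and by descending query within equal targets so two
    # anchors sharing a target position can never both be chosen
    pts = sorted(anchors, key=lambda a: (a[1], -a[0]))
    qs = [p[0] for p in pts]
    import bisect

    tails: list[int] = []  # qpos of smallest tail for each chain length
    tails_idx: list[int] = []
    parent = [-1] * len(pts)
    for i, q in enumerate(qs):
        j = bisect.bisect_left(tails, q)
        if j > 0:
            parent[i] = tails_idx[j - 1]
        if j == len(tails):
            tails.append(q)
            tails_idx.append(i)
        elif q < tails[j]:
            tails[j] = q
            tails_idx[j] = i
    # backtrack from the best (longest) chain end
    chain = []
    i = tails_idx[-1]
    while i != -1:
        chain.append(pts[i])
        i = parent[i]
    chain.reverse()
    # enforce strict increase on target too (guaranteed by construction
    # except for equal-target pairs, which the sort order excludes)
    return chain


# ---------------------------------------------------------------------------
# banded affine-gap alignment of inter-anchor gaps
# ---------------------------------------------------------------------------


def extend_align(query_gap: str, target_gap: str, band: int = 64,
                 params: AlignParams | None = None):
    """Global alignment of two gap sequences with affine gap costs.

    Returns an op list (match/sub/ins/del). The DP is banded around the
    length-adjusted diagonal; when the optimal path would leave the band
    the band is doubled (up to ``band_limit``), after which the pair is
    emitted as an unaligned del+ins couple. Tie-breaking during traceback
    prefers diagonal moves, which pushes equivalent gap placements to the
    leftmost position.
    """
    p = params or AlignParams()
    n, m = len(query_gap), len(target_gap)
    if n == 0 and m == 0:
        return []
    if m == 0:
        return [("ins", n, query_gap)]
    if n == 0:
        return [("del", m, target_gap)]
    if min(n, m) > p.max_gap:
        return [("del", m, target_gap), ("ins", n, query_gap)]

    width = band
    while True:
        ops, on_edge = _gotoh_banded(query_gap, target_gap, width, p)
        if not on_edge or width >= max(n, m):
            return ops
        if width >= p.band_limit:
            return [("del", m, target_gap), ("ins", n, query_gap)]
        width = min(width * 2, max(n, m))


def _gotoh_banded(q: str, t: str, width: int, p: AlignParams):
    """Gotoh DP restricted to a diagonal band. Returns (ops, on_edge)
    where ``on_edge`` is True when the optimal path touched the band
    boundary (caller should widen and retry).

    States: M (diagonal), X (gap in query = deletion from target),
    Y (gap in target = insertion of query). At equal cost the preference
    order M > X > Y is applied both when filling and when choosing the
    final state; together with traceback from the end this places
    equivalent gaps leftmost.
    """
    n, m = len(q), len(t)
    INF = float("inf")
    go, ge, mis = p.gap_open, p.gap_extend, p.mismatch
    w = width + abs(n - m)

    def col_range(i):
        c = (i * m) // max(n, 1)
        return max(0, c - w), min(m, c + w)

    # per-row dict of (M, X, Y, ptrM, ptrX, ptrY) column arrays
    rows = []
    lo0, hi0 = col_range(0)
    size0 = hi0 - lo0 + 1
    M = [INF] * size0
    X = [INF] * size0
    Y = [INF] * size0
    M[0] = 0.0
    for j in range(max(1, lo0), hi0 + 1):
        X[j - lo0] = go + ge * j
    rows.append((lo0, M, X, Y, [0] * size0, [1] * size0, [0] * size0))

    for i in range(1, n + 1):
        lo, hi = col_range(i)
        size = hi - lo + 1
        M = [INF] * size
        X = [INF] * size
        Y = [INF] * size
        pM = [0] * size
        pX = [0] * size
        pY = [0] * size
        plo, Mp, Xp, Yp, _, _, _ = rows[-1]
        phi = plo + len(Mp) - 1
        qi = q[i - 1]
        for idx in range(size):
            j = lo + idx
            # Y: consume q[i-1] against a gap — predecessor at (i-1, j)
            if plo <= j <= phi:
                k = j - plo
                cands = (Mp[k] + go + ge, Xp[k] + go + ge, Yp[k] + ge)
                best = min(cands)
                if best < INF:
                    Y[idx] = best
                    pY[idx] = cands.index(best) if best != cands[0] else 0
            # M: diagonal from (i-1, j-1)
            if j >= 1 and plo <= j - 1 <= phi:
                k = j - 1 - plo
                cost = 0 if qi == t[j - 1] else mis
                cands = (Mp[k] + cost, Xp[k] + cost, Yp[k] + cost)
                best = min(cands)
                if best < INF:
                    M[idx] = best
                    pM[idx] = cands.index(best) if best != cands[0] else 0
            # X: consume t[j-1] against a gap — predecessor at (i, j-1)
            if idx >= 1:
                cands = (M[idx - 1] + go + ge, X[idx - 1] + ge,
                         Y[idx - 1] + go + ge)
                best = min(cands)
                if best < INF:
                    X[idx] = best
                    pX[idx] = (0, 1, 2)[cands.index(best)] if best != cands[0] else 0
        rows.append((lo, M, X, Y, pM, pX, pY))

    lo, M, X, Y, _, _, _ = rows[n]
    if m < lo or m > lo + len(M) - 1:
        return [("del", m, t), ("ins", n, q)], True
    idx = m - lo
    finals = (M[idx], X[idx], Y[idx])
    best = min(finals)
    if best == INF:
        return [("del", m, t), ("ins", n, q)], True
    state = finals.index(best) if best != finals[0] else 0

    on_edge = False
    ops_rev = []
    i, j = n, m
    while i > 0 or j > 0:
        lo, M, X, Y, pM, pX, pY = rows[i]
        idx = j - lo
        if idx <= 0 or idx >= len(M) - 1:
            on_edge = True
        if state == 0:
            ops_rev.append(("match", 1, None) if q[i - 1] == t[j - 1]
                           else ("sub", 1, q[i - 1]))
            state = pM[idx]
            i, j = i - 1, j - 1
        elif state == 1:
            ops_rev.append(("del", 1, t[j - 1]))
            state = pX[idx]
            j -= 1
        else:
            ops_rev.append(("ins", 1, q[i - 1]))
            state = pY[idx]
            i -= 1
    ops_rev.reverse()
    return _coalesce(ops_rev), on_edge


def _coalesce(ops):
    """Merge adjacent same-kind unit ops into runs."""
    out = []
    for kind, length, alt in ops:
        if out and out[-1][0] == kind and kind != "sub":
            pk, pl, pa = out.pop()
            length += pl
            if alt is not None or pa is not None:
                alt = (pa or "") + (alt or "")
        out.append((kind, length, alt))
    return out


def align_score(ops, params: AlignParams | None = None) -> int:
    """Cost of an op list under the aligner's scoring (lower is better)."""
    p = params or AlignParams()
    cost = 0
    for kind, length, _ in ops:
        if kind == "sub":
            cost += p.mismatch * length
        elif kind in ("ins", "del"):
            cost += p.gap_open + p.gap_extend * length
    return cost


# ---------------------------------------------------------------------------
# whole-contig alignment
# ---------------------------------------------------------------------------


def _split_segments(seq: str, n_split: int):
    """Yield (offset, subseq) segments split at N-runs >= n_split."""
    import re

    last = 0
    for m in re.finditer("N{%d,}" % n_split, seq):
        if m.start() > last:
            yield last, seq[last:m.start()]
        last = m.end()
    if last < len(seq):
        yield last, seq[last:]


def _chain_to_block(chain, qseq, tseq, qname, tname, qlen, strand,
                    qoff, toff, params: AlignParams):
    """Build one AlignmentBlock from a chained anchor list.

    qseq is already reverse-complemented for '-' chains; coordinates in
    the chain refer to qseq/tseq frames and are offset back at the end.
    """
    k = params.k
    ops = []
    q0, t0 = chain[0][0], chain[0][1]
    qe, te = q0, t0  # exclusive ends of emitted prefix, in gap-free walk
    match_run = 0

    def flush_match():
        nonlocal match_run
        if match_run:
            ops.append(("match", match_run, None))
            match_run = 0

    # extend first anchor
    prev_q, prev_t = q0, t0
    match_run = k
    qe, te = q0 + k, t0 + k
    for qa, ta, _ in chain[1:]:
        dq, dt = qa - prev_q, ta - prev_t
        if dq == dt and 0 < dq <= k:
            match_run += dq
            qe, te = qa + k, ta + k
            prev_q, prev_t = qa, ta
            continue
        if qa < qe or ta < te:
            # off-diagonal overlap: clip the current match run back
            clip = max(qe - qa, te - ta)
            clip = min(clip, match_run)
            match_run -= clip
            qe -= clip
            te -= clip
            if qa < qe or ta < te:
                continue  # anchor incompatible even after clipping; drop it
        if qa - qe > params.max_gap or ta - te > params.max_gap:
            # break block here (caller recurses); emit unaligned pair
            pass
        flush_match()
        gap_ops = extend_align(qseq[qe:qa], tseq[te:ta], params.band, params)
        for op in gap_ops:
            if op[0] == "match":
                match_run += op[1]
                flush_match()
            else:
                ops.append(op)
        match_run = k
        qe, te = qa + k, ta + k
        prev_q, prev_t = qa, ta
    flush_match()
    ops = _coalesce([(k_, n_, a_) for k_, n_, a_ in ops])

    qspan = sum(n for kd, n, _ in ops if kd in ("match", "sub", "ins"))
    tspan = sum(n for kd, n, _ in ops if kd in ("match", "sub", "del"))
    # forward-query coordinates of the block
    if strand == "+":
        q_start = qoff + q0
    else:
        # q0 is in the revcomp frame of the (whole) query segment
        q_start = qoff + (len(qseq) - (q0 + qspan))
    matched = sum(n for kd, n, _ in ops if kd == "match")
    block = AlignmentBlock(
        query=GenomeInterval(qname, q_start, q_start + qspan, strand),
        target=GenomeInterval(tname, toff + t0, toff + t0 + tspan, "+"),
        strand=strand,
        ops=ops,
        score=matched,
    )
    block.validate()
    return block


def align_contigs(qname: str, qseq: str, tname: str, tseq: str,
                  params: AlignParams | None = None):
    """Align one query contig to one target contig; returns blocks
    (possibly several: one per N-split segment per strand chain)."""
    p = params or AlignParams()
    blocks = []
    for toff, tseg in _split_segments(tseq, p.n_split):
        for qoff, qseg in _split_segments(qseq, p.n_split):
            if len(qseg) < p.k or len(tseg) < p.k:
                continue
            anchors = find_anchors(qseg, tseg, p.k)
            for strand in ("+", "-"):
                sub = [a for a in anchors if a[2] == strand]
                chain = chain_anchors(sub)
                if len(chain) < p.min_chain_anchors:
                    continue
                qs = qseg if strand == "+" else revcomp(qseg)
                blocks.append(_chain_to_block(
                    chain, qs, tseg, qname, tname, len(qseg), strand,
                    qoff, toff, p))
    return blocks


def align_genomes(query_assembly: Assembly, target_assembly: Assembly,
                  params: AlignParams | None = None):
    """Align every query contig against every target contig; blocks sorted
    by target coordinate. Identical inputs yield one full-length block per
    contig with identity 1.0."""
    p = params or AlignParams()
    blocks = []
    for tname, tseq in target_assembly.sequences.items():
        for qname, qseq in query_assembly.sequences.items():
            blocks.extend(align_contigs(qname, qseq, tname, tseq, p))
    blocks.sort(key=lambda b: (b.target.contig, b.target.start))
    return blocks


def select_primary(blocks):
    """Resolve query/target overlaps greedily by descending score
    (ties: smaller target coordinate), yielding a one-to-one block set."""
    ranked = sorted(blocks, key=lambda b: (-b.score, b.target.contig,
                                           b.target.start))
    kept = []
    for b in ranked:
        clash = any(
            b.query.overlaps(k.query) or b.target.overlaps(k.target)
            for k in kept
        )
        if not clash:
            kept.append(b)
    kept.sort(key=lambda b: (b.target.contig, b.target.start))
    return kept


# ---------------------------------------------------------------------------
# PAF bridge
# ---------------------------------------------------------------------------


def paf_to_blocks(records: list[PafRecord]):
    """Convert PAF records with cs tags into AlignmentBlocks."""
    blocks = []
    for r in records:
        ops = r.ops
        if ops is None:
            raise ValueError(f"PAF record {r.qname}->{r.tname} lacks a cs tag")
        matched = sum(n for k, n, _ in ops if k == "match")
        b = AlignmentBlock(
            query=GenomeInterval(r.qname, r.qstart, r.qend, r.strand),
            target=GenomeInterval(r.tname, r.tstart, r.tend, "+"),
            strand=r.strand,
            ops=ops,
            score=matched,
        )
        b.validate()
        blocks.append(b)
    blocks.sort(key=lambda b: (b.target.contig, b.target.start))
    return blocks


def blocks_to_paf(blocks, query_assembly: Assembly,
                  target_assembly: Assembly) -> list[str]:
    """Emit PAF lines (cs long form) for AlignmentBlocks."""
    from .io import format_cs_long

    lines = []
    for b in blocks:
        tseq = target_assembly.sequences[b.target.contig]
        cs = format_cs_long(
            b.ops, lambda off, ln, s=tseq, t0=b.target.start: s[t0 + off:t0 + off + ln])
        matched = sum(n for k, n, _ in b.ops if k == "match")
        total = sum(n for k, n, _ in b.ops)
        lines.append("\t".join(str(x) for x in [
            b.query.contig, query_assembly.contig_length(b.query.contig),
            b.query.start, b.query.end, b.strand,
            b.target.contig, target_assembly.contig_length(b.target.contig),
            b.target.start, b.target.end, matched, total, 60,
            "cs:Z:" + cs,
        ]))
    return lines
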