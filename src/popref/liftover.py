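"""UCSC chain construction and interval/annotation liftover.

Chains are built either from AlignmentBlocks (genome-to-genome) or from
the CoordinateMap produced when major alleles are applied to a backbone
(backbone-to-consensus). Chain semantics follow the UCSC spec: the header
carries target (t) and query (q) frames, each data line is
``size dt dq`` with the last line a bare size; '-' strand query
coordinates are expressed in the reversed frame. Chain score is the
number of aligned bases (documented, not semantically load-bearing).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .io import FormatError
from .consensus import CoordinateMap


@dataclass
class ChainRecord:
    score: int
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    blocks: list = field(default_factory=list)  # (size, dt, dq); last (size, None, None)
    t_strand: str = "+"

    def validate(self):
        tsum = sum(s for s, _, _ in self.blocks) + \
            sum(dt for _, dt, _ in self.blocks if dt is not None)
        qsum = sum(s for s, _, _ in self.blocks) + \
            sum(dq for _, _, dq in self.blocks if dq is not None)
        if tsum != self.t_end - self.t_start:
            raise ValueError(f"chain {self.chain_id}: target span {tsum} != "
                             f"{self.t_end - self.t_start}")
        if qsum != self.q_end - self.q_start:
            raise ValueError(f"chain {self.chain_id}: query span {qsum} != "
                             f"{self.q_end - self.q_start}")
        if self.blocks and (self.blocks[-1][1] is not None
                            or self.blocks[-1][2] is not None):
            raise ValueError("last chain block must have no dt/dq")


def blocks_to_chain(blocks=None, coordinate_map: CoordinateMap | None = None,
                    q_sizes: dict | None = None,
                    t_sizes: dict | None = None) -> list[ChainRecord]:
    """Build ChainRecords from AlignmentBlocks or a CoordinateMap.

    For AlignmentBlocks the target is the chain target; match/sub runs
    become chain blocks, del ops become dt, ins ops dq. '-' strand
    queries are expressed in the reversed frame per the UCSC spec (the
    block walks the target forward and the reverse-complemented query
    forward, which is exactly the chain convention).

    For a CoordinateMap the backbone is the target and the consensus the
    query; identity segments become chain blocks.
    """
    chains: list[ChainRecord] = []
    cid = 0
    if blocks is not None:
        _check_no_overlap(blocks)
        for b in sorted(blocks, key=lambda b: (b.target.contig, b.target.start)):
            cid += 1
            cblocks = []
            size = dt = dq = 0
            for kind, length, _ in b.ops:
                if kind in ("match", "sub"):
                    if (dt or dq) and size:
                        cblocks.append((size, dt, dq))
                        size = dt = dq = 0
                    size += length
                elif kind == "del":
                    dt += length
                elif kind == "ins":
                    dq += length
            if size:
                cblocks.append((size, None, None))
            elif cblocks:
                s, _, _ = cblocks.pop()
                cblocks.append((s, None, None))
            t_size = t_sizes[b.target.contig] if t_sizes else b.target.end
            q_size = q_sizes[b.query.contig] if q_sizes else b.query.end
            if b.strand == "+":
                q_start, q_end = b.query.start, b.query.end
            else:
                q_start = q_size - b.query.end
                q_end = q_size - b.query.start
            rec = ChainRecord(
                score=b.score, t_name=b.target.contig, t_size=t_size,
                t_start=b.target.start, t_end=b.target.end,
                q_name=b.query.contig, q_size=q_size, q_strand=b.strand,
                q_start=q_start, q_end=q_end, chain_id=cid, blocks=cblocks)
            rec.validate()
            chains.append(rec)
        return chains

    if coordinate_map is None:
        raise ValueError("need blocks or coordinate_map")
    for contig, segs in coordinate_map.segments.items():
        if not segs:
            continue
        cid += 1
        b_len, c_len = coordinate_map.lengths.get(
            contig, (segs[-1][1], segs[-1][2] + segs[-1][1] - segs[-1][0]))
        cblocks = []
        aligned = 0
        for i, (b_start, b_end, c_start) in enumerate(segs):
            size = b_end - b_start
            aligned += size
            if i + 1 < len(segs):
                nb, _, nc = segs[i + 1][0], segs[i + 1][1], segs[i + 1][2]
                dt = nb - b_end
                dq = nc - (c_start + size)
                cblocks.append((size, dt, dq))
            else:
                cblocks.append((size, None, None))
        rec = ChainRecord(
            score=aligned, t_name=contig, t_size=b_len,
            t_start=segs[0][0], t_end=segs[-1][1],
            q_name=contig, q_size=c_len, q_strand="+",
            q_start=segs[0][2], q_end=segs[-1][2] + segs[-1][1] - segs[-1][0],
            chain_id=cid, blocks=cblocks)
        rec.validate()
        chains.append(rec)
    return chains


def _check_no_overlap(blocks):
    seen = sorted(blocks, key=lambda b: (b.target.contig, b.target.start))
    for a, b in zip(seen, seen[1:]):
        if a.target.overlaps(b.target):
            raise ValueError(
                f"overlapping input blocks on {a.target.contig}: "
                f"{a.target.start}-{a.target.end} vs {b.target.start}-{b.target.end}")


def write_chain(chains, path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            c.validate()
            fh.write(f"chain {c.score} {c.t_name} {c.t_size} {c.t_strand} "
                     f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} "
                     f"{c.q_strand} {c.q_start} {c.q_end} {c.chain_id}\n")
            for size, dt, dq in c.blocks[:-1]:
                fh.write(f"{size}\t{dt}\t{dq}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")


def read_chain(path) -> list:
    chains = []
    cur = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                cur = None
                continue
            if line.startswith("chain"):
                f = line.split()
                if len(f) != 13:
                    raise FormatError(f"{path}:{lineno}: bad chain header")
                cur = ChainRecord(
                    score=int(f[1]), t_name=f[2], t_size=int(f[3]),
                    t_strand=f[4], t_start=int(f[5]), t_end=int(f[6]),
                    q_name=f[7], q_size=int(f[8]), q_strand=f[9],
                    q_start=int(f[10]), q_end=int(f[11]), chain_id=int(f[12]))
                chains.append(cur)
            else:
                f = line.split()
                if cur is None:
                    raise FormatError(f"{path}:{lineno}: data before header")
                if len(f) == 3:
                    cur.blocks.append((int(f[0]), int(f[1]), int(f[2])))
                elif len(f) == 1:
                    cur.blocks.append((int(f[0]), None, None))
                else:
                    raise FormatError(f"{path}:{lineno}: bad chain data line")
    for c in chains:
        c.validate()
    return chains


# ---------------------------------------------------------------------------
# lifting
# ---------------------------------------------------------------------------


class ChainIndex:
    """Per-target-contig sorted index of aligned chain blocks for point
    lifting."""

    def __init__(self, chains):
        # entries: (t_start, t_end, q_start_in_+frame_walk, chain)
        self.blocks: dict[str, list] = {}
        for c in chains:
            t = c.t_start
            q = c.q_start  # walk coordinate in the (possibly reversed) q frame
            for size, dt, dq in c.blocks:
                self.blocks.setdefault(c.t_name, []).append((t, t + size, q, c))
                t += size + (dt or 0)
                q += size + (dq or 0)
        for v in self.blocks.values():
            v.sort()
        self.starts = {k: [b[0] for b in v] for k, v in self.blocks.items()}

    def lift_point(self, contig: str, pos: int, nearest: bool = False):
        """Lift one target point. Returns (q_contig, q_pos, strand) or None.

        ``nearest=True`` snaps a point inside a gap to the closest block
        edge (used for partial interval lifts). '-' strand results are
        converted back to forward-query coordinates.
        """
        entries = self.blocks.get(contig)
        if not entries:
            return None
        i = bisect.bisect_right(self.starts[contig], pos) - 1
        cand = None
        if i >= 0:
            t0, t1, q0, c = entries[i]
            if t0 <= pos < t1:
                cand = (q0 + (pos - t0), c)
            elif nearest:
                cand = (q0 + (t1 - 1 - t0), c)  # snap left edge
        if cand is None and nearest and i + 1 < len(entries):
            t0, t1, q0, c = entries[i + 1]
            cand = (q0, c)
        if cand is None:
            return None
        qw, c = cand
        if c.q_strand == "+":
            return (c.q_name, qw, "+")
        return (c.q_name, c.q_size - 1 - qw, "-")


def lift_interval(chains, interval, min_overlap: float = 1.0):
    """Lift a 0-based half-open interval through chains.

    Returns (status, lifted GenomeInterval | None) with status in
    {"exact", "partial", "unmapped"}: fully inside aligned blocks ->
    exact; spanning gaps with aligned fraction >= min_overlap -> lifting
    each end through the nearest block -> partial; less -> unmapped.
    """
    from .io import GenomeInterval

    index = chains if isinstance(chains, ChainIndex) else ChainIndex(chains)
    contig, start, end = interval.contig, interval.start, interval.end
    if end <= start:
        raise ValueError("malformed interval")
    entries = index.blocks.get(contig, [])
    covered = 0
    for t0, t1, _, _ in entries:
        covered += max(0, min(end, t1) - max(start, t0))
    frac = covered / (end - start)
    if covered == 0:
        return "unmapped", None
    a = index.lift_point(contig, start, nearest=True)
    b = index.lift_point(contig, end - 1, nearest=True)
    if a is None or b is None or a[0] != b[0] or a[2] != b[2]:
        return "unmapped", None
    strand = a[2]
    if strand == "+":
        lo, hi = a[1], b[1] + 1
    else:
        lo, hi = b[1], a[1] + 1
    if hi <= lo:
        return "unmapped", None
    status = "exact" if frac >= 1.0 else (
        "partial" if frac >= min_overlap else "unmapped")
    if status == "unmapped":
        return "unmapped", None
    return status, GenomeInterval(a[0], lo, hi, strand)


def lift_annotation(features, chains, policy: str = "strict",
                    min_overlap: float = 0.95):
    """Lift BED rows or Gff3Features through chains.

    GFF3: feature groups are tied by ID/Parent attributes; under the
    strict policy a group with any rejected member is rejected whole.
    Strand is flipped on '-' chains. Returns (lifted, rejects) where
    rejects carry (feature, reason).
    """
    from .io import Gff3Feature, GenomeInterval

    index = chains if isinstance(chains, ChainIndex) else ChainIndex(chains)
    lifted, rejects = [], []

    def lift_one(seqid, start0, end0):
        status, iv = lift_interval(index, GenomeInterval(seqid, start0, end0),
                                   min_overlap=min_overlap)
        if status == "unmapped" or (policy == "strict" and status != "exact"):
            return None, status
        return iv, status

    gff = [f for f in features if isinstance(f, Gff3Feature)]
    if gff:
        # group by root: a feature's root is its topmost Parent chain
        parent = {f.attr.get("ID", id(f)): f.attr.get("Parent") for f in gff}

        def root_of(f):
            key = f.attr.get("ID", id(f))
            seen = set()
            while parent.get(key) is not None and key not in seen:
                seen.add(key)
                key = parent[key]
            return key

        groups: dict = {}
        for f in gff:
            groups.setdefault(root_of(f), []).append(f)
        for _root, members in groups.items():
            results = []
            failure = None
            for f in members:
                iv, status = lift_one(f.seqid, f.start - 1, f.end)
                if iv is None:
                    failure = (f, status)
                    break
                results.append((f, iv))
            if failure is not None:
                rejects.extend((f, failure[1]) for f in members)
                continue
            for f, iv in results:
                strand = f.strand
                if iv.strand == "-" and strand in ("+", "-"):
                    strand = "+" if strand == "-" else "-"
                lifted.append(Gff3Feature(
                    iv.contig, f.source, f.ftype, iv.start + 1, iv.end,
                    f.score, strand, f.phase, f.attributes))
        lifted.sort(key=lambda f: (f.seqid, f.start))
        return lifted, rejects

    for row in features:  # BED tuples
        seqid, start, end = row[0], row[1], row[2]
        iv, status = lift_one(seqid, start, end)
        if iv is None:
            rejects.append((row, status))
            continue
        rest = list(row[3:])
        if len(rest) >= 3 and iv.strand == "-" and rest[2] in ("+", "-"):
            rest[2] = "+" if rest[2] == "-" else "-"
        lifted.append(tuple([iv.contig, iv.start, iv.end] + rest))
    lifted.sort(key=lambda r: (r[0], r[1]))
    return lifted, rejects
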