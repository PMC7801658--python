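"""Majority-vote allele substitution.

Variants are extracted from one-to-one alignment blocks of each input
assembly against a shared backbone, normalized (left-aligned,
parsimonious), grouped by site, and voted: an allele supported by at
least ``min_share`` of the N assemblies (default ⌊N/2⌋+1, i.e. 2 of 3)
replaces the backbone allele. Sites where several alleles are observed
but none reaches the share are tie sites and resolved by a seeded
uniform random choice among the alleles the assemblies actually carry
(an assembly with no variant at the site votes for the backbone allele).
Applying the winning set yields the consensus sequence plus a
CoordinateMap that tracks every length change for liftover.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Assembly

SV_MIN_LEN = 51  # |len(ref) - len(alt)| at or above this is an SV


@dataclass
class VariantRecord:
    """A normalized SNV/indel/SV against the backbone (VCF-style 1-based
    pos, left-anchored for indels)."""

    contig: str
    pos: int
    ref: str
    alt: str
    support: set = field(default_factory=set)
    tie: bool = False
    sv: bool | None = None

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("empty ref/alt")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.contig}:{self.pos}")
        if self.sv is None:
            self.sv = abs(len(self.ref) - len(self.alt)) >= SV_MIN_LEN

    @property
    def vtype(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    def key(self):
        return (self.contig, self.pos, self.ref, self.alt)

    def site(self):
        return (self.contig, self.pos)

    def end(self) -> int:
        """0-based half-open end of the ref span."""
        return self.pos - 1 + len(self.ref)


class CoordinateMap:
    """Monotone piecewise mapping backbone -> consensus coordinates.

    Stored per contig as sorted segments (b_start, b_end, c_start) of
    identity-copied runs; positions inside a replaced indel span (other
    than the anchor base) map to None.
    """

    def __init__(self):
        self.segments: dict[str, list[tuple[int, int, int]]] = {}
        self.lengths: dict[str, tuple[int, int]] = {}  # contig -> (b_len, c_len)

    def add_segment(self, contig: str, b_start: int, b_end: int, c_start: int):
        segs = self.segments.setdefault(contig, [])
        if segs and b_start < segs[-1][1]:
            raise ValueError("segments must be added in order")
        if b_end > b_start:
            segs.append((b_start, b_end, c_start))

    def map_point(self, contig: str, pos: int) -> int | None:
        """Lift a 0-based backbone position to the consensus (None when
        the position falls in replaced/deleted sequence)."""
        segs = self.segments.get(contig)
        if not segs:
            return None
        i = bisect.bisect_right(segs, (pos, float("inf"), float("inf"))) - 1
        if i < 0:
            return None
        b_start, b_end, c_start = segs[i]
        if b_start <= pos < b_end:
            return c_start + (pos - b_start)
        return None

    def validate(self):
        for contig, segs in self.segments.items():
            b_len, c_len = self.lengths.get(contig, (None, None))
            prev_b = prev_c = -1
            for b_start, b_end, c_start in segs:
                if b_start < prev_b or c_start < prev_c:
                    raise ValueError(f"{contig}: segments not monotone")
                prev_b, prev_c = b_end, c_start + (b_end - b_start)
            if b_len is not None and segs and segs[-1][1] > b_len:
                raise ValueError(f"{contig}: segment beyond backbone length")


# ---------------------------------------------------------------------------
# calling and normalization
# ---------------------------------------------------------------------------


def call_variants(blocks, backbone: Assembly, query_id: str,
                  sv_min_len: int = SV_MIN_LEN) -> list[VariantRecord]:
    """Turn every sub/ins/del op of one-to-one blocks into VariantRecords.

    Indels are emitted left-anchored on the preceding matched target base;
    an indel op with no preceding base inside the block is skipped (block
    edges are alignment artifacts, not callable variants). A ref that
    does not match the backbone sequence raises ValueError.
    """
    out = []
    for b in blocks:
        tseq = backbone.sequences[b.target.contig]
        tpos = b.target.start  # 0-based cursor on the target/backbone
        for kind, length, alt in b.ops:
            if kind == "match":
                tpos += length
            elif kind == "sub":
                ref = tseq[tpos:tpos + length]
                if len(ref) != length:
                    raise ValueError("sub op runs past backbone end")
                for off in range(length):
                    a = alt[off] if alt and len(alt) == length else alt
                    if ref[off] != a:
                        out.append(VariantRecord(
                            contig=b.target.contig, pos=tpos + off + 1,
                            ref=ref[off], alt=a, support={query_id},
                            sv=False))
                tpos += length
            elif kind == "ins":
                if tpos > b.target.start:
                    anchor = tseq[tpos - 1]
                    out.append(VariantRecord(
                        contig=b.target.contig, pos=tpos,
                        ref=anchor, alt=anchor + alt, support={query_id},
                        sv=length >= sv_min_len))
            elif kind == "del":
                deleted = tseq[tpos:tpos + length]
                if alt is not None and deleted != alt:
                    raise ValueError(
                        f"del op ref mismatch at {b.target.contig}:{tpos} "
                        f"({deleted[:10]!r} vs {alt[:10]!r})")
                if tpos > b.target.start:
                    anchor = tseq[tpos - 1]
                    out.append(VariantRecord(
                        contig=b.target.contig, pos=tpos,
                        ref=anchor + deleted, alt=anchor, support={query_id},
                        sv=length >= sv_min_len))
                tpos += length
    out.sort(key=lambda v: (v.contig, v.pos))
    return out


def normalize_variant(v: VariantRecord, backbone: Assembly,
                      sv_min_len: int = SV_MIN_LEN) -> VariantRecord:
    """Left-align and make parsimonious one variant (vcf-norm semantics).

    Idempotent; SNVs come back unchanged.
    """
    seq = backbone.sequences[v.contig]
    pos = v.pos - 1  # 0-based
    ref, alt = v.ref, v.alt
    if seq[pos:pos + len(ref)] != ref:
        raise ValueError(
            f"ref mismatch at {v.contig}:{v.pos}: {ref!r} vs backbone")
    # right-trim with left extension (left-aligns indels), then left-trim
    while ref and alt and ref[-1] == alt[-1]:
        if (len(ref) == 1 or len(alt) == 1) and pos == 0:
            break  # cannot left-extend past the contig start
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            pos -= 1
            ref, alt = seq[pos] + ref, seq[pos] + alt
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantRecord(contig=v.contig, pos=pos + 1, ref=ref, alt=alt,
                         support=set(v.support), tie=v.tie,
                         sv=abs(len(ref) - len(alt)) >= sv_min_len)


def normalize_variants(variants, backbone: Assembly,
                       sv_min_len: int = SV_MIN_LEN) -> list[VariantRecord]:
    out = [normalize_variant(v, backbone, sv_min_len) for v in variants]
    out.sort(key=lambda v: (v.contig, v.pos))
    return out


def split_multiallelic(variants):
    """Merge identical records (union of support) and register sites with
    >= 2 distinct alleles.

    Returns (biallelic records, registry) where registry maps site ->
    sorted list of distinct (ref, alt) alleles at that site.
    """
    by_key: dict[tuple, VariantRecord] = {}
    for v in variants:
        k = v.key()
        if k in by_key:
            by_key[k].support |= v.support
        else:
            by_key[k] = VariantRecord(contig=v.contig, pos=v.pos, ref=v.ref,
                                      alt=v.alt, support=set(v.support),
                                      tie=v.tie, sv=v.sv)
    records = sorted(by_key.values(), key=lambda v: (v.contig, v.pos, v.ref, v.alt))
    registry: dict[tuple, list] = {}
    by_site: dict[tuple, list] = {}
    for v in records:
        by_site.setdefault(v.site(), []).append((v.ref, v.alt))
    for site, alleles in by_site.items():
        if len(alleles) >= 2:
            registry[site] = sorted(alleles)
    return records, registry


# ---------------------------------------------------------------------------
# voting
# ---------------------------------------------------------------------------


@dataclass
class TieSite:
    contig: str
    pos: int
    candidates: list  # list of (ref, alt); alt == ref marks the backbone allele
    supports: dict    # (ref, alt) -> support count


@dataclass
class VoteResult:
    major: list  # VariantRecords meeting min_share
    ties: list   # TieSites
    dropped: list  # records observed in fewer than min_share assemblies, no tie


def vote_major_alleles(variants_per_assembly: dict[str, list],
                       n_assemblies: int | None = None,
                       min_share: int | None = None,
                       include_backbone_candidate: bool = False) -> VoteResult:
    """Vote normalized variant sets from N assemblies against one backbone.

    * allele with support >= min_share (default ⌊N/2⌋+1) -> major set
    * site with >= 2 observed alleles, all below min_share -> tie site;
      candidates are the alleles the assemblies carry, including the
      backbone allele once for every assembly with no variant there
    * site with a single below-share allele -> backbone retained
    """
    n = n_assemblies if n_assemblies is not None else len(variants_per_assembly)
    share = min_share if min_share is not None else n // 2 + 1
    if share > n:
        raise ValueError(f"min_share {share} > N {n}")

    merged = []
    for aid, recs in variants_per_assembly.items():
        for v in recs:
            merged.append(VariantRecord(
                contig=v.contig, pos=v.pos, ref=v.ref, alt=v.alt,
                support={aid}, sv=v.sv))
    records, _registry = split_multiallelic(merged)

    by_site: dict[tuple, list[VariantRecord]] = {}
    for v in records:
        by_site.setdefault(v.site(), []).append(v)

    major, ties, dropped = [], [], []
    for site in sorted(by_site):
        alleles = by_site[site]
        best = max(alleles, key=lambda v: (len(v.support), v.alt))
        if len(best.support) >= share:
            contenders = [v for v in alleles if len(v.support) == len(best.support)]
            if len(contenders) > 1:
                # two alleles both at/above share: genuine tie among them
                ties.append(TieSite(
                    contig=site[0], pos=site[1],
                    candidates=sorted((v.ref, v.alt) for v in contenders),
                    supports={(v.ref, v.alt): len(v.support) for v in alleles}))
            else:
                major.append(best)
                dropped.extend(v for v in alleles if v is not best)
        elif len(alleles) >= 2:
            n_var = len(set().union(*(v.support for v in alleles)))
            cands = sorted((v.ref, v.alt) for v in alleles)
            supports = {(v.ref, v.alt): len(v.support) for v in alleles}
            if n_var < n or include_backbone_candidate:
                # assemblies matching the backbone vote for its allele
                ref0 = alleles[0].ref[0]
                cands.append((ref0, ref0))
                supports[(ref0, ref0)] = n - n_var
                cands.sort()
            ties.append(TieSite(contig=site[0], pos=site[1],
                                candidates=cands, supports=supports))
        else:
            dropped.extend(alleles)
    return VoteResult(major=major, ties=ties, dropped=dropped)


def break_ties(tie_sites, seed: int):
    """Uniform seeded choice among each tie site's candidates.

    Returns (chosen records, decision table). A candidate whose alt equals
    its ref is the backbone allele: choosing it substitutes nothing but is
    still logged. Identical (sites, seed) give identical choices.
    """
    if seed is None:
        raise ValueError("break_ties requires an explicit seed")
    rng = np.random.default_rng(seed)
    chosen, log = [], []
    for site in sorted(tie_sites, key=lambda s: (s.contig, s.pos)):
        if not site.candidates:
            raise ValueError(f"empty candidate set at {site.contig}:{site.pos}")
        cands = sorted(site.candidates)
        pick = cands[int(rng.integers(len(cands)))]
        log.append({
            "contig": site.contig, "pos": site.pos,
            "candidates": ";".join(f"{r}>{a}" for r, a in cands),
            "chosen_ref": pick[0], "chosen_alt": pick[1],
            "is_backbone": pick[0] == pick[1],
        })
        if pick[0] != pick[1]:
            chosen.append(VariantRecord(
                contig=site.contig, pos=site.pos, ref=pick[0], alt=pick[1],
                support=set(), tie=True))
    return chosen, pd.DataFrame(log)


# ---------------------------------------------------------------------------
# applying the consensus
# ---------------------------------------------------------------------------


def apply_variants(backbone: Assembly, major_variants,
                   consensus_name: str = "consensus"):
    """Substitute every major allele into the backbone.

    Variants must be normalized and sorted; overlapping records keep the
    first by coordinate, the rest are dropped with a report line.
    Returns (consensus Assembly, CoordinateMap, dropped report DataFrame).
    """
    by_contig: dict[str, list[VariantRecord]] = {}
    for v in sorted(major_variants, key=lambda v: (v.contig, v.pos)):
        by_contig.setdefault(v.contig, []).append(v)

    cons = Assembly(consensus_name)
    cmap = CoordinateMap()
    dropped = []
    for contig, seq in backbone.sequences.items():
        parts = []
        cursor = 0  # backbone 0-based
        out_len = 0
        for v in by_contig.get(contig, []):
            start = v.pos - 1
            if start < cursor:
                dropped.append({"contig": contig, "pos": v.pos, "ref": v.ref,
                                "alt": v.alt, "reason": "overlaps_previous"})
                continue
            if seq[start:start + len(v.ref)] != v.ref:
                raise ValueError(
                    f"ref mismatch applying {contig}:{v.pos} {v.ref}>{v.alt}")
            parts.append(seq[cursor:start])
            cmap.add_segment(contig, cursor, start, out_len)
            out_len += start - cursor
            parts.append(v.alt)
            if len(v.ref) == len(v.alt) == 1:
                # SNV: position itself still maps 1:1
                cmap.add_segment(contig, start, start + 1, out_len)
            elif v.ref[0] == v.alt[0]:
                # indel: the anchor base maps
                cmap.add_segment(contig, start, start + 1, out_len)
            out_len += len(v.alt)
            cursor = start + len(v.ref)
        parts.append(seq[cursor:])
        cmap.add_segment(contig, cursor, len(seq), out_len)
        out_len += len(seq) - cursor
        cons.add_contig(contig, "".join(parts))
        cmap.lengths[contig] = (len(seq), out_len)
    cmap.validate()
    return cons, cmap, pd.DataFrame(dropped)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def support_summary(major_variants, n_assemblies: int) -> pd.DataFrame:
    """Counts and percentages of major variants by support level.

    ``major_variants`` may be an iterable of records or a mapping
    {support_level: count} (useful for published count tables).
    """
    if isinstance(major_variants, dict):
        counts = dict(major_variants)
    else:
        counts = {}
        for v in major_variants:
            lvl = len(v.support)
            counts[lvl] = counts.get(lvl, 0) + 1
    if not counts:
        raise ValueError("no variants to summarize")
    total = sum(counts.values())
    rows = [
        {"support": lvl, "count": counts.get(lvl, 0),
         "pct": 100.0 * counts.get(lvl, 0) / total}
        for lvl in range(1, n_assemblies + 1)
    ]
    return pd.DataFrame(rows)


def expected_tie_errors(tie_decisions, af_panel):
    """Expected number of erroneous random tie picks, judged against a
    population AF panel.

    Per site with m candidates: p_err = 1 - (1/m) if the panel-major
    allele at the site is among the candidates, else 1. Sites absent from
    the panel are counted separately and excluded from the sum.
    Returns (sum of p_err, per-site DataFrame).
    """
    rows = []
    total = 0.0
    n_absent = 0
    for site in tie_decisions:
        sites = af_panel.lookup(site.contig, site.pos)
        if not sites:
            n_absent += 1
            rows.append({"contig": site.contig, "pos": site.pos,
                         "p_err": None, "panel": "absent"})
            continue
        # panel-major allele: alt if af > 0.5 else ref
        top = max(sites, key=lambda s: s.af)
        major_allele = top.alt_allele if top.af > 0.5 else top.ref_allele
        m = len(site.candidates)
        present = any(alt == major_allele for _, alt in site.candidates)
        p_err = 1.0 - (1.0 / m if present else 0.0)
        total += p_err
        rows.append({"contig": site.contig, "pos": site.pos,
                     "p_err": p_err, "panel": "found"})
    df = pd.DataFrame(rows)
    df.attrs["n_absent"] = n_absent
    return total, df
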