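"""SV extraction, SURVIVOR-style merging, depth-based representativeness
statistics and concordance metrics.

Structural variants here are insertions/deletions with |length| >= 51 bp
called from genome-to-genome alignment. Merging treats two records as
identical when they share the SV type and both breakpoints lie within
1000 bp (inclusive) — the same rule as a merge with options
'1000 1 1 0 0 1'. The Δ-average-depth statistic compares the most
deviant per-position mean depth inside an SV window against the mean of
an equal-length upstream window; on a genome that carries the
population-shared allele the dip/pile-up disappears and |Δ| shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

SV_MIN_LEN = 51


@dataclass
class SVRecord:
    """0-based half-open SV on a reference frame. INS uses a 1-bp anchor
    interval (end == start + 1); DEL spans the deleted bases."""

    contig: str
    start: int
    end: int
    svtype: str  # {"INS", "DEL"}
    length: int
    source: str = ""

    def __post_init__(self):
        if self.svtype not in ("INS", "DEL"):
            raise ValueError(f"bad svtype {self.svtype!r}")
        if self.svtype == "INS" and self.end != self.start + 1:
            raise ValueError("INS records use a 1-bp anchor interval")
        if self.svtype == "DEL" and self.end - self.start != self.length:
            raise ValueError("DEL end - start must equal length")

    def breakpoints(self):
        """(bp1, bp2) used for merging: INS spans its inserted length on
        the inserted-sequence frame, DEL its deleted span."""
        if self.svtype == "INS":
            return (self.start, self.start + self.length)
        return (self.start, self.end)


def filter_svs(variants, sv_min_len: int = SV_MIN_LEN,
               source: str = "") -> list[SVRecord]:
    """Keep INS/DEL VariantRecords with |len(alt)-len(ref)| >= threshold
    and convert them to SVRecords (anchor-base conventions applied)."""
    out = []
    for v in variants:
        delta = len(v.alt) - len(v.ref)
        if abs(delta) < sv_min_len:
            continue
        start = v.pos  # first inserted/deleted base, 0-based (pos is the anchor)
        if delta > 0:
            out.append(SVRecord(v.contig, start, start + 1, "INS", delta,
                                source=source))
        else:
            out.append(SVRecord(v.contig, start, start - delta, "DEL", -delta,
                                source=source))
    return out


def merge_svs(call_sets, max_dist: int = 1000, type_aware: bool = True):
    """Single-linkage merge across call sets.

    ``call_sets`` is an ordered mapping set_id -> list[SVRecord] (or a
    list of (set_id, records) pairs). Two records link iff they share the
    contig, the svtype (when type_aware) and |Δbp1| <= max_dist and
    |Δbp2| <= max_dist. Returns a list of dicts with the representative
    record (from the first-listed set present in the cluster) and the
    support set of set ids.
    """
    if isinstance(call_sets, dict):
        pairs = list(call_sets.items())
    else:
        pairs = list(call_sets)
    set_order = {sid: i for i, (sid, _) in enumerate(pairs)}
    records = []
    for sid, recs in pairs:
        for r in recs:
            records.append((sid, r))
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    keyed = sorted(range(n), key=lambda i: (
        records[i][1].contig,
        records[i][1].svtype if type_aware else "",
        records[i][1].breakpoints()[0]))
    for a in range(len(keyed)):
        ia = keyed[a]
        ra = records[ia][1]
        bp1a, bp2a = ra.breakpoints()
        for b in range(a + 1, len(keyed)):
            ib = keyed[b]
            rb = records[ib][1]
            if rb.contig != ra.contig:
                break
            if type_aware and rb.svtype != ra.svtype:
                break
            bp1b, bp2b = rb.breakpoints()
            if bp1b - bp1a > max_dist:
                break
            if abs(bp2b - bp2a) <= max_dist:
                union(ia, ib)

    clusters: dict[int, list] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    merged = []
    for members in clusters.values():
        members.sort(key=lambda i: (set_order[records[i][0]],
                                    records[i][1].start))
        rep_sid, rep = records[members[0]]
        support = sorted({records[i][0] for i in members},
                         key=lambda s: set_order[s])
        merged.append({"record": rep, "support": support,
                       "n_records": len(members)})
    merged.sort(key=lambda d: (d["record"].contig, d["record"].start,
                               d["record"].svtype))
    return merged


def support_rate(primary_set, validation_set, max_dist: int = 1000,
                 type_aware: bool = True) -> float:
    """Fraction of primary records with >= 1 validation record matching
    under the merge criteria (same type, both breakpoints <= max_dist)."""
    if not primary_set:
        raise ValueError("empty primary set")
    by_contig: dict[str, list] = {}
    for r in validation_set:
        by_contig.setdefault(r.contig, []).append(r)
    matched = 0
    for p in primary_set:
        bp1, bp2 = p.breakpoints()
        ok = False
        for v in by_contig.get(p.contig, []):
            if type_aware and v.svtype != p.svtype:
                continue
            v1, v2 = v.breakpoints()
            if abs(v1 - bp1) <= max_dist and abs(v2 - bp2) <= max_dist:
                ok = True
                break
        if ok:
            matched += 1
    return matched / len(primary_set)


# ---------------------------------------------------------------------------
# depth statistics
# ---------------------------------------------------------------------------


def accessible_regions(depth_track: dict[str, np.ndarray],
                       min_depth: float = 5.0,
                       sd_mult: float = 2.0):
    """Maximal runs where depth is within [min_depth, mean + sd_mult*SD];
    mean/SD computed per contig. Returns {contig: [(start, end), ...]}."""
    out = {}
    for contig, vec in depth_track.items():
        vec = np.asarray(vec, float)
        hi = vec.mean() + sd_mult * vec.std()
        ok = (vec >= min_depth) & (vec <= hi)
        if not ok.any():
            out[contig] = []
            continue
        diff = np.diff(ok.astype(np.int8))
        starts = np.flatnonzero(diff == 1) + 1
        ends = np.flatnonzero(diff == -1) + 1
        if ok[0]:
            starts = np.concatenate([[0], starts])
        if ok[-1]:
            ends = np.concatenate([ends, [len(ok)]])
        out[contig] = list(zip(starts.tolist(), ends.tolist()))
    return out


def delta_avg_depth(depth_track: dict[str, np.ndarray], sv: SVRecord,
                    accessible: dict | None = None):
    """Signed Δ average depth for one SV.

    Reference value = mean depth of the upstream window [start-len, start)
    of the same length as the SV window [start, end); Δ = depth at the
    position of maximum |depth - reference| within the SV window, minus
    the reference. Returns (delta, reason) with delta None when skipped
    (window out of bounds or not fully accessible).
    """
    vec = depth_track.get(sv.contig)
    if vec is None:
        return None, "no_track"
    win_len = sv.end - sv.start
    up_start = sv.start - win_len
    if up_start < 0 or sv.end > len(vec):
        return None, "out_of_bounds"
    if accessible is not None:
        runs = accessible.get(sv.contig, [])
        need = (up_start, sv.end)
        if not any(s <= need[0] and need[1] <= e for s, e in runs):
            return None, "not_accessible"
    ref = float(np.mean(vec[up_start:sv.start]))
    window = np.asarray(vec[sv.start:sv.end], float)
    i = int(np.argmax(np.abs(window - ref)))
    return float(window[i] - ref), None


def delta_table(depth_track, svs, accessible=None) -> pd.DataFrame:
    rows = []
    for sv in svs:
        d, reason = delta_avg_depth(depth_track, sv, accessible)
        rows.append({"contig": sv.contig, "start": sv.start, "end": sv.end,
                     "svtype": sv.svtype, "length": sv.length,
                     "delta": d, "skip_reason": reason})
    return pd.DataFrame(rows, columns=["contig", "start", "end", "svtype",
                                       "length", "delta", "skip_reason"])


def paired_wilcoxon(deltas_a, deltas_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (classic Wilcoxon convention); the exact
    null distribution is used for n <= 25, the normal approximation with
    continuity correction beyond.
    """
    a = np.asarray(deltas_a, float)
    b = np.asarray(deltas_b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 5:
        raise ValueError("need n >= 5 pairs")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    method = "exact" if len(d) <= 25 else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                       alternative="two-sided", method=method)
    return float(res.pvalue)


def concordance_metrics(n_called: int | None = None,
                        n_called_confirmed: int | None = None,
                        n_true: int | None = None,
                        n_true_detected: int | None = None) -> dict:
    """PPV and sensitivity as percentages, one-decimal rounding.

    ppv = 100 * confirmed / called; sensitivity = 100 * detected / true.
    Pass None for the pair you don't need.
    """
    out = {}
    if n_called is not None:
        if n_called == 0:
            raise ZeroDivisionError("n_called is zero")
        out["ppv"] = round(100.0 * n_called_confirmed / n_called, 1)
    if n_true is not None:
        if n_true == 0:
            raise ZeroDivisionError("n_true is zero")
        out["sensitivity"] = round(100.0 * n_true_detected / n_true, 1)
    return out
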