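"""Independent reference implementations used as test oracles.

Each function here recomputes a quantity by brute force (exhaustive
enumeration or all-positions scanning) and must stay independent of the
implementation paths it checks.
"""

import itertools

import numpy as np

from popref.epcr import EpcrParams
from popref.io import revcomp


def leftmost_equivalent(seq, hap, pos0, lref, lalt):
    """Leftmost anchored parsimonious (pos, ref, alt) rebuilding ``hap``
    from ``seq`` — brute-force scan of a window, for indel normalization."""
    delta = lalt - lref
    lo = max(0, pos0 - 60)
    for p in range(lo, pos0 + max(lref, lalt) + 1):
        for lr in range(1, max(lref, lalt) + 61):
            la = lr + delta
            if la < 1 or p + lr > len(seq) or p + la > len(hap):
                continue
            ref = seq[p:p + lr]
            alt = hap[p:p + la]
            if ref == alt:
                continue
            if ref[0] != alt[0] and min(lr, la) > 1:
                continue
            if lr > 1 and la > 1 and (ref[-1] == alt[-1] or ref[1] == alt[1]):
                continue
            if seq[:p] + alt + seq[p + lr:] == hap:
                return (p + 1, ref, alt)
    raise AssertionError("oracle found no representation")


def brute_force_epcr(markers, assembly, p: EpcrParams):
    """All-positions e-PCR scan without candidate pruning."""
    hits = []
    for scaffold, seq in assembly.sequences.items():
        L = len(seq)
        for m in markers:
            if m.expected_size:
                lo = int(m.expected_size[0] * (1 - p.size_tolerance))
                hi = int(np.ceil(m.expected_size[1] * (1 + p.size_tolerance)))
            else:
                lo, hi = len(m.primer_fwd) + len(m.primer_rev), p.max_amplicon

            def sites(primer, anchor_end):
                out = []
                pl = len(primer)
                for i in range(L - pl + 1):
                    w = seq[i:i + pl]
                    mm = sum(a != b for a, b in zip(w, primer))
                    if mm > p.max_mismatch:
                        continue
                    k = p.three_prime_exact
                    if anchor_end and w[-k:] != primer[-k:]:
                        continue
                    if not anchor_end and w[:k] != primer[:k]:
                        continue
                    out.append((i, mm))
                return out

            for strand, lprim, rprim in (
                    ("+", m.primer_fwd, revcomp(m.primer_rev)),
                    ("-", m.primer_rev, revcomp(m.primer_fwd))):
                for lp, lmm in sites(lprim, True):
                    for rp, rmm in sites(rprim, False):
                        size = rp + len(rprim) - lp
                        if rp >= lp + len(lprim) and lo <= size <= hi:
                            mf, mr = (lmm, rmm) if strand == "+" else (rmm, lmm)
                            hits.append((m.marker_id, scaffold, lp,
                                         rp + len(rprim), strand, mf, mr))
    return sorted(hits)


def exact_wilcoxon_enumeration(d):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4
    total = extreme = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            extreme += 1
    return extreme / total
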