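"""Unfolded site-frequency spectrum of the alleles a consensus employs.

Given SNVs called between the consensus and an external reference, each
consensus ("non-reference-type") allele is looked up in a population AF
panel; the spectrum of those frequencies is right-skewed when the
consensus carries population-major alleles. Threshold summaries report
how many of the panel's near-fixed sites the consensus captures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AFPanel


@dataclass
class SiteAF:
    contig: str
    pos: int
    allele: str
    af: float | None
    status: str  # {"found", "missing", "allele_mismatch"}


@dataclass
class SFS:
    """Histogram over AF bins [0.00,0.01) ... [0.99,1.00) plus a closed
    top bin for af == 1.0 exactly (reported separately downstream)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_missing: int = 0
    n_allele_mismatch: int = 0

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum()) + self.n_missing + self.n_allele_mismatch


def employed_allele_freq(variants, af_panel: AFPanel) -> list[SiteAF]:
    """Look up each SNV's consensus allele in the panel.

    ``variants`` are SNV VariantRecords of the consensus against the
    external reference: ``alt`` is the allele the consensus employs.
    Statuses: found (panel has the site with that alt), missing (site not
    in panel), allele_mismatch (site present, different alt).
    """
    out = []
    for v in variants:
        if len(v.ref) != 1 or len(v.alt) != 1:
            continue
        sites = af_panel.lookup(v.contig, v.pos)
        if not sites:
            out.append(SiteAF(v.contig, v.pos, v.alt, None, "missing"))
            continue
        hit = next((s for s in sites if s.alt_allele == v.alt
                    and s.ref_allele == v.ref), None)
        if hit is None:
            out.append(SiteAF(v.contig, v.pos, v.alt, None, "allele_mismatch"))
        else:
            out.append(SiteAF(v.contig, v.pos, v.alt, hit.af, "found"))
    return out


def build_sfs(per_site_afs) -> SFS:
    """Bin found-site AFs at width 0.01; af == 1.0 is its own closed bin.

    Sites with af exactly 0 are kept in the first bin (alignment-edge
    artifacts show up there and are worth seeing, not dropping).
    Conservation: Σ counts + missing + mismatch == number of input sites.
    """
    edges = np.round(np.arange(0.0, 1.01, 0.01), 2)  # 101 edges; last bin [1.0]
    counts = np.zeros(101, dtype=int)
    n_missing = n_mismatch = 0
    for s in per_site_afs:
        if s.status == "missing":
            n_missing += 1
        elif s.status == "allele_mismatch":
            n_mismatch += 1
        else:
            if s.af >= 1.0:
                counts[100] += 1
            else:
                counts[min(int(s.af / 0.01), 99)] += 1
    return SFS(bin_edges=edges, counts=counts, n_missing=n_missing,
               n_allele_mismatch=n_mismatch)


def sfs_table(sfs: SFS) -> pd.DataFrame:
    lo = sfs.bin_edges
    hi = np.concatenate([sfs.bin_edges[1:], [1.0]])
    return pd.DataFrame({"af_lo": lo, "af_hi": hi, "count": sfs.counts})


DEFAULT_THRESHOLDS = (1.0, 0.99, 0.90)


def representativeness_summary(per_site_afs, panel_totals: dict,
                               thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Counts of consensus sites meeting each AF threshold and the
    percentage of the panel's sites at that threshold they capture.

    ``panel_totals`` maps threshold -> number of panel sites meeting it
    (an explicit input so the denominator's scope — genome-wide vs
    aligned-only — is the caller's choice). Threshold 1.0 means af == 1.0
    exactly; others mean af >= threshold. Percentages to two decimals.
    """
    rows = []
    found = [s.af for s in per_site_afs if s.status == "found"]
    for t in thresholds:
        if t >= 1.0:
            count = sum(1 for af in found if af >= 1.0)
            label = "= 1.0"
        else:
            count = sum(1 for af in found if af >= t)
            label = f">= {t:.2f}"
        total = panel_totals.get(t)
        if total in (None, 0):
            raise ValueError(f"panel total for threshold {t} missing or zero")
        rows.append({"threshold": label, "count": count,
                     "panel_total": total,
                     "pct_of_panel": round(100.0 * count / total, 2)})
    return pd.DataFrame(rows)


def panel_threshold_totals(af_panel: AFPanel,
                           thresholds=DEFAULT_THRESHOLDS) -> dict:
    """Count panel sites meeting each threshold (af == 1.0 for the 1.0
    class, af >= t otherwise)."""
    afs = [s.af for s in af_panel.by_key.values()]
    out = {}
    for t in thresholds:
        if t >= 1.0:
            out[t] = sum(1 for af in afs if af >= 1.0)
        else:
            out[t] = sum(1 for af in afs if af >= t)
    return out
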