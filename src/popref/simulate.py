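"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates, at desk scale, the situation the toolkit is
built for: a population whose variant catalogue (SNVs, small indels and
SVs with ~300 bp and ~6 kb insertion length modes) segregates at known
allele frequencies; several haploid assemblies sampled from it; scaffold
fragmentation; genetic/RH marker maps with primer pairs; and per-sample
read-depth tracks. Every output comes with its truth table so recovery
can be asserted exactly.

All randomness flows from one master seed through named substreams, so
any stage can be re-run reproducibly in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .consensus import VariantRecord, apply_variants, normalize_variant
from .io import (AFPanel, AFPanelSite, Assembly, MarkerRecord, revcomp,
                 write_af_panel, write_depth_track, write_fasta,
                 write_marker_table)
from .svdepth import SVRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG substream of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(name.encode()),)))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@dataclass
class CatalogEntry:
    variant: VariantRecord
    af: float  # population frequency of the alt allele


@dataclass
class PopulationTruth:
    ancestral: Assembly
    catalog: list = field(default_factory=list)  # CatalogEntry, coordinate-sorted

    def af_panel(self) -> AFPanel:
        """Panel view of the catalogue (matches it exactly by design)."""
        return AFPanel([
            AFPanelSite(e.variant.contig, e.variant.pos, e.variant.ref,
                        e.variant.alt, e.af)
            for e in self.catalog
        ])


@dataclass
class SimParams:
    """Population-simulation knobs (rates are per base)."""

    n_chrom: int = 2
    chrom_len: int = 50_000
    snv_rate: float = 1 / 800
    indel_rate: float = 1 / 8_000
    sv_rate: float = 1 / 25_000
    af_alpha: float = 0.8
    af_beta: float = 0.8
    sv_len_modes: tuple = ((300, 0.25, 0.7), (6000, 0.15, 0.3))  # (mode, lognorm sd, weight)
    min_site_gap: int = 60
    indel_max: int = 10


def simulate_population(params: SimParams | None = None, seed: int = 0,
                        **overrides) -> PopulationTruth:
    """Simulate an ancestral genome and its segregating variant catalogue.

    Sites are placed with exponential spacing (floor ``min_site_gap`` so
    normalized representations never collide); types are drawn by rate;
    alt allele frequencies follow Beta(af_alpha, af_beta) — a U-shaped
    frequency spectrum with both alleles segregating. SV lengths come
    from a two-mode log-normal mixture (~300 bp and ~6 kb). Deterministic
    under the seed; the exported AF panel matches the catalogue exactly.
    """
    p = params or SimParams()
    for k, v in overrides.items():
        setattr(p, k, v)
    rng_seq = substream(seed, "ancestral")
    rng_site = substream(seed, "sites")

    anc = Assembly("ancestral")
    catalog: list[CatalogEntry] = []
    total_rate = p.snv_rate + p.indel_rate + p.sv_rate
    for ci in range(p.n_chrom):
        contig = f"chr{ci + 1}"
        seq = random_sequence(rng_seq, p.chrom_len)
        anc.add_contig(contig, seq)
        if total_rate == 0:
            continue
        cursor = p.min_site_gap
        while True:
            gap = rng_site.exponential(1.0 / total_rate)
            cursor += int(gap) + p.min_site_gap
            if cursor >= p.chrom_len - p.min_site_gap:
                break
            u = rng_site.random() * total_rate
            pos0 = cursor  # 0-based anchor
            anchor = seq[pos0]
            if u < p.snv_rate:
                alt = "ACGT"[int(rng_site.integers(4))]
                while alt == anchor:
                    alt = "ACGT"[int(rng_site.integers(4))]
                ref_s, alt_s = anchor, alt
            else:
                if u < p.snv_rate + p.indel_rate:
                    length = int(rng_site.integers(1, p.indel_max + 1))
                else:
                    mode, sd, w1 = p.sv_len_modes[0]
                    modes = p.sv_len_modes
                    weights = np.array([m[2] for m in modes], float)
                    mi = int(rng_site.choice(len(modes), p=weights / weights.sum()))
                    mode, sd, _ = modes[mi]
                    length = max(51, int(round(rng_site.lognormal(
                        np.log(mode), sd))))
                if rng_site.random() < 0.5:  # insertion
                    ins = random_sequence(rng_site, length)
                    ref_s, alt_s = anchor, anchor + ins
                else:  # deletion
                    if pos0 + 1 + length >= p.chrom_len - p.min_site_gap:
                        break
                    ref_s = seq[pos0:pos0 + 1 + length]
                    alt_s = anchor
                    cursor += length
            if ref_s == alt_s:
                continue
            af = float(rng_site.beta(p.af_alpha, p.af_beta))
            v = VariantRecord(contig=contig, pos=pos0 + 1, ref=ref_s,
                              alt=alt_s, support=set())
            catalog.append(CatalogEntry(variant=v, af=af))
            cursor += len(ref_s)

    # normalize against the ancestral genome; drop any entry whose
    # normalized form collides with a neighbour (cannot happen with the
    # spacing floor, but guard anyway)
    normd: list[CatalogEntry] = []
    seen = set()
    for e in catalog:
        nv = normalize_variant(e.variant, anc)
        if nv.key() in seen:
            continue
        seen.add(nv.key())
        normd.append(CatalogEntry(variant=nv, af=e.af))
    normd.sort(key=lambda e: (e.variant.contig, e.variant.pos))
    return PopulationTruth(ancestral=anc, catalog=normd)


def sample_haploid_assembly(truth: PopulationTruth, seed: int,
                            name: str | None = None):
    """Draw one haploid: each catalogue site carries its alt allele with
    probability af, independently. Returns (Assembly, carried entries)."""
    rng = substream(seed, "haploid")
    carried = [e for e in truth.catalog if rng.random() < e.af]
    asm, _cmap, _dropped = apply_variants(
        truth.ancestral, [e.variant for e in carried],
        consensus_name=name or f"hap{seed}")
    return asm, carried


def fragment_into_scaffolds(assembly: Assembly, target_n50: int,
                            gap_len_range: tuple[int, int] = (50, 200),
                            seed: int = 0, min_fragment: int = 500,
                            invert_prob: float = 0.0):
    """Fragment contigs into scaffolds with unsequenced gaps between.

    Fragment lengths are exponential with mean target_n50/1.678 (the
    length-weighted median of an exponential is ≈1.678×its mean, so the
    realized N50 lands near the target). With ``invert_prob`` each
    scaffold is emitted reverse-complemented (placement strand '-') so
    orientation recovery can be exercised. Returns (scaffolded Assembly,
    placement table rows (scaffold, contig, start, end, strand)).
    """
    rng = substream(seed, "fragment")
    mean_len = max(min_fragment * 2, target_n50 / 1.678)
    out = Assembly(assembly.name + "_scaffolds")
    placements = []
    i = 0
    for contig, seq in assembly.sequences.items():
        cursor = 0
        while cursor < len(seq):
            frag = max(min_fragment, int(rng.exponential(mean_len)))
            end = min(len(seq), cursor + frag)
            if len(seq) - end < min_fragment:
                end = len(seq)
            name = f"scaf_{i:04d}"
            i += 1
            piece = seq[cursor:end]
            strand = "+"
            if invert_prob > 0 and rng.random() < invert_prob:
                piece = revcomp(piece)
                strand = "-"
            out.add_contig(name, piece)
            placements.append((name, contig, cursor, end, strand))
            if end >= len(seq):
                break
            gap = int(rng.integers(gap_len_range[0], gap_len_range[1] + 1))
            cursor = min(end + gap, len(seq))
    return out, placements


@dataclass
class MapSpec:
    map_id: str
    map_type: str  # {"genetic", "RH"}
    map_length: float = 100.0  # cM or cR span per chromosome
    noise_sd: float = 0.0      # positional noise, map units
    markers_per_chrom: int = 20


DEFAULT_MAP_SPECS = (
    MapSpec("gen1", "genetic", 100.0, 0.0, 20),
    MapSpec("rh1", "RH", 2000.0, 40.0, 20),
)


def simulate_marker_maps(truth: PopulationTruth, map_specs=DEFAULT_MAP_SPECS,
                         primer_len: int = 20,
                         amplicon_range: tuple[int, int] = (200, 500),
                         seed: int = 0) -> list[MarkerRecord]:
    """Place STS markers on the ancestral genome and position them on
    each map.

    Primers are exact substrings flanking a unique amplicon; marker loci
    avoid catalogued variant spans (with margin) so the same primers
    amplify on every sampled haploid. Genetic maps get low/zero noise,
    RH maps higher, per each spec's noise_sd. Map positions are the true
    genomic fraction scaled to map_length plus Gaussian noise, floored
    at 0.
    """
    rng = substream(seed, "markers")
    # forbidden intervals: variant ref spans + margin
    margin = 10
    forbidden: dict[str, list] = {}
    for e in truth.catalog:
        v = e.variant
        forbidden.setdefault(v.contig, []).append(
            (v.pos - 1 - margin, v.end() + margin))
    for iv in forbidden.values():
        iv.sort()

    def clean(contig, start, end):
        for s, e in forbidden.get(contig, []):
            if s < end and start < e:
                return False
            if s >= end:
                break
        return True

    genome = truth.ancestral
    markers: list[MarkerRecord] = []
    for spec in map_specs:
        for contig, seq in genome.sequences.items():
            L = len(seq)
            n = spec.markers_per_chrom
            slots = np.linspace(0.05, 0.95, n) * L
            for mi, center in enumerate(slots):
                placed = False
                for attempt in range(30):
                    amp_len = int(rng.integers(*amplicon_range))
                    start = int(center) + int(rng.integers(-L // (4 * n),
                                                           L // (4 * n) + 1))
                    start = max(0, min(L - amp_len, start))
                    end = start + amp_len
                    if not clean(contig, start, end):
                        continue
                    fwd = seq[start:start + primer_len]
                    rev = revcomp(seq[end - primer_len:end])
                    # amplicon (and primers) must be unique in the genome
                    occ = sum(s.count(fwd) + s.count(revcomp(fwd))
                              for s in genome.sequences.values())
                    occ2 = sum(s.count(seq[end - primer_len:end])
                               + s.count(rev)
                               for s in genome.sequences.values())
                    if occ != 1 or occ2 != 1:
                        continue
                    true_frac = (start + amp_len / 2) / L
                    pos = true_frac * spec.map_length
                    if spec.noise_sd > 0:
                        pos += rng.normal(0.0, spec.noise_sd)
                    markers.append(MarkerRecord(
                        marker_id=f"{spec.map_id}_{contig}_m{mi:03d}",
                        map_id=spec.map_id, map_type=spec.map_type,
                        linkage_group=contig,
                        map_position=max(0.0, float(pos)),
                        primer_fwd=fwd, primer_rev=rev,
                        expected_size=(amp_len, amp_len)))
                    placed = True
                    break
                if not placed:
                    continue
    return markers


# ---------------------------------------------------------------------------
# depth tracks
# ---------------------------------------------------------------------------


def simulate_depth_tracks(contig_lengths: dict[str, int], events,
                          mean_depth: float = 30.0, n_samples: int = 200,
                          seed: int = 0, pile_halfwidth: int = 50):
    """Mean per-position depth across samples on one genome frame.

    ``events`` is a list of (kind, contig, start, end, n_carriers):
    * ``absent``: n_carriers samples lack this frame sequence — they
      contribute zero depth over [start, end)
    * ``pile``: n_carriers samples have sequence this frame lacks — their
      reads pile into a window of 2×pile_halfwidth starting at the
      junction ``start`` (downstream, so an upstream reference window
      stays unaffected)

    Per-sample per-position depth is Poisson(mean_depth); the sum over
    present samples at a position is drawn as a single
    Poisson(n_present × mean_depth), which is the same distribution.
    Returns {contig: mean-depth float vector}.
    """
    rng = substream(seed, "depth")
    tracks = {}
    for contig, length in contig_lengths.items():
        present = np.full(length, n_samples, dtype=np.int64)
        extra = np.zeros(length, dtype=np.int64)
        for kind, c, start, end, carriers in events:
            if c != contig:
                continue
            if kind == "absent":
                present[max(0, start):min(length, end)] -= carriers
            elif kind == "pile":
                lo = max(0, start)
                hi = min(length, start + 2 * pile_halfwidth)
                extra[lo:hi] += carriers
        present = np.clip(present, 0, None)
        lam = (present + extra) * mean_depth
        total = rng.poisson(lam)
        tracks[contig] = total / n_samples
    return tracks


def make_depth_fixture(n_svs: int = 50, sv_carrier_af: float = 0.9,
                       mean_depth: float = 30.0, n_samples: int = 200,
                       chrom_len: int | None = None, seed: int = 0):
    """Paired backbone/consensus depth tracks around shared SVs.

    Builds a backbone with ``n_svs`` alternating DEL/INS SVs whose alt
    alleles segregate at ``sv_carrier_af`` (the consensus carries every
    alt, as a majority-vote genome would). Carriers are binomial per SV;
    on each frame every sample lacking the frame's local allele either
    drops out (missing sequence) or piles at the junction (extra
    sequence). Returns a dict with tracks and SVRecords on both frames.
    """
    rng = substream(seed, "depthfix")
    sv_len_choices = [60, 120, 300, 800]
    spacing = 4000
    length = chrom_len or (n_svs + 2) * spacing
    backbone = Assembly("backbone")
    backbone.add_contig("chr1", random_sequence(rng, length))

    variants = []
    for i in range(n_svs):
        pos0 = (i + 1) * spacing  # 0-based anchor
        anchor = backbone.sequences["chr1"][pos0]
        ln = int(sv_len_choices[i % len(sv_len_choices)])
        if i % 2 == 0:  # deletion of backbone sequence
            ref = backbone.sequences["chr1"][pos0:pos0 + 1 + ln]
            variants.append(VariantRecord("chr1", pos0 + 1, ref, anchor,
                                          support=set()))
        else:  # insertion absent from the backbone
            ins = random_sequence(rng, ln)
            variants.append(VariantRecord("chr1", pos0 + 1, anchor,
                                          anchor + ins, support=set()))
    consensus, cmap, _ = apply_variants(backbone, variants, "consensus")

    carriers = rng.binomial(n_samples, sv_carrier_af, size=n_svs)
    ev_back, ev_cons = [], []
    sv_back, sv_cons = [], []
    for i, v in enumerate(variants):
        ln = abs(len(v.alt) - len(v.ref))
        c = int(carriers[i])
        if v.vtype == "DEL":
            # backbone has the sequence; carriers lack it
            s, e = v.pos, v.pos + ln  # 0-based deleted span
            ev_back.append(("absent", "chr1", s, e, c))
            sv_back.append(SVRecord("chr1", s, e, "DEL", ln, "truth"))
            # consensus lacks it; non-carriers pile at the junction, and
            # the measurement window covers the junction region of the
            # same length as the deleted sequence
            junction = cmap.map_point("chr1", v.pos - 1) + 1
            ev_cons.append(("pile", "chr1", junction, junction + 1,
                            n_samples - c))
            sv_cons.append(SVRecord("chr1", junction, junction + ln,
                                    "DEL", ln, "truth"))
        else:
            # backbone lacks the insertion; carriers pile at the anchor
            ev_back.append(("pile", "chr1", v.pos, v.pos + 1, c))
            sv_back.append(SVRecord("chr1", v.pos, v.pos + 1, "INS", ln,
                                    "truth"))
            # consensus has it; non-carriers drop out over the insert
            start_c = cmap.map_point("chr1", v.pos - 1) + 1
            ev_cons.append(("absent", "chr1", start_c, start_c + ln,
                            n_samples - c))
            sv_cons.append(SVRecord("chr1", start_c, start_c + 1, "INS", ln,
                                    "truth"))
    track_back = simulate_depth_tracks(
        {"chr1": length}, ev_back, mean_depth, n_samples, seed=seed + 1)
    track_cons = simulate_depth_tracks(
        {"chr1": consensus.contig_length("chr1")}, ev_cons, mean_depth,
        n_samples, seed=seed + 2)
    return {
        "backbone": backbone, "consensus": consensus, "cmap": cmap,
        "track_backbone": track_back, "track_consensus": track_cons,
        "svs_backbone": sv_back, "svs_consensus": sv_cons,
        "carriers": carriers, "n_samples": n_samples,
    }


# ---------------------------------------------------------------------------
# fixture directories
# ---------------------------------------------------------------------------

PROFILES = {
    "tiny": SimParams(n_chrom=2, chrom_len=50_000),
    "desk": SimParams(n_chrom=2, chrom_len=500_000),
}


def make_fixture(profile_name: str, seed: int, outdir) -> dict:
    """Generate a complete, documented test dataset in ``outdir``.

    Writes the ancestral (external-reference) genome, three haploid
    assemblies (the first doubling as the backbone), a fragmented
    backbone with placement truth, marker tables, the AF panel, a depth
    track on the backbone frame, and truth tables. Returns the in-memory
    objects keyed by name.
    """
    if profile_name not in PROFILES:
        raise KeyError(f"unknown profile {profile_name!r}")
    import copy

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = copy.deepcopy(PROFILES[profile_name])
    truth = simulate_population(params, seed=seed)
    write_fasta(truth.ancestral, out / "ancestral.fa")
    panel = truth.af_panel()
    write_af_panel(panel, out / "af_panel.tsv")

    haploids = {}
    carried = {}
    for i, hap in enumerate(("hap_a", "hap_b", "hap_c")):
        asm, car = sample_haploid_assembly(truth, seed=seed * 10 + i, name=hap)
        haploids[hap] = asm
        carried[hap] = car
        write_fasta(asm, out / f"{hap}.fa")
    backbone = haploids["hap_a"]
    write_fasta(backbone, out / "backbone.fa")

    scaffolds, placements = fragment_into_scaffolds(
        backbone, target_n50=params.chrom_len // 6, seed=seed)
    write_fasta(scaffolds, out / "scaffolds.fa")
    with open(out / "scaffold_placements.tsv", "w") as fh:
        fh.write("scaffold\tcontig\tstart\tend\tstrand\n")
        for row in placements:
            fh.write("\t".join(str(x) for x in row) + "\n")

    markers = simulate_marker_maps(truth, seed=seed)
    write_marker_table(markers, out / "markers.tsv")

    svs = [(e.variant, e.af) for e in truth.catalog
           if abs(len(e.variant.alt) - len(e.variant.ref)) >= 51]
    rng = substream(seed, "fixture-depth")
    events = []
    for v, af in svs:
        ln = abs(len(v.alt) - len(v.ref))
        c = int(rng.binomial(200, af))
        if v.vtype == "DEL":
            events.append(("absent", v.contig, v.pos, v.pos + ln, c))
        else:
            events.append(("pile", v.contig, v.pos, v.pos + 1, c))
    lengths = {c: backbone.contig_length(c) for c in backbone.sequences}
    tracks = simulate_depth_tracks(lengths, events, seed=seed)
    write_depth_track(tracks, out / "depth_backbone.tsv")

    with open(out / "catalog.tsv", "w") as fh:
        fh.write("contig\tpos\tref\talt\taf\n")
        for e in truth.catalog:
            v = e.variant
            fh.write(f"{v.contig}\t{v.pos}\t{v.ref}\t{v.alt}\t{e.af:.6g}\n")
    for hap, car in carried.items():
        with open(out / f"carried_{hap}.tsv", "w") as fh:
            fh.write("contig\tpos\tref\talt\n")
            for e in car:
                v = e.variant
                fh.write(f"{v.contig}\t{v.pos}\t{v.ref}\t{v.alt}\n")

    return {"truth": truth, "haploids": haploids, "carried": carried,
            "backbone": backbone, "scaffolds": scaffolds,
            "placements": placements, "markers": markers, "panel": panel,
            "depth": tracks}
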