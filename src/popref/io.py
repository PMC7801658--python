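"""Readers and writers for every external format the toolkit touches.

All internal coordinates are 0-based half-open. Conversion to 1-based
happens only at the VCF/GFF boundaries. Soft-masking (lowercase in FASTA)
is preserved through I/O but ignored by every algorithm downstream: all
sequences are capitalized on read and the lowercase runs recorded as
intervals, re-emitted as lowercase on write.

Dialects implemented here (deliberately minimal, strictly validated):

* FASTA (via Bio.SeqIO)
* PAF with ``cs:Z`` tag in short (``:12*at``) or long (``=ACGT*at``) form
* VCF 4.2 subset: no genotypes; INFO keys ``SVTYPE``, ``SVLEN``, ``SUPP``
  (comma-separated assembly ids), ``TIE`` (1 marks randomly resolved sites)
* BED (0-based half-open), GFF3 (minimal 9-column), AGP 2.1
* TSV dialects for STS marker tables, allele-frequency panels and
  per-position depth tracks
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed input file; message carries file/line context."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"bad interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


class Assembly:
    """A named set of contigs over {A,C,G,T,N} with soft-mask intervals.

    ``sequences`` maps contig name -> uppercase sequence string;
    ``softmask`` maps contig name -> list of (start, end) lowercase runs.
    Contig order is preserved (insertion order of the dict).
    """

    def __init__(self, name: str, sequences: dict[str, str] | None = None,
                 softmask: dict[str, list[tuple[int, int]]] | None = None):
        self.name = name
        self.sequences: dict[str, str] = {}
        self.softmask: dict[str, list[tuple[int, int]]] = {}
        for contig, seq in (sequences or {}).items():
            self.add_contig(contig, seq, (softmask or {}).get(contig))

    def add_contig(self, contig: str, seq: str,
                   softmask: list[tuple[int, int]] | None = None) -> None:
        if contig in self.sequences:
            raise ValueError(f"duplicate contig name {contig!r}")
        if not seq:
            raise ValueError(f"empty sequence for contig {contig!r}")
        upper = seq.upper()
        bad = set(upper) - VALID_BASES
        if bad:
            raise ValueError(
                f"illegal character(s) {sorted(bad)} in contig {contig!r}"
            )
        mask = list(softmask) if softmask else []
        if not softmask and upper != seq:
            # derive soft-mask intervals from lowercase runs
            mask = [
                (m.start(), m.end())
                for m in re.finditer("[acgtn]+", seq)
            ]
        self.sequences[contig] = upper
        self.softmask[contig] = mask

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    def contig_length(self, contig: str) -> int:
        return len(self.sequences[contig])

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.sequences[contig][start:end]

    def __eq__(self, other) -> bool:  # sequence identity, mask included
        return (
            isinstance(other, Assembly)
            and self.sequences == other.sequences
            and {k: sorted(v) for k, v in self.softmask.items()}
            == {k: sorted(v) for k, v in other.softmask.items()}
        )


@dataclass
class MarkerRecord:
    """An STS marker: primer pair plus its position on one map.

    ``map_type`` distinguishes genetic maps (positions in cM) from
    radiation-hybrid maps (centirays); the two receive different anchoring
    weights downstream. ``expected_size`` is an optional (lo, hi) bp range
    for the amplicon.
    """

    marker_id: str
    map_id: str
    map_type: str  # {"genetic", "RH"}
    linkage_group: str
    map_position: float
    primer_fwd: str
    primer_rev: str
    expected_size: tuple[int, int] | None = None

    def __post_init__(self):
        if self.map_type not in ("genetic", "RH"):
            raise ValueError(f"map_type must be genetic|RH, got {self.map_type!r}")
        if len(self.primer_fwd) < 15 or len(self.primer_rev) < 15:
            raise ValueError(f"marker {self.marker_id}: primers must be >= 15 bp")
        if self.map_position < 0:
            raise ValueError(f"marker {self.marker_id}: negative map position")


@dataclass(frozen=True)
class AFPanelSite:
    """One site of a population allele-frequency panel (1-based pos)."""

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    af: float

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"panel site {self.contig}:{self.pos} ref == alt")
        if not (0.0 <= self.af <= 1.0):
            raise ValueError(f"panel site {self.contig}:{self.pos} af out of [0,1]")


class AFPanel:
    """Indexed collection of AFPanelSite, keyed by (contig, pos)."""

    def __init__(self, sites):
        self.by_key: dict[tuple[str, int, str, str], AFPanelSite] = {}
        self.by_pos: dict[tuple[str, int], list[AFPanelSite]] = {}
        for s in sites:
            key = (s.contig, s.pos, s.ref_allele, s.alt_allele)
            if key in self.by_key:
                raise ValueError(f"duplicate panel record {key}")
            self.by_key[key] = s
            self.by_pos.setdefault((s.contig, s.pos), []).append(s)

    def __len__(self):
        return len(self.by_key)

    def lookup(self, contig: str, pos: int) -> list[AFPanelSite]:
        return self.by_pos.get((contig, pos), [])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path, name: str | None = None) -> Assembly:
    """Read a FASTA file into an Assembly.

    Lowercase bases are uppercased and recorded as soft-masked intervals.
    Characters outside {A,C,G,T,N,a,c,g,t,n} raise FormatError.
    """
    path = Path(path)
    asm = Assembly(name or path.stem)
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        try:
            asm.add_contig(rec.id, str(rec.seq))
        except ValueError as e:
            raise FormatError(f"{path}: {e}") from e
    if n == 0:
        raise FormatError(f"{path}: empty or not FASTA")
    return asm


def write_fasta(assembly: Assembly, path, wrap: int = 60) -> None:
    """Write an Assembly to FASTA; soft-mask re-emitted as lowercase.

    ``wrap=0`` writes single-line sequences.
    """
    with open(path, "w") as fh:
        for contig, seq in assembly.sequences.items():
            chars = list(seq)
            for s, e in assembly.softmask.get(contig, []):
                chars[s:e] = seq[s:e].lower()
            out = "".join(chars)
            fh.write(f">{contig}\n")
            if wrap and wrap > 0:
                for i in range(0, len(out), wrap):
                    fh.write(out[i:i + wrap] + "\n")
            else:
                fh.write(out + "\n")


# ---------------------------------------------------------------------------
# PAF (+cs tag)
# ---------------------------------------------------------------------------


@dataclass
class PafRecord:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alnlen: int
    mapq: int
    tags: dict = field(default_factory=dict)

    @property
    def ops(self):
        """Expanded op list from the cs tag, or None when absent.

        Ops are (kind, length, alt) with kind in {match, sub, ins, del};
        ``alt`` carries the query base(s) for sub/ins, the deleted target
        bases for del, None for match.
        """
        cs = self.tags.get("cs")
        if cs is None:
            return None
        ops = parse_cs(cs)
        tspan = sum(n for k, n, _ in ops if k in ("match", "sub", "del"))
        qspan = sum(n for k, n, _ in ops if k in ("match", "sub", "ins"))
        if tspan != self.tend - self.tstart or qspan != self.qend - self.qstart:
            raise FormatError(
                f"cs tag span ({tspan} t / {qspan} q) inconsistent with "
                f"alignment {self.tname}:{self.tstart}-{self.tend} / "
                f"{self.qname}:{self.qstart}-{self.qend}"
            )
        return ops


_CS_TOKEN = re.compile(r"(=[A-Za-z]+|:[0-9]+|\*[a-zA-Z][a-zA-Z]|\+[A-Za-z]+|-[A-Za-z]+)")


def parse_cs(cs: str) -> list[tuple[str, int, str | None]]:
    """Expand a minimap2 cs tag (short or long form) into an op list.

    Adjacent same-kind ops are merged so the result is canonical:
    ``=AC*gt=T`` and ``:2*gt:1`` expand identically.
    """
    ops: list[tuple[str, int, str | None]] = []
    pos = 0
    for m in _CS_TOKEN.finditer(cs):
        if m.start() != pos:
            raise FormatError(f"cannot parse cs tag at offset {pos}: {cs[pos:pos+10]!r}")
        pos = m.end()
        tok = m.group(0)
        c = tok[0]
        if c == "=":
            _push(ops, "match", len(tok) - 1, None)
        elif c == ":":
            _push(ops, "match", int(tok[1:]), None)
        elif c == "*":
            _push(ops, "sub", 1, tok[2].upper())
        elif c == "+":
            _push(ops, "ins", len(tok) - 1, tok[1:].upper())
        elif c == "-":
            _push(ops, "del", len(tok) - 1, tok[1:].upper())
    if pos != len(cs):
        raise FormatError(f"cannot parse cs tag at offset {pos}: {cs[pos:pos+10]!r}")
    return ops


def _push(ops, kind, length, alt):
    """Append an op, merging with the previous one if same-kind."""
    if ops and ops[-1][0] == kind and kind in ("match", "ins", "del"):
        pk, pl, pa = ops.pop()
        length += pl
        if alt is not None or pa is not None:
            alt = (pa or "") + (alt or "")
    ops.append((kind, length, alt))


def read_paf(path) -> list[PafRecord]:
    """Read PAF records (>=12 tab-separated columns, optional cs:Z tag)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: PAF needs >=12 columns, got {len(cols)}")
            tags = {}
            for tag in cols[12:]:
                parts = tag.split(":", 2)
                if len(parts) == 3:
                    tags[parts[0]] = parts[2]
            try:
                rec = PafRecord(
                    qname=cols[0], qlen=int(cols[1]), qstart=int(cols[2]),
                    qend=int(cols[3]), strand=cols[4], tname=cols[5],
                    tlen=int(cols[6]), tstart=int(cols[7]), tend=int(cols[8]),
                    nmatch=int(cols[9]), alnlen=int(cols[10]), mapq=int(cols[11]),
                    tags=tags,
                )
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
            if "cs" in tags:
                rec.ops  # validates span consistency
            records.append(rec)
    return records


def format_cs_long(ops, target_seq_fn=None) -> str:
    """Emit a cs long-form string from an op list.

    ``target_seq_fn(offset, length)`` must return the matched target bases
    for match ops; if None, matches are emitted in short form (``:N``).
    """
    out = []
    toff = 0
    for kind, length, alt in ops:
        if kind == "match":
            if target_seq_fn is None:
                out.append(f":{length}")
            else:
                out.append("=" + target_seq_fn(toff, length))
            toff += length
        elif kind == "sub":
            ref = target_seq_fn(toff, 1) if target_seq_fn else "n"
            out.append(f"*{ref.lower()}{alt.lower()}")
            toff += 1
        elif kind == "ins":
            out.append("+" + alt.lower())
        elif kind == "del":
            ref = alt if alt else (target_seq_fn(toff, length) if target_seq_fn else "n" * length)
            out.append("-" + ref.lower())
            toff += length
    return "".join(out)


# ---------------------------------------------------------------------------
# marker table / AF panel / depth TSV
# ---------------------------------------------------------------------------

MARKER_COLUMNS = [
    "marker_id", "map_id", "map_type", "linkage_group", "map_position",
    "primer_fwd", "primer_rev", "expected_size",
]


def read_marker_table(path) -> list[MarkerRecord]:
    """Read the STS marker TSV dialect.

    Columns (header required, tab-separated): marker_id, map_id, map_type
    (genetic|RH), linkage_group, map_position, primer_fwd, primer_rev,
    expected_size ("lo-hi" bp range or empty).
    """
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        if header != MARKER_COLUMNS:
            raise FormatError(f"{path}: bad marker header {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != len(MARKER_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(MARKER_COLUMNS)} columns")
            size = None
            if cols[7]:
                lo, hi = cols[7].split("-")
                size = (int(lo), int(hi))
            try:
                records.append(MarkerRecord(
                    marker_id=cols[0], map_id=cols[1], map_type=cols[2],
                    linkage_group=cols[3], map_position=float(cols[4]),
                    primer_fwd=cols[5].upper(), primer_rev=cols[6].upper(),
                    expected_size=size,
                ))
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
    return records


def write_marker_table(markers, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MARKER_COLUMNS) + "\n")
        for m in markers:
            size = f"{m.expected_size[0]}-{m.expected_size[1]}" if m.expected_size else ""
            fh.write("\t".join([
                m.marker_id, m.map_id, m.map_type, m.linkage_group,
                repr(m.map_position), m.primer_fwd, m.primer_rev, size,
            ]) + "\n")


def read_af_panel(path) -> AFPanel:
    """Read the AF panel TSV: contig, pos (1-based), ref, alt, af."""
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            try:
                sites.append(AFPanelSite(
                    contig=cols[0], pos=int(cols[1]), ref_allele=cols[2],
                    alt_allele=cols[3], af=float(cols[4]),
                ))
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
    try:
        return AFPanel(sites)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def write_af_panel(panel: AFPanel, path) -> None:
    with open(path, "w") as fh:
        for s in panel.by_key.values():
            fh.write(f"{s.contig}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t{s.af:.6g}\n")


def read_depth_track(path) -> dict[str, np.ndarray]:
    """Read a bedGraph-like depth TSV (contig, start, end, depth) into
    per-contig float vectors. Rows must tile each contig without gaps."""
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            spans.setdefault(cols[0], []).append(
                (int(cols[1]), int(cols[2]), float(cols[3])))
    tracks = {}
    for contig, rows in spans.items():
        rows.sort()
        length = rows[-1][1]
        vec = np.zeros(length, dtype=float)
        cursor = 0
        for s, e, d in rows:
            if s != cursor:
                raise FormatError(f"{path}: depth rows for {contig} do not tile ({cursor} vs {s})")
            vec[s:e] = d
            cursor = e
        tracks[contig] = vec
    return tracks


def write_depth_track(tracks: dict[str, np.ndarray], path, decimals: int = 4) -> None:
    """Write per-contig depth vectors run-length encoded as bedGraph-like TSV."""
    with open(path, "w") as fh:
        for contig, vec in tracks.items():
            vals = np.round(np.asarray(vec, dtype=float), decimals)
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vals)]])
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{vals[s]:.{decimals}g}\n")


# ---------------------------------------------------------------------------
# BED / GFF3 / AGP
# ---------------------------------------------------------------------------


def read_bed(path) -> list[tuple]:
    """Read BED rows as (contig, start, end[, name[, score[, strand]]])."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            row = [cols[0], int(cols[1]), int(cols[2])] + cols[3:6]
            rows.append(tuple(row))
    return rows


def write_bed(rows, path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


@dataclass
class Gff3Feature:
    seqid: str
    source: str
    ftype: str
    start: int  # 1-based inclusive, per GFF3
    end: int
    score: str
    strand: str
    phase: str
    attributes: str

    @property
    def attr(self) -> dict[str, str]:
        out = {}
        for part in self.attributes.split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                out[k] = v
        return out


def read_gff3(path) -> list[Gff3Feature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
            feats.append(Gff3Feature(
                cols[0], cols[1], cols[2], int(cols[3]), int(cols[4]),
                cols[5], cols[6], cols[7], cols[8],
            ))
    return feats


def write_gff3(features, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write("\t".join([
                f.seqid, f.source, f.ftype, str(f.start), str(f.end),
                f.score, f.strand, f.phase, f.attributes,
            ]) + "\n")


def write_agp(rows, path) -> None:
    """Write AGP v2.1. ``rows`` are 9-tuples: W rows
    (object, obj_beg, obj_end, part, 'W', scaffold, comp_beg, comp_end, orient)
    and N rows (object, obj_beg, obj_end, part, 'N', gap_len, gap_type,
    linkage, evidence). Coordinates 1-based inclusive, per AGP."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_agp(path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: AGP needs 9 columns")
            rows.append(tuple(cols))
    return rows


# ---------------------------------------------------------------------------
# minimal VCF
# ---------------------------------------------------------------------------

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type (INS or DEL)">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">
##INFO=<ID=SUPP,Number=1,Type=String,Description="Comma-separated supporting assembly ids">
##INFO=<ID=TIE,Number=0,Type=Flag,Description="Allele chosen by seeded random tie-break">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf_min(variants, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write VariantRecord-like objects (contig, pos 1-based, ref, alt,
    support set, tie flag, sv flag/vtype) to the minimal VCF dialect."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        for line in VCF_HEADER.splitlines()[1:]:
            fh.write(line + "\n")
        for v in variants:
            info = []
            svlen = len(v.alt) - len(v.ref)
            if getattr(v, "sv", False):
                info.append(f"SVTYPE={'INS' if svlen > 0 else 'DEL'}")
                info.append(f"SVLEN={svlen}")
            supp = getattr(v, "support", None)
            if supp:
                info.append("SUPP=" + ",".join(sorted(supp)))
            if getattr(v, "tie", False):
                info.append("TIE")
            fh.write("\t".join([
                v.contig, str(v.pos), ".", v.ref, v.alt, ".", ".",
                ";".join(info) or ".",
            ]) + "\n")


def read_vcf_min(path):
    """Read the minimal VCF dialect back into VariantRecords."""
    from .consensus import VariantRecord  # local import to avoid a cycle

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise FormatError(f"{path}:{lineno}: VCF needs 8 columns")
            info = {}
            for part in cols[7].split(";"):
                if "=" in part:
                    k, v = part.split("=", 1)
                    info[k] = v
                elif part and part != ".":
                    info[part] = True
            support = set(info["SUPP"].split(",")) if "SUPP" in info else set()
            out.append(VariantRecord(
                contig=cols[0], pos=int(cols[1]), ref=cols[3], alt=cols[4],
                support=support, tie=bool(info.get("TIE", False)),
                sv="SVTYPE" in info,
            ))
    return out
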