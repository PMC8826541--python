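"""Readers and writers for every external format the scaffolder touches.

Contigs come in as FASTA, paired-read alignments as SAM/BAM or a documented
plain TSV dialect, genetic maps and library descriptions as TSV, and layouts
go out as AGP v2.1 plus gapped FASTA.  All internal coordinates are 0-based
half-open; AGP rows are converted to the 1-based inclusive convention the
format mandates.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class BaylinkError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(BaylinkError):
    """Malformed or invalid input file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contig:
    """An input assembly fragment: the atomic unit of scaffolding."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"contig {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ParseError(
                f"contig {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class MateAlignment:
    """One mate's placement: contig, 0-based leftmost position, strand, MAPQ."""

    contig_id: str
    pos: int
    strand: str  # '+' or '-'
    mapq: int
    aln_len: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ParseError(f"negative alignment position {self.pos}")
        if self.mapq < 0:
            raise ParseError(f"negative mapping quality {self.mapq}")
        if self.strand not in ("+", "-"):
            raise ParseError(f"bad strand {self.strand!r}")


@dataclass(frozen=True, slots=True)
class ReadPairAlignment:
    """Both mates of one read pair plus the library it came from."""

    pair_id: str
    library_id: str
    mate1: MateAlignment
    mate2: MateAlignment


@dataclass(frozen=True)
class Library:
    """A sequencing library with its declared insert-size profile.

    ``insert_mu``/``insert_sigma`` describe the outer distance between the two
    mate alignments of a pair; ``orientation`` is the expected relative mate
    orientation ('innie' = mates face each other, 'outie' = they face away).
    """

    id: str
    insert_mu: float
    insert_sigma: float
    orientation: str = "innie"
    read_len: int = 100
    weight_note: str = ""

    def __post_init__(self) -> None:
        if self.insert_mu <= 0 or self.insert_sigma <= 0 or self.read_len <= 0:
            raise ParseError(f"library {self.id!r}: non-positive size parameter")
        if self.orientation not in ("innie", "outie"):
            raise ParseError(f"library {self.id!r}: bad orientation")

    @property
    def is_bac(self) -> bool:
        return "bac" in self.weight_note.lower()


@dataclass(frozen=True)
class Marker:
    """A genetic-map marker with a centimorgan position and a placement handle.

    Either ``seq`` (located by exact sequence match) or ``contig_id``/``offset``
    (lifted through the contig's position in its layout); when both are given
    the coordinates take precedence.
    """

    id: str
    linkage_group: str
    cm: float
    seq: Optional[str] = None
    contig_id: Optional[str] = None
    offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cm < 0:
            raise ParseError(f"marker {self.id!r}: negative cM position")
        if self.seq is None and self.contig_id is None:
            raise ParseError(f"marker {self.id!r}: no sequence and no coordinates")


@dataclass
class GeneticMap:
    markers: list[Marker]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ParseError(f"duplicate marker ids {dup!r}")

    def linkage_groups(self) -> list[str]:
        return sorted({m.linkage_group for m in self.markers})

    def sorted_markers(self, linkage_group: str) -> list[Marker]:
        """cM-sorted view of one linkage group's markers."""
        return sorted(
            (m for m in self.markers if m.linkage_group == linkage_group),
            key=lambda m: (m.cm, m.id),
        )

    def __len__(self) -> int:
        return len(self.markers)


@dataclass(frozen=True)
class AgpRecord:
    """One AGP v2.1 row (1-based inclusive coordinates)."""

    object_id: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # 'W' contig, 'N' gap
    component_id: Optional[str] = None
    component_beg: Optional[int] = None
    component_end: Optional[int] = None
    orientation: Optional[str] = None
    gap_length: Optional[int] = None
    gap_type: Optional[str] = None
    linkage: Optional[str] = None
    evidence: Optional[str] = None


# layout parts are defined here (not in the scaffolder) so every writer and
# reader shares one representation without circular imports
@dataclass(frozen=True)
class LayoutPart:
    """One contig slot in a layout, with the gap that follows it (if any).

    ``gap_kind`` distinguishes paired-read-supported within-scaffold gaps
    ('paired') from fixed map-evidence gaps between anchored scaffolds ('map').
    ``join_posterior`` records the accepted link's posterior for later
    chimera surgery.
    """

    contig_id: str
    orientation: str  # '+' or '-'
    gap_after: Optional[float] = None
    gap_kind: str = "paired"
    join_posterior: Optional[float] = None


@dataclass
class ScaffoldLayout:
    """An ordered, oriented run of contigs with inter-contig gaps."""

    id: str
    parts: list[LayoutPart]
    provenance: list = field(default_factory=list)
    repeat_flag: bool = False

    def contig_ids(self) -> list[str]:
        return [p.contig_id for p in self.parts]

    def total_contig_bases(self, contigs: dict[str, Contig]) -> int:
        return sum(contigs[p.contig_id].length for p in self.parts)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_contigs(path: str | Path) -> dict[str, Contig]:
    """Parse a FASTA file into an id-keyed contig set.

    Sequences are upper-cased; duplicate ids or non-IUPAC characters are fatal.
    """
    path = Path(path)
    contigs: dict[str, Contig] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ParseError(f"{path}: duplicate contig id {rec.id!r}")
        contigs[rec.id] = Contig(rec.id, str(rec.seq).upper())
    if not contigs:
        raise ParseError(f"{path}: no FASTA records found")
    return contigs


def read_libraries(path: str | Path) -> dict[str, Library]:
    """Read a library-description TSV.

    Columns: id, insert_mu, insert_sigma, orientation, read_len, weight_note
    (the last two optional).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "insert_mu", "insert_sigma", "orientation"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing library columns {sorted(missing)}")
    libs: dict[str, Library] = {}
    for row in df.itertuples(index=False):
        if row.id in libs:
            raise ParseError(f"{path}: duplicate library id {row.id!r}")
        libs[row.id] = Library(
            id=row.id,
            insert_mu=float(row.insert_mu),
            insert_sigma=float(row.insert_sigma),
            orientation=row.orientation,
            read_len=int(getattr(row, "read_len", 100) or 100),
            weight_note=str(getattr(row, "weight_note", "") or ""),
        )
    return libs


ALIGNMENT_TSV_COLUMNS = [
    "pair_id", "lib",
    "ctg1", "pos1", "strand1", "mapq1", "len1",
    "ctg2", "pos2", "strand2", "mapq2", "len2",
]


def _validate_pair(
    pair: ReadPairAlignment,
    contigs: Optional[dict[str, Contig]],
) -> bool:
    """True if both mates land on known contigs within bounds."""
    if contigs is None:
        return True
    for mate in (pair.mate1, pair.mate2):
        ctg = contigs.get(mate.contig_id)
        if ctg is None:
            return False
        if mate.pos + mate.aln_len > ctg.length:
            return False
    return True


def _read_alignments_tsv(
    path: Path,
    libraries: dict[str, Library],
    contigs: Optional[dict[str, Contig]],
    stats: dict,
) -> list[ReadPairAlignment]:
    pairs: list[ReadPairAlignment] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "pair_id":
                continue
            if len(row) != len(ALIGNMENT_TSV_COLUMNS):
                raise ParseError(
                    f"{path}: expected {len(ALIGNMENT_TSV_COLUMNS)} columns, "
                    f"got {len(row)}: {row!r}"
                )
            (pid, lib, c1, p1, s1, q1, l1, c2, p2, s2, q2, l2) = row
            stats["pairs_read"] += 1
            if lib not in libraries:
                raise ParseError(f"{path}: unknown library {lib!r} for pair {pid!r}")
            pair = ReadPairAlignment(
                pid, lib,
                MateAlignment(c1, int(p1), s1, int(q1), int(l1)),
                MateAlignment(c2, int(p2), s2, int(q2), int(l2)),
            )
            if not _validate_pair(pair, contigs):
                stats["pairs_skipped_unknown_contig"] += 1
                continue
            pairs.append(pair)
    return pairs


def _read_alignments_sam(
    path: Path,
    libraries: dict[str, Library],
    contigs: Optional[dict[str, Contig]],
    stats: dict,
) -> list[ReadPairAlignment]:
    """Pair up primary SAM/BAM records by read name; RG tag selects the library."""
    mode = "rb" if path.suffix == ".bam" else "r"
    pending: dict[str, MateAlignment | tuple] = {}
    pairs: list[ReadPairAlignment] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            try:
                lib = aln.get_tag("RG")
            except KeyError:
                raise ParseError(f"{path}: read {aln.query_name!r} has no RG tag")
            if lib not in libraries:
                raise ParseError(f"{path}: unknown library {lib!r}")
            if aln.is_unmapped or aln.mate_is_unmapped:
                mate = None
            else:
                mate = MateAlignment(
                    contig_id=aln.reference_name,
                    pos=aln.reference_start,
                    strand="-" if aln.is_reverse else "+",
                    mapq=aln.mapping_quality,
                    aln_len=aln.reference_length or aln.query_length,
                )
            key = aln.query_name
            if key not in pending:
                pending[key] = (lib, aln.is_read1, mate)
                continue
            lib0, was_read1, mate0 = pending.pop(key)
            stats["pairs_read"] += 1
            if mate is None or mate0 is None:
                stats["pairs_unmapped_mate"] += 1
                continue
            m1, m2 = (mate0, mate) if was_read1 else (mate, mate0)
            pair = ReadPairAlignment(key, lib0, m1, m2)
            if not _validate_pair(pair, contigs):
                stats["pairs_skipped_unknown_contig"] += 1
                continue
            pairs.append(pair)
    return pairs


def read_alignments(
    path: str | Path,
    libraries: dict[str, Library],
    contigs: Optional[dict[str, Contig]] = None,
    stats: Optional[dict] = None,
) -> list[ReadPairAlignment]:
    """Read paired alignments from SAM/BAM or the plain TSV dialect.

    Only pairs with both mates mapped are returned; secondary and
    supplementary records are ignored; a mate referencing an unknown contig
    drops the pair with a counted warning; an unknown library is fatal.
    ``stats``, if supplied, is filled with filter counts.
    """
    path = Path(path)
    if stats is None:
        stats = {}
    stats.setdefault("pairs_read", 0)
    stats.setdefault("pairs_skipped_unknown_contig", 0)
    stats.setdefault("pairs_unmapped_mate", 0)
    if path.suffix in (".sam", ".bam"):
        pairs = _read_alignments_sam(path, libraries, contigs, stats)
    else:
        pairs = _read_alignments_tsv(path, libraries, contigs, stats)
    stats["pairs_both_mapped"] = len(pairs)
    if stats["pairs_skipped_unknown_contig"]:
        logger.warning(
            "%s: skipped %d pairs referencing unknown contigs",
            path, stats["pairs_skipped_unknown_contig"],
        )
    return pairs


def write_alignments_tsv(pairs: Iterable[ReadPairAlignment], path: str | Path) -> None:
    """Write pairs in the documented 12-column TSV dialect."""
    with open(path, "w") as fh:
        fh.write("\t".join(ALIGNMENT_TSV_COLUMNS) + "\n")
        for p in pairs:
            m1, m2 = p.mate1, p.mate2
            fh.write(
                "\t".join(map(str, [
                    p.pair_id, p.library_id,
                    m1.contig_id, m1.pos, m1.strand, m1.mapq, m1.aln_len,
                    m2.contig_id, m2.pos, m2.strand, m2.mapq, m2.aln_len,
                ])) + "\n"
            )


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a marker table: marker_id, linkage_group, cm, then seq and/or
    contig_id+offset.  Coordinates win over sequence when both are present."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker_id", "linkage_group", "cm"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing map columns {sorted(missing)}")
    markers: list[Marker] = []
    for row in df.itertuples(index=False):
        seq = getattr(row, "seq", None)
        seq = None if (seq is None or pd.isna(seq) or seq == "") else str(seq).upper()
        ctg = getattr(row, "contig_id", None)
        ctg = None if (ctg is None or pd.isna(ctg) or ctg == "") else str(ctg)
        off = getattr(row, "offset", None)
        off = None if (off is None or pd.isna(off) or off == "") else int(off)
        if seq is not None and ctg is not None:
            logger.warning(
                "marker %s: both sequence and coordinates given; coordinates win",
                row.marker_id,
            )
            seq = None
        markers.append(
            Marker(
                id=str(row.marker_id),
                linkage_group=str(row.linkage_group),
                cm=float(row.cm),
                seq=seq,
                contig_id=ctg,
                offset=off,
            )
        )
    return GeneticMap(markers)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tlinkage_group\tcm\tseq\tcontig_id\toffset\n")
        for m in gmap.markers:
            fh.write(
                f"{m.id}\t{m.linkage_group}\t{m.cm:.6f}\t{m.seq or ''}\t"
                f"{m.contig_id or ''}\t{'' if m.offset is None else m.offset}\n"
            )


# ---------------------------------------------------------------------------
# AGP and scaffold FASTA
# ---------------------------------------------------------------------------

MIN_AGP_GAP = 13          # smallest informative gap emitted in AGP
DEFAULT_UNKNOWN_GAP = 100  # gap length when no estimate exists


def effective_gap(part: LayoutPart) -> int:
    """Integer gap length actually written after this part.

    Estimated gaps are rounded and floored at the AGP minimum (negative
    estimates — possible overlaps — are floored too); missing estimates get
    the fixed default.  Map-evidence gaps are written as given.
    """
    if part.gap_after is None:
        return DEFAULT_UNKNOWN_GAP
    if part.gap_kind == "map":
        return int(round(part.gap_after))
    return max(MIN_AGP_GAP, int(round(part.gap_after)))


def layout_sequence(layout: ScaffoldLayout, contigs: dict[str, Contig]) -> str:
    """Gapped sequence of a layout: oriented contigs separated by N runs."""
    chunks: list[str] = []
    for i, part in enumerate(layout.parts):
        ctg = contigs[part.contig_id]
        chunks.append(ctg.sequence if part.orientation == "+" else revcomp(ctg.sequence))
        if i < len(layout.parts) - 1:
            chunks.append("N" * effective_gap(part))
    return "".join(chunks)


def layout_offsets(layout: ScaffoldLayout, contigs: dict[str, Contig]) -> dict[str, int]:
    """0-based start of each contig within its layout's gapped sequence."""
    offsets: dict[str, int] = {}
    pos = 0
    for i, part in enumerate(layout.parts):
        offsets[part.contig_id] = pos
        pos += contigs[part.contig_id].length
        if i < len(layout.parts) - 1:
            pos += effective_gap(part)
    return offsets


def layouts_to_agp_records(
    layouts: Sequence[ScaffoldLayout],
    contigs: dict[str, Contig],
) -> list[AgpRecord]:
    records: list[AgpRecord] = []
    for layout in layouts:
        pos = 0  # 0-based running cursor
        part_no = 0
        for i, part in enumerate(layout.parts):
            ctg = contigs.get(part.contig_id)
            if ctg is None:
                raise BaylinkError(f"unknown component {part.contig_id!r}")
            part_no += 1
            records.append(
                AgpRecord(
                    object_id=layout.id,
                    object_beg=pos + 1,
                    object_end=pos + ctg.length,
                    part_number=part_no,
                    component_type="W",
                    component_id=ctg.id,
                    component_beg=1,
                    component_end=ctg.length,
                    orientation=part.orientation,
                )
            )
            pos += ctg.length
            if i < len(layout.parts) - 1:
                gap = effective_gap(part)
                part_no += 1
                if part.gap_kind == "map":
                    gap_type, linkage, evidence = "contig", "no", "map"
                else:
                    gap_type, linkage, evidence = "scaffold", "yes", "paired-ends;map"
                records.append(
                    AgpRecord(
                        object_id=layout.id,
                        object_beg=pos + 1,
                        object_end=pos + gap,
                        part_number=part_no,
                        component_type="N",
                        gap_length=gap,
                        gap_type=gap_type,
                        linkage=linkage,
                        evidence=evidence,
                    )
                )
                pos += gap
    return records


def write_agp(
    layouts: Sequence[ScaffoldLayout],
    contigs: dict[str, Contig],
    path: str | Path,
) -> None:
    """Serialize layouts as AGP v2.1."""
    records = layouts_to_agp_records(layouts, contigs)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for r in records:
            if r.component_type == "W":
                tail = [r.component_id, r.component_beg, r.component_end, r.orientation]
            else:
                tail = [r.gap_length, r.gap_type, r.linkage, r.evidence]
            fh.write(
                "\t".join(map(str, [
                    r.object_id, r.object_beg, r.object_end, r.part_number,
                    r.component_type, *tail,
                ])) + "\n"
            )


def read_agp(path: str | Path) -> list[AgpRecord]:
    """Parse an AGP v2.1 file, checking that parts tile each object."""
    path = Path(path)
    records: list[AgpRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ParseError(f"{path}: AGP row with {len(f)} columns: {line!r}")
            base = dict(
                object_id=f[0], object_beg=int(f[1]), object_end=int(f[2]),
                part_number=int(f[3]), component_type=f[4],
            )
            if f[4] == "N":
                rec = AgpRecord(**base, gap_length=int(f[5]), gap_type=f[6],
                                linkage=f[7], evidence=f[8])
            elif f[4] == "W":
                rec = AgpRecord(**base, component_id=f[5], component_beg=int(f[6]),
                                component_end=int(f[7]), orientation=f[8])
            else:
                raise ParseError(f"{path}: unsupported component type {f[4]!r}")
            records.append(rec)
    # tiling check
    cursor: dict[str, int] = {}
    for rec in records:
        expect = cursor.get(rec.object_id, 0) + 1
        if rec.object_beg != expect:
            raise ParseError(
                f"{path}: object {rec.object_id!r} part {rec.part_number} "
                f"starts at {rec.object_beg}, expected {expect}"
            )
        cursor[rec.object_id] = rec.object_end
    return records


def agp_records_to_layouts(records: Sequence[AgpRecord]) -> list[ScaffoldLayout]:
    """Rebuild layouts from AGP rows (inverse of ``layouts_to_agp_records``)."""
    layouts: dict[str, list[LayoutPart]] = {}
    pending_gap: dict[str, tuple[int, str]] = {}
    order: list[str] = []
    for rec in records:
        if rec.object_id not in layouts:
            layouts[rec.object_id] = []
            order.append(rec.object_id)
        parts = layouts[rec.object_id]
        if rec.component_type == "W":
            gap = pending_gap.pop(rec.object_id, None)
            if gap is not None and parts:
                prev = parts[-1]
                parts[-1] = LayoutPart(
                    prev.contig_id, prev.orientation,
                    gap_after=float(gap[0]), gap_kind=gap[1],
                )
            parts.append(LayoutPart(rec.component_id, rec.orientation))
        else:
            kind = "map" if rec.gap_type == "contig" else "paired"
            pending_gap[rec.object_id] = (rec.gap_length, kind)
    return [ScaffoldLayout(oid, layouts[oid]) for oid in order]


def write_fasta(
    layouts: Sequence[ScaffoldLayout],
    contigs: dict[str, Contig],
    path: str | Path,
    width: int = 80,
) -> None:
    """Write each layout's gapped sequence as a FASTA record."""
    with open(path, "w") as fh:
        for layout in layouts:
            seq = layout_sequence(layout, contigs)
            fh.write(f">{layout.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_contig_fasta(contigs: dict[str, Contig], path: str | Path,
                       width: int = 80) -> None:
    with open(path, "w") as fh:
        for ctg in contigs.values():
            fh.write(f">{ctg.id}\n")
            for i in range(0, len(ctg.sequence), width):
                fh.write(ctg.sequence[i:i + width] + "\n")
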