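"""Truth-tracked simulation of genomes, contigs, paired reads and genetic maps.

Everything downstream of read mapping can be exercised without any external
data: the simulator emits contigs (some reverse-complemented), read pairs
already expressed as alignments (as a mapper would report them — downstream
code never sees the truth), and a genetic map whose markers carry the 31-mer
at their genomic position so sequence placement works.  A single integer seed
drives a named generator per sub-stage, so stages are independently
reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import (
    Contig,
    GeneticMap,
    Library,
    Marker,
    MateAlignment,
    ReadPairAlignment,
    revcomp,
)

_BASES = np.array(list("ACGT"))

# sub-stage tags for the seeded generators
_STAGE_GENOME = 1
_STAGE_FRAGMENT = 2
_STAGE_READS = 3
_STAGE_MAP = 4


def _rng(seed: int, stage: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([stage, extra, seed])


@dataclass
class TruthSet:
    """Ground truth of one simulated dataset."""

    genome: dict[str, str]
    repeats: dict[str, list[tuple[int, int]]]
    contig_truth: list[tuple[str, str, int, str]]  # (contig_id, chrom, start, strand)
    marker_truth: list[tuple[str, str, int, float]]  # (marker_id, chrom, pos, cm)
    libraries: dict[str, Library] = field(default_factory=dict)
    seed: int = 0

    def true_adjacencies(self) -> list[tuple[tuple[str, str], tuple[str, str]]]:
        """Consecutive (contig, strand) pairs along each chromosome."""
        by_chrom: dict[str, list[tuple[int, str, str]]] = {}
        for cid, chrom, start, strand in self.contig_truth:
            by_chrom.setdefault(chrom, []).append((start, cid, strand))
        adj = []
        for chrom in sorted(by_chrom):
            entries = sorted(by_chrom[chrom])
            for (_, c1, s1), (_, c2, s2) in zip(entries, entries[1:]):
                adj.append(((c1, s1), (c2, s2)))
        return adj

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "chromosome_lengths": {c: len(s) for c, s in self.genome.items()},
            "repeats": self.repeats,
            "contig_truth": self.contig_truth,
            "marker_truth": self.marker_truth,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def adjacencies_from_json(path: str | Path) -> list:
        with open(path) as fh:
            payload = json.load(fh)
        dummy = TruthSet(
            genome={c: "N" * n for c, n in payload["chromosome_lengths"].items()},
            repeats={},
            contig_truth=[tuple(t) for t in payload["contig_truth"]],
            marker_truth=[tuple(t) for t in payload["marker_truth"]],
        )
        return dummy.true_adjacencies()


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(
    n_chromosomes: int = 2,
    length_per_chromosome: int = 500_000,
    gc: float = 0.36,
    repeat_fraction: float = 0.0,
    seed: int = 0,
    repeat_unit: int = 2_000,
) -> tuple[dict[str, str], dict[str, list[tuple[int, int]]]]:
    """i.i.d.-base chromosomes with an optional central near-identical repeat
    block emulating a recombination-poor pericentromere.

    Repeat copies are 99%-identical to a per-chromosome template.  Returns
    (genome, repeat annotation as 0-based half-open intervals).
    """
    if n_chromosomes <= 0 or length_per_chromosome <= 0:
        raise ValueError("chromosome count and length must be positive")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome: dict[str, str] = {}
    repeats: dict[str, list[tuple[int, int]]] = {}
    for c in range(1, n_chromosomes + 1):
        rng = _rng(seed, _STAGE_GENOME, c)
        seq = rng.choice(_BASES, size=length_per_chromosome, p=probs)
        name = str(c)
        repeats[name] = []
        if repeat_fraction > 0:
            block = int(round(repeat_fraction * length_per_chromosome))
            start = (length_per_chromosome - block) // 2
            template = rng.choice(_BASES, size=repeat_unit, p=probs)
            pos = start
            while pos < start + block:
                copy = template.copy()
                n_mut = rng.binomial(repeat_unit, 0.01)
                sites = rng.choice(repeat_unit, size=n_mut, replace=False)
                copy[sites] = rng.choice(_BASES, size=n_mut)
                take = min(repeat_unit, start + block - pos)
                seq[pos:pos + take] = copy[:take]
                pos += take
            repeats[name].append((start, start + block))
        genome[name] = "".join(seq)
    return genome, repeats


# ---------------------------------------------------------------------------
# fragmentation into contigs
# ---------------------------------------------------------------------------


def fragment_genome(
    genome: dict[str, str],
    n_contigs_per_chromosome: int = 20,
    gap_range: tuple[int, int] = (100, 300),
    reverse_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[dict[str, Contig], list[tuple[str, str, int, str]]]:
    """Tile each chromosome with contigs separated by sampled gaps.

    A ``reverse_fraction`` of contigs is emitted reverse-complemented to
    exercise orientation logic.  Concatenating the truth-ordered,
    truth-oriented contigs plus gaps reconstructs the chromosome.
    """
    contigs: dict[str, Contig] = {}
    truth: list[tuple[str, str, int, str]] = []
    for chrom in sorted(genome):
        rng = _rng(seed, _STAGE_FRAGMENT, int(chrom) if chrom.isdigit() else 0)
        L = len(genome[chrom])
        n = n_contigs_per_chromosome
        gaps = rng.integers(gap_range[0], gap_range[1] + 1, size=n - 1) if n > 1 \
            else np.array([], dtype=int)
        seq_total = L - int(gaps.sum())
        if seq_total < n:
            raise ValueError(
                f"chromosome {chrom}: {n} contigs do not fit in {L} bases"
            )
        # jittered contig lengths that sum exactly to seq_total
        raw = rng.uniform(0.7, 1.3, size=n)
        lens = np.maximum(1, np.floor(raw / raw.sum() * seq_total).astype(int))
        lens[-1] += seq_total - int(lens.sum())
        pos = 0
        for i in range(n):
            start, end = pos, pos + int(lens[i])
            strand = "-" if rng.random() < reverse_fraction else "+"
            cid = f"ctg{chrom}_{i:03d}"
            interval = genome[chrom][start:end]
            contigs[cid] = Contig(
                cid, interval if strand == "+" else revcomp(interval)
            )
            truth.append((cid, chrom, start, strand))
            pos = end + (int(gaps[i]) if i < n - 1 else 0)
    return contigs, truth


# ---------------------------------------------------------------------------
# read pairs
# ---------------------------------------------------------------------------


def simulate_read_pairs(
    genome: dict[str, str],
    contig_truth: Sequence[tuple[str, str, int, str]],
    contigs: dict[str, Contig],
    library: Library,
    coverage: float,
    mismap_rate: float = 0.0,
    mapq: int = 40,
    seed: int = 0,
) -> list[ReadPairAlignment]:
    """Emit read pairs as the alignments a mapper would report.

    Fragment midpoints are uniform over the genome, outer spans are
    Normal(insert_mu, insert_sigma^2), and each mate is projected into contig
    coordinates through the truth (pairs with a mate in an inter-contig gap
    are dropped).  With probability ``mismap_rate`` one mate is teleported to
    a uniform random contig position with MAPQ <= 3; correctly mapped mates
    get the constant model MAPQ.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rl = library.read_len
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    total = float(lengths.sum())
    n_pairs = int(round(coverage * total / (2 * rl)))
    rng = _rng(seed, _STAGE_READS, zlib.crc32(library.id.encode()) % (2**31))

    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=lengths / total)
    mid = rng.uniform(0, 1, size=n_pairs)
    spans = np.maximum(
        rng.normal(library.insert_mu, library.insert_sigma, size=n_pairs),
        2 * rl,
    )
    teleport = rng.random(size=n_pairs) < mismap_rate
    teleport_mate = rng.integers(1, 3, size=n_pairs)

    # per-chromosome sorted contig tables for projection
    tables: dict[str, tuple[np.ndarray, np.ndarray, list[str], list[str]]] = {}
    for chrom in chroms:
        entries = sorted(
            (start, cid, strand)
            for cid, c, start, strand in contig_truth
            if c == chrom
        )
        starts = np.array([e[0] for e in entries], dtype=int)
        ends = np.array(
            [e[0] + contigs[e[1]].length for e in entries], dtype=int
        )
        tables[chrom] = (starts, ends, [e[1] for e in entries],
                         [e[2] for e in entries])

    truth_strand = {cid: strand for cid, _c, _s, strand in contig_truth}
    truth_start = {cid: start for cid, _c, start, _s in contig_truth}
    all_cids = sorted(contigs)

    def project(chrom: str, gstart: int, gstrand: str) -> Optional[MateAlignment]:
        starts, ends, cids, strands = tables[chrom]
        i = int(np.searchsorted(starts, gstart, side="right")) - 1
        if i < 0:
            return None
        if gstart + rl > ends[i]:
            return None
        cid = cids[i]
        if strands[i] == "+":
            pos = gstart - truth_start[cid]
            strand = gstrand
        else:
            pos = ends[i] - (gstart + rl)
            strand = "-" if gstrand == "+" else "+"
        return MateAlignment(cid, int(pos), strand, mapq, rl)

    pairs: list[ReadPairAlignment] = []
    outie = library.orientation == "outie"
    for k in range(n_pairs):
        chrom = chroms[chrom_idx[k]]
        L = len(genome[chrom])
        span = float(spans[k])
        left = int(mid[k] * L - span / 2)
        right_start = left + int(round(span)) - rl
        if left < 0 or right_start + rl > L:
            continue
        s1, s2 = ("-", "+") if outie else ("+", "-")
        m1 = project(chrom, left, s1)
        m2 = project(chrom, right_start, s2)
        if m1 is None or m2 is None:
            continue
        if teleport[k]:
            cid = all_cids[rng.integers(0, len(all_cids))]
            clen = contigs[cid].length
            tele = MateAlignment(
                cid,
                int(rng.integers(0, max(1, clen - rl + 1))),
                "+" if rng.random() < 0.5 else "-",
                int(rng.integers(0, 4)),
                min(rl, clen),
            )
            if teleport_mate[k] == 1:
                m1 = tele
            else:
                m2 = tele
        pairs.append(
            ReadPairAlignment(f"{library.id}_p{k}", library.id, m1, m2)
        )
    return pairs


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


def simulate_map(
    genome: dict[str, str],
    n_markers_per_chromosome: int = 15,
    cm_per_mb: float = 4.0,
    suppressed_interval: Optional[tuple[float, float]] = (0.4, 0.6),
    suppression_factor: float = 0.01,
    kmer: int = 31,
    seed: int = 0,
) -> tuple[GeneticMap, list[tuple[str, str, int, float]]]:
    """Uniformly placed markers with a cumulative linear genetic map.

    The recombination rate is ``cm_per_mb`` outside ``suppressed_interval``
    (given as chromosome fractions) and ``suppression_factor`` times that
    inside it, so cM is monotone non-decreasing with position.  Each marker
    carries the ``kmer``-mer at its position for sequence placement.
    """
    if n_markers_per_chromosome < 2:
        raise ValueError("need at least 2 markers per chromosome")
    markers: list[Marker] = []
    truth: list[tuple[str, str, int, float]] = []

    for chrom in sorted(genome):
        rng = _rng(seed, _STAGE_MAP, int(chrom) if chrom.isdigit() else 0)
        L = len(genome[chrom])

        def cm_at(pos: int) -> float:
            if suppressed_interval is None:
                return cm_per_mb * pos / 1e6
            a, b = (int(suppressed_interval[0] * L),
                    int(suppressed_interval[1] * L))
            normal = min(pos, a) + max(0, pos - b)
            slow = min(max(pos - a, 0), b - a)
            return cm_per_mb * (normal + suppression_factor * slow) / 1e6

        positions = np.sort(
            rng.choice(L - kmer, size=n_markers_per_chromosome, replace=False)
        )
        for j, pos in enumerate(positions):
            pos = int(pos)
            mid = f"m{chrom}_{j:03d}"
            cm = cm_at(pos)
            markers.append(
                Marker(mid, chrom, cm, seq=genome[chrom][pos:pos + kmer])
            )
            truth.append((mid, chrom, pos, cm))
    return GeneticMap(markers), truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """One simulated dataset plus its truth."""

    contigs: dict[str, Contig]
    alignments: list[ReadPairAlignment]
    libraries: dict[str, Library]
    gmap: GeneticMap
    holdout: Optional[GeneticMap]
    truth: TruthSet


def default_libraries() -> dict[str, Library]:
    """The two linking libraries of the standard scenario: a 3 kb mate-pair
    library and a sparse BAC-end-like 30 kb library."""
    return {
        "mp3k": Library("mp3k", 3000, 300, "innie", 100),
        "bac30k": Library("bac30k", 30_000, 3_000, "innie", 100,
                          weight_note="BAC ends"),
    }


def clean_scenario(
    seed: int = 1,
    n_chromosomes: int = 2,
    chromosome_length: int = 500_000,
    n_contigs_per_chromosome: int = 20,
    n_markers_per_chromosome: int = 15,
    n_holdout_per_chromosome: int = 3,
    mismap_rate: float = 0.02,
    mp_coverage: float = 20.0,
    bac_coverage: float = 0.5,
    repeat_fraction: float = 0.0,
) -> Scenario:
    """The standard study conditions: 2 x 500 kb chromosomes, 40 contigs,
    mate pairs 3000±300 at 20x, BAC-like 30k±3k at 0.5x, 30 anchoring
    markers (plus held-out validation markers), 2% mismapping."""
    genome, repeats = simulate_genome(
        n_chromosomes, chromosome_length, repeat_fraction=repeat_fraction,
        seed=seed,
    )
    contigs, contig_truth = fragment_genome(
        genome, n_contigs_per_chromosome, seed=seed
    )
    libs = default_libraries()
    alignments: list[ReadPairAlignment] = []
    for lib_id, cov in (("mp3k", mp_coverage), ("bac30k", bac_coverage)):
        if cov <= 0:
            continue
        alignments.extend(
            simulate_read_pairs(
                genome, contig_truth, contigs, libs[lib_id], cov,
                mismap_rate=mismap_rate, seed=seed,
            )
        )
    total_markers = n_markers_per_chromosome + n_holdout_per_chromosome
    full_map, marker_truth = simulate_map(
        genome, total_markers, seed=seed
    )
    holdout = None
    if n_holdout_per_chromosome > 0:
        rng = _rng(seed, _STAGE_MAP, 999)
        holdout_ids: set[str] = set()
        for chrom in sorted(genome):
            ids = [m.id for m in full_map.markers if m.linkage_group == chrom]
            picked = rng.choice(len(ids), size=n_holdout_per_chromosome,
                                replace=False)
            holdout_ids |= {ids[i] for i in picked}
        holdout = GeneticMap(
            [m for m in full_map.markers if m.id in holdout_ids]
        )
        full_map = GeneticMap(
            [m for m in full_map.markers if m.id not in holdout_ids]
        )
    truth = TruthSet(genome, repeats, contig_truth, marker_truth,
                     libraries=libs, seed=seed)
    return Scenario(contigs, alignments, libs, full_map, holdout, truth)


def noisy_scenario(seed: int = 1, mismap_rate: float = 0.2, **kwargs) -> Scenario:
    return clean_scenario(seed=seed, mismap_rate=mismap_rate, **kwargs)


def write_scenario(scenario: Scenario, outdir: str | Path) -> None:
    """Materialize a scenario as the file set the CLI stages consume."""
    from . import io as bio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bio.write_contig_fasta(scenario.contigs, outdir / "contigs.fa")
    bio.write_alignments_tsv(scenario.alignments, outdir / "aln.tsv")
    with open(outdir / "libs.tsv", "w") as fh:
        fh.write("id\tinsert_mu\tinsert_sigma\torientation\tread_len\tweight_note\n")
        for lib in scenario.libraries.values():
            fh.write(
                f"{lib.id}\t{lib.insert_mu}\t{lib.insert_sigma}\t"
                f"{lib.orientation}\t{lib.read_len}\t{lib.weight_note}\n"
            )
    bio.write_genetic_map(scenario.gmap, outdir / "map.tsv")
    if scenario.holdout is not None:
        bio.write_genetic_map(scenario.holdout, outdir / "holdout.tsv")
    scenario.truth.to_json(outdir / "truth.json")


def write_fastq(
    alignments: Sequence[ReadPairAlignment],
    contigs: dict[str, Contig],
    prefix: str | Path,
) -> None:
    """Optional FASTQ emission for end-to-end demos with a real mapper.

    Read sequences are reconstructed from the contig the mate aligns to
    (reverse-complemented for '-' mates); qualities are constant."""
    prefix = str(prefix)
    with open(prefix + "_R1.fastq", "w") as f1, open(prefix + "_R2.fastq", "w") as f2:
        for pair in alignments:
            for mate, fh in ((pair.mate1, f1), (pair.mate2, f2)):
                seq = contigs[mate.contig_id].sequence[
                    mate.pos:mate.pos + mate.aln_len
                ]
                if mate.strand == "-":
                    seq = revcomp(seq)
                fh.write(f"@{pair.pair_id}\n{seq}\n+\n{'I' * len(seq)}\n")
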