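"""Merging scaffolds with a genetic map into pseudomolecules.

Markers are placed on scaffold sequences (exact match on both strands, or a
coordinate lift through the contig's slot in its layout), map-discordant
chimeric scaffolds are split at their weakest intervening join, and the
survivors are ordered and oriented along each linkage group by marker
centimorgan positions.  Colinearity between physical and genetic marker order
is quantified per chromosome with Spearman's rho.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import spearmanr

from .io import (
    Contig,
    GeneticMap,
    LayoutPart,
    ScaffoldLayout,
    layout_offsets,
    layout_sequence,
    revcomp,
)
from .linkmodel import ModelParams

logger = logging.getLogger(__name__)

PLACED = "placed"
AMBIGUOUS = "ambiguous"
UNPLACED = "unplaced"


@dataclass(frozen=True)
class MarkerPlacement:
    marker_id: str
    linkage_group: str
    cm: float
    status: str  # placed | ambiguous | unplaced
    scaffold_id: Optional[str] = None
    scaffold_pos: Optional[int] = None


@dataclass
class Pseudomolecule:
    """Ordered, oriented scaffolds along one linkage group."""

    id: str
    linkage_group: str
    entries: list[tuple[str, str, str]]  # (scaffold_id, orientation, confidence)
    gap: int = 10_000

    def scaffold_ids(self) -> list[str]:
        return [sid for sid, _o, _c in self.entries]


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def place_markers(
    gmap: GeneticMap,
    layouts: Sequence[ScaffoldLayout],
    contigs: dict[str, Contig],
) -> list[MarkerPlacement]:
    """Locate every marker on the scaffold set.

    Sequence markers: exact match against both strands of every scaffold;
    exactly one hit -> placed, several -> ambiguous (excluded from anchoring),
    none -> unplaced.  Coordinate markers are lifted through their contig's
    position and orientation in its layout.
    """
    seqs = {lo.id: layout_sequence(lo, contigs) for lo in layouts}
    contig_home: dict[str, tuple[ScaffoldLayout, LayoutPart, int]] = {}
    for lo in layouts:
        offs = layout_offsets(lo, contigs)
        for part in lo.parts:
            contig_home[part.contig_id] = (lo, part, offs[part.contig_id])

    placements: list[MarkerPlacement] = []
    for m in gmap.markers:
        if m.contig_id is not None:
            home = contig_home.get(m.contig_id)
            if home is None:
                logger.warning("marker %s: unknown contig %s", m.id, m.contig_id)
                placements.append(
                    MarkerPlacement(m.id, m.linkage_group, m.cm, UNPLACED)
                )
                continue
            lo, part, start = home
            clen = contigs[m.contig_id].length
            if not 0 <= m.offset < clen:
                placements.append(
                    MarkerPlacement(m.id, m.linkage_group, m.cm, UNPLACED)
                )
                continue
            if part.orientation == "+":
                pos = start + m.offset
            else:
                pos = start + (clen - 1 - m.offset)
            placements.append(
                MarkerPlacement(m.id, m.linkage_group, m.cm, PLACED, lo.id, pos)
            )
            continue
        hits: list[tuple[str, int]] = []
        rc = revcomp(m.seq)
        for sid, seq in seqs.items():
            hits += [(sid, i) for i in _find_all(seq, m.seq)]
            if rc != m.seq:
                hits += [(sid, i) for i in _find_all(seq, rc)]
        if len(hits) == 1:
            sid, pos = hits[0]
            placements.append(
                MarkerPlacement(m.id, m.linkage_group, m.cm, PLACED, sid, pos)
            )
        elif len(hits) > 1:
            placements.append(
                MarkerPlacement(m.id, m.linkage_group, m.cm, AMBIGUOUS)
            )
        else:
            placements.append(
                MarkerPlacement(m.id, m.linkage_group, m.cm, UNPLACED)
            )
    return placements


# ---------------------------------------------------------------------------
# chimera surgery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreakEvent:
    scaffold_id: str
    junction_index: int  # split after parts[junction_index]
    join_posterior: Optional[float]
    reason: str  # multi-lg | cm-discordant


def _scaffold_conflict(
    markers: list[MarkerPlacement], cm_window: float
) -> Optional[tuple[int, int, str]]:
    """Find the first map conflict among one scaffold's placed markers.

    Markers must be sorted by scaffold position.  Returns (i, j, reason) for
    the offending marker index pair, or None.  Two kinds of conflict:
    markers from two linkage groups, or same-LG markers that regress by more
    than ``cm_window`` against the scaffold's dominant cM direction.
    """
    for i in range(len(markers) - 1):
        if markers[i].linkage_group != markers[i + 1].linkage_group:
            return i, i + 1, "multi-lg"
    if len(markers) < 2:
        return None
    cms = [m.cm for m in markers]
    # dominant direction: sign of the overall trend (first-to-last tiebreak)
    rho = spearmanr(range(len(cms)), cms).statistic if len(cms) > 2 else 0.0
    ascending = (rho > 0) or (rho == 0 and cms[-1] >= cms[0]) or np.isnan(rho)
    if not ascending:
        cms = [-c for c in cms]
    best_i, best = 0, cms[0]
    for j in range(1, len(cms)):
        if best - cms[j] > cm_window:
            return best_i, j, "cm-discordant"
        if cms[j] > best:
            best_i, best = j, cms[j]
    return None


def _split_layout(
    layout: ScaffoldLayout, junction: int, counter: list[int]
) -> tuple[ScaffoldLayout, ScaffoldLayout]:
    """Split after parts[junction]; the sacrificed join's gap is dropped."""
    left_parts = [*layout.parts[:junction]]
    cut = layout.parts[junction]
    left_parts.append(LayoutPart(cut.contig_id, cut.orientation))
    right_parts = list(layout.parts[junction + 1:])
    counter[0] += 1
    a = ScaffoldLayout(f"{layout.id}_b{counter[0]}", left_parts,
                       provenance=list(layout.provenance))
    counter[0] += 1
    b = ScaffoldLayout(f"{layout.id}_b{counter[0]}", right_parts,
                       provenance=list(layout.provenance))
    return a, b


def detect_and_break_chimeras(
    layouts: Sequence[ScaffoldLayout],
    gmap: GeneticMap,
    contigs: dict[str, Contig],
    params: ModelParams,
) -> tuple[list[ScaffoldLayout], list[BreakEvent], set[str]]:
    """Split map-discordant scaffolds at their weakest intervening join.

    Repeats until no conflict remains.  A conflict whose offending markers
    have no accepted join between them (both inside one contig) is flagged
    unresolvable and the scaffold is excluded from anchoring.  Returns
    (revised layouts, break log, unresolvable scaffold ids).
    """
    layouts = list(layouts)
    breaks: list[BreakEvent] = []
    unresolvable: set[str] = set()
    counter = [0]
    while True:
        placements = place_markers(gmap, layouts, contigs)
        by_scaffold: dict[str, list[MarkerPlacement]] = {}
        for p in placements:
            if p.status == PLACED:
                by_scaffold.setdefault(p.scaffold_id, []).append(p)
        offsets = {lo.id: layout_offsets(lo, contigs) for lo in layouts}
        did_break = False
        for lo in sorted(layouts, key=lambda l: l.id):
            if lo.id in unresolvable:
                continue
            ms = sorted(
                by_scaffold.get(lo.id, []), key=lambda p: (p.scaffold_pos, p.marker_id)
            )
            conflict = _scaffold_conflict(ms, params.chimera_cm_window)
            if conflict is None:
                continue
            i, j, reason = conflict
            lo_off = offsets[lo.id]
            pos_i, pos_j = ms[i].scaffold_pos, ms[j].scaffold_pos
            # joins strictly between the offending marker positions
            candidates: list[tuple[float, int]] = []
            for k, part in enumerate(lo.parts[:-1]):
                junction_pos = lo_off[part.contig_id] + contigs[part.contig_id].length
                if pos_i < junction_pos <= pos_j:
                    post = part.join_posterior
                    candidates.append((post if post is not None else 1.0, k))
            if not candidates:
                logger.warning(
                    "scaffold %s: %s conflict inside a single contig; "
                    "flagged unresolvable", lo.id, reason,
                )
                unresolvable.add(lo.id)
                continue
            candidates.sort(key=lambda t: (t[0], t[1]))
            post, junction = candidates[0]
            a, b = _split_layout(lo, junction, counter)
            breaks.append(BreakEvent(lo.id, junction, lo.parts[junction].join_posterior,
                                     reason))
            layouts = [l for l in layouts if l.id != lo.id] + [a, b]
            did_break = True
            break  # placements are stale; recompute
        if not did_break:
            return sorted(layouts, key=lambda l: l.id), breaks, unresolvable


# ---------------------------------------------------------------------------
# ordering and orientation
# ---------------------------------------------------------------------------


def order_and_orient(
    layouts: Sequence[ScaffoldLayout],
    placements: Sequence[MarkerPlacement],
    gmap: GeneticMap,
    contigs: dict[str, Contig],
    params: ModelParams,
    exclude: Optional[set[str]] = None,
) -> tuple[list[Pseudomolecule], list[str]]:
    """Order and orient scaffolds along each linkage group.

    Scaffolds are sorted by the mean cM of their placed markers (ties: longer
    first, then id); orientation comes from the sign of the cM-versus-position
    slope over markers with at least two distinct cM values, defaulting to '+'
    with confidence 'single_marker' otherwise.  Scaffolds without placed
    markers (or excluded ones) are returned as the unanchored set.
    """
    exclude = exclude or set()
    by_scaffold: dict[str, list[MarkerPlacement]] = {}
    for p in placements:
        if p.status == PLACED:
            by_scaffold.setdefault(p.scaffold_id, []).append(p)

    length_of = {lo.id: lo.total_contig_bases(contigs) for lo in layouts}
    anchored: dict[str, list[tuple[float, int, str, str, str]]] = {}
    unanchored: list[str] = []
    for lo in sorted(layouts, key=lambda l: l.id):
        ms = by_scaffold.get(lo.id)
        if lo.id in exclude or not ms:
            unanchored.append(lo.id)
            continue
        lgs = sorted({m.linkage_group for m in ms})
        if len(lgs) > 1:
            counts = {lg: sum(m.linkage_group == lg for m in ms) for lg in lgs}
            lg = max(sorted(counts), key=lambda g: counts[g])
            logger.warning(
                "scaffold %s: markers from %s; assigning to majority group %s",
                lo.id, lgs, lg,
            )
            ms = [m for m in ms if m.linkage_group == lg]
        else:
            lg = lgs[0]
        mean_cm = float(np.mean([m.cm for m in ms]))
        distinct = sorted({m.cm for m in ms})
        if len(distinct) >= 2:
            pos = np.array([m.scaffold_pos for m in ms], dtype=float)
            cm = np.array([m.cm for m in ms], dtype=float)
            slope = float(np.cov(pos, cm, bias=True)[0, 1])
            orientation = "-" if slope < 0 else "+"
            confidence = "two_plus_markers"
        else:
            orientation, confidence = "+", "single_marker"
        anchored.setdefault(lg, []).append(
            (mean_cm, -length_of[lo.id], lo.id, orientation, confidence)
        )

    pseudomolecules: list[Pseudomolecule] = []
    for lg in gmap.linkage_groups():
        entries = anchored.get(lg, [])
        if not entries:
            logger.warning("linkage group %s: no anchored scaffolds", lg)
        entries.sort()  # mean cM, then longer first, then id
        pseudomolecules.append(
            Pseudomolecule(
                id=f"chr{lg}",
                linkage_group=lg,
                entries=[(sid, o, conf) for _cm, _nl, sid, o, conf in entries],
                gap=params.pseudo_gap,
            )
        )
    return pseudomolecules, unanchored


def pseudomolecule_layout(
    pm: Pseudomolecule,
    layouts: dict[str, ScaffoldLayout],
) -> ScaffoldLayout:
    """Flatten a pseudomolecule to a contig-level layout for AGP/FASTA output.

    Scaffolds oriented '-' contribute their mirror part list; the fixed
    inter-scaffold gap carries map (not paired-read) evidence.
    """
    parts: list[LayoutPart] = []
    for idx, (sid, orientation, _conf) in enumerate(pm.entries):
        lo = layouts[sid]
        sparts = lo.parts
        if orientation == "-":
            mirrored = []
            for i in range(len(sparts) - 1, -1, -1):
                p = sparts[i]
                gap = gap_post = None
                kind = "paired"
                if i > 0:
                    prev = sparts[i - 1]
                    gap, kind, gap_post = (
                        prev.gap_after, prev.gap_kind, prev.join_posterior
                    )
                mirrored.append(
                    LayoutPart(
                        p.contig_id,
                        "+" if p.orientation == "-" else "-",
                        gap_after=gap, gap_kind=kind, join_posterior=gap_post,
                    )
                )
            sparts = mirrored
        for j, p in enumerate(sparts):
            last_in_scaffold = j == len(sparts) - 1
            last_overall = last_in_scaffold and idx == len(pm.entries) - 1
            if last_overall:
                parts.append(LayoutPart(p.contig_id, p.orientation))
            elif last_in_scaffold:
                parts.append(
                    LayoutPart(p.contig_id, p.orientation,
                               gap_after=float(pm.gap), gap_kind="map")
                )
            else:
                parts.append(p)
    return ScaffoldLayout(pm.id, parts)


# ---------------------------------------------------------------------------
# colinearity QC
# ---------------------------------------------------------------------------


@dataclass
class ColinearityResult:
    chromosome: str
    n_markers: int
    rho: Optional[float]  # None when fewer than 3 markers
    discordant: list[str] = field(default_factory=list)


def _rho(pos: Sequence[float], cm: Sequence[float]) -> float:
    return float(spearmanr(pos, cm).statistic)


def colinearity_check(
    chromosome_layouts: Sequence[ScaffoldLayout],
    gmap: GeneticMap,
    contigs: dict[str, Contig],
    params: ModelParams,
) -> list[ColinearityResult]:
    """Per-chromosome Spearman rho between physical and genetic marker order.

    Midrank ties; defined only with >= 3 placed markers.  A marker whose
    removal raises rho by more than ``discord_eps`` is listed as discordant.
    Holdout markers can be checked by passing their own map.
    """
    placements = place_markers(gmap, chromosome_layouts, contigs)
    by_chrom: dict[str, list[MarkerPlacement]] = {lo.id: [] for lo in chromosome_layouts}
    for p in placements:
        if p.status == PLACED:
            by_chrom.setdefault(p.scaffold_id, []).append(p)
    results = []
    for lo in chromosome_layouts:
        ms = sorted(by_chrom.get(lo.id, []), key=lambda p: (p.scaffold_pos, p.marker_id))
        if len(ms) < 3:
            results.append(ColinearityResult(lo.id, len(ms), None))
            continue
        pos = [m.scaffold_pos for m in ms]
        cm = [m.cm for m in ms]
        rho = _rho(pos, cm)
        discordant = []
        for k, m in enumerate(ms):
            if len(ms) - 1 < 3:
                break
            sub_pos = pos[:k] + pos[k + 1:]
            sub_cm = cm[:k] + cm[k + 1:]
            if _rho(sub_pos, sub_cm) - rho > params.discord_eps:
                discordant.append(m.marker_id)
        results.append(ColinearityResult(lo.id, len(ms), rho, discordant))
    return results
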