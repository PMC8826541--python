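"""Greedy construction of superscaffolds from scored link bundles.

Repeat-like contigs are masked first (coverage and link-degree rules), then
bundles are accepted best-first under conflict constraints: each contig end is
used at most once and no accepted set of joins may close a cycle.  The
resulting chains are emitted as deterministic, canonically oriented layouts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import Contig, LayoutPart, ReadPairAlignment, ScaffoldLayout
from .linkmodel import HEAD, TAIL, LinkBundle, ModelParams

logger = logging.getLogger(__name__)


class _DisjointSet:
    def __init__(self) -> None:
        self._parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        parent = self._parent.setdefault(x, x)
        if parent != x:
            parent = self._parent[x] = self.find(parent)
        return parent

    def union(self, a: str, b: str) -> None:
        self._parent[self.find(a)] = self.find(b)


def contig_coverage(
    contigs: dict[str, Contig], alignments: Sequence[ReadPairAlignment]
) -> dict[str, float]:
    """Per-base read coverage of each contig from both mates of every pair."""
    bases = {cid: 0 for cid in contigs}
    for pair in alignments:
        for mate in (pair.mate1, pair.mate2):
            if mate.contig_id in bases:
                bases[mate.contig_id] += mate.aln_len
    return {cid: bases[cid] / contigs[cid].length for cid in contigs}


def detect_repeats(
    contigs: dict[str, Contig],
    alignments: Sequence[ReadPairAlignment],
    bundles: Sequence[LinkBundle],
    params: ModelParams,
) -> set[str]:
    """Contigs too repeat-like to scaffold safely.

    A contig is masked when its coverage exceeds ``repeat_cov_factor`` times
    the median, or when one of its ends carries more than ``max_degree``
    confident (above-threshold) bundles — the signature of a repeat attracting
    links from many loci.
    """
    cov = contig_coverage(contigs, alignments)
    masked: set[str] = set()
    if cov:
        med = float(np.median(list(cov.values())))
        if med > 0:
            masked |= {
                cid for cid, c in cov.items()
                if c > params.repeat_cov_factor * med
            }
    degree: dict[tuple[str, str], int] = {}
    for b in bundles:
        if b.posterior is None or b.posterior < params.posterior_threshold:
            continue
        degree[(b.contig_a, b.end_a)] = degree.get((b.contig_a, b.end_a), 0) + 1
        degree[(b.contig_b, b.end_b)] = degree.get((b.contig_b, b.end_b), 0) + 1
    masked |= {cid for (cid, _end), d in degree.items() if d > params.max_degree}
    return masked


@dataclass
class Rejection:
    bundle_key: tuple
    posterior: float
    reason: str  # below-threshold | end-occupied | cycle | repeat-masked


def _canonicalize(
    parts: list[LayoutPart],
) -> list[LayoutPart]:
    """Pick the canonical one of a layout's two mirror representations.

    Prefer the representation whose first contig is '+'; when both or neither
    qualify, take the one whose first (terminal) contig id sorts lower.
    """
    if len(parts) == 1:
        p = parts[0]
        return [LayoutPart(p.contig_id, "+")]

    def mirror(ps: list[LayoutPart]) -> list[LayoutPart]:
        out = []
        for i in range(len(ps) - 1, -1, -1):
            p = ps[i]
            gap = gap_post = None
            kind = "paired"
            if i > 0:  # the gap that preceded p becomes the gap after it
                prev = ps[i - 1]
                gap, kind, gap_post = prev.gap_after, prev.gap_kind, prev.join_posterior
            out.append(
                LayoutPart(
                    p.contig_id,
                    "+" if p.orientation == "-" else "-",
                    gap_after=gap, gap_kind=kind, join_posterior=gap_post,
                )
            )
        return out

    rev = mirror(parts)
    fwd_plus = parts[0].orientation == "+"
    rev_plus = rev[0].orientation == "+"
    if fwd_plus != rev_plus:
        return parts if fwd_plus else rev
    return parts if parts[0].contig_id <= rev[0].contig_id else rev


def build_scaffolds(
    bundles: Sequence[LinkBundle],
    contigs: dict[str, Contig],
    params: ModelParams,
    masked: Optional[set[str]] = None,
) -> tuple[list[ScaffoldLayout], list[Rejection]]:
    """Greedy best-first merging of contig ends.

    Bundles are visited in (posterior desc, pair count desc, correctness mass
    desc, lexicographic) order and accepted iff the posterior clears the
    threshold, neither contig is repeat-masked, both implicated ends are free
    and the union would not close a cycle.  Every contig ends up in exactly
    one layout; masked contigs stay singletons flagged as repeats.
    """
    masked = masked or set()
    ordered = sorted(
        bundles,
        key=lambda b: (
            -(b.posterior or 0.0), -b.n_pairs, -b.correctness_mass,
            b.contig_a, b.end_a, b.contig_b, b.end_b,
        ),
    )
    dsu = _DisjointSet()
    end_used: dict[tuple[str, str], LinkBundle] = {}
    accepted: list[LinkBundle] = []
    rejections: list[Rejection] = []
    for b in ordered:
        post = b.posterior or 0.0
        if post < params.posterior_threshold:
            rejections.append(Rejection(b.key, post, "below-threshold"))
            continue
        if b.contig_a in masked or b.contig_b in masked:
            rejections.append(Rejection(b.key, post, "repeat-masked"))
            continue
        ea, eb = (b.contig_a, b.end_a), (b.contig_b, b.end_b)
        if ea in end_used or eb in end_used:
            rejections.append(Rejection(b.key, post, "end-occupied"))
            continue
        if dsu.find(b.contig_a) == dsu.find(b.contig_b):
            rejections.append(Rejection(b.key, post, "cycle"))
            continue
        end_used[ea] = end_used[eb] = b
        dsu.union(b.contig_a, b.contig_b)
        accepted.append(b)

    # adjacency: (contig, end) -> (other contig, entry end on the other contig, bundle)
    adj: dict[tuple[str, str], tuple[str, str, LinkBundle]] = {}
    for b in accepted:
        adj[(b.contig_a, b.end_a)] = (b.contig_b, b.end_b, b)
        adj[(b.contig_b, b.end_b)] = (b.contig_a, b.end_a, b)

    joined = {c for b in accepted for c in (b.contig_a, b.contig_b)}
    visited: set[str] = set()
    raw_layouts: list[tuple[list[LayoutPart], list[LinkBundle]]] = []
    for cid in sorted(joined):
        if cid in visited:
            continue
        # walk to a terminal: a contig with at least one unused end, following
        # one direction until the chain stops (cycles are impossible)
        start, entry = cid, None
        seen_walk = {cid}
        while True:
            # try to extend "leftwards" through whichever end is not the entry
            ends = [HEAD, TAIL] if entry is None else [e for e in (HEAD, TAIL) if e != entry]
            step = None
            for e in ends:
                if (start, e) in adj:
                    step = adj[(start, e)]
                    break
            if step is None or step[0] in seen_walk:
                break
            start, entry = step[0], step[1]
            seen_walk.add(start)
        # traverse from the terminal; its exit end is its single joined end
        parts: list[LayoutPart] = []
        prov: list[LinkBundle] = []
        cur, entry_end = start, None
        while True:
            visited.add(cur)
            if entry_end is None:  # terminal: orientation set by its exit end
                exit_end = TAIL if (cur, TAIL) in adj else HEAD
                orient = "+" if exit_end == TAIL else "-"
            else:
                orient = "+" if entry_end == HEAD else "-"
                exit_end = TAIL if entry_end == HEAD else HEAD
            nxt = adj.get((cur, exit_end))
            if nxt is not None and nxt[0] not in visited:
                _, _, bundle = nxt
                parts.append(
                    LayoutPart(
                        cur, orient,
                        gap_after=bundle.gap_hat,
                        join_posterior=bundle.posterior,
                    )
                )
                prov.append(bundle)
                cur, entry_end = nxt[0], nxt[1]
            else:
                parts.append(LayoutPart(cur, orient))
                break
        raw_layouts.append((_canonicalize(parts), prov))

    for cid in sorted(contigs):
        if cid not in joined:
            raw_layouts.append(([LayoutPart(cid, "+")], []))

    # deterministic naming: big scaffolds first, ties by first contig id
    def total_len(parts: list[LayoutPart]) -> int:
        return sum(contigs[p.contig_id].length for p in parts)

    raw_layouts.sort(key=lambda lp: (-total_len(lp[0]), lp[0][0].contig_id))
    layouts = []
    for i, (parts, prov) in enumerate(raw_layouts, start=1):
        layouts.append(
            ScaffoldLayout(
                id=f"scaffold_{i}",
                parts=parts,
                provenance=[(b.key, b.posterior) for b in prov],
                repeat_flag=(len(parts) == 1 and parts[0].contig_id in masked),
            )
        )
    n_rej = {}
    for r in rejections:
        n_rej[r.reason] = n_rej.get(r.reason, 0) + 1
    logger.info(
        "scaffolding: %d joins accepted, rejections %s, %d layouts",
        len(accepted), n_rej, len(layouts),
    )
    return layouts, rejections
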