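"""Assembly metrics: N50, join precision/recall against a truth set,
orientation accuracy, anchored fraction."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io import Contig, ScaffoldLayout


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that objects of length >= L sum to at least half the total."""
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for L in ordered:
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable")


Adjacency = tuple[tuple[str, str], tuple[str, str]]  # ((ctg, strand), (ctg, strand))


def _predicted_adjacencies(layouts: Sequence[ScaffoldLayout]) -> list[Adjacency]:
    out: list[Adjacency] = []
    for lo in layouts:
        for a, b in zip(lo.parts, lo.parts[1:]):
            out.append(((a.contig_id, a.orientation), (b.contig_id, b.orientation)))
    return out


def _junction_matches(pred: Adjacency, truth: Adjacency) -> bool:
    """Same junction with compatible orientation, allowing the mirror image."""
    (p1, o1), (p2, o2) = pred
    (t1, s1), (t2, s2) = truth

    def flip(x: str) -> str:
        return "-" if x == "+" else "+"

    if (p1, p2) == (t1, t2):
        return o1 == s1 and o2 == s2
    if (p1, p2) == (t2, t1):
        return o1 == flip(s2) and o2 == flip(s1)
    return False


def join_accuracy(
    layouts: Sequence[ScaffoldLayout],
    true_adjacencies: Sequence[Adjacency],
) -> dict:
    """Precision, recall and orientation accuracy of predicted contig joins.

    A predicted adjacent pair is true iff its contigs are truth-adjacent with
    a compatible relative orientation (a layout and its mirror describe the
    same molecule, so both images count).  With no predicted joins, precision
    is reported as 1.0 with a 'no joins' flag rather than 0/0.
    """
    if true_adjacencies is None:
        raise ValueError("truth adjacencies are required")
    preds = _predicted_adjacencies(layouts)
    truth_by_pair: dict[frozenset, Adjacency] = {
        frozenset((t[0][0], t[1][0])): t for t in true_adjacencies
    }
    tp = 0
    adjacent_preds = 0
    oriented_ok = 0
    for pred in preds:
        key = frozenset((pred[0][0], pred[1][0]))
        truth = truth_by_pair.get(key)
        if truth is None:
            continue
        adjacent_preds += 1
        if _junction_matches(pred, truth):
            tp += 1
            oriented_ok += 1
    fp = len(preds) - tp
    flags = []
    if preds:
        precision = tp / len(preds)
    else:
        precision = 1.0
        flags.append("no joins")
    recall = tp / len(true_adjacencies) if true_adjacencies else 1.0
    orientation_accuracy = (
        oriented_ok / adjacent_preds if adjacent_preds else 1.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "orientation_accuracy": orientation_accuracy,
        "tp": tp,
        "fp": fp,
        "misjoins": fp,
        "n_predicted": len(preds),
        "n_true": len(true_adjacencies),
        "flags": flags,
    }


def anchored_fraction(
    pseudomolecule_layouts: Sequence[ScaffoldLayout],
    all_layouts: Sequence[ScaffoldLayout],
    contigs: dict[str, Contig],
) -> float:
    """Fraction of contig bases (gaps excluded) anchored into pseudomolecules."""
    anchored_ids = {
        p.contig_id for lo in pseudomolecule_layouts for p in lo.parts
    }
    all_ids = {p.contig_id for lo in all_layouts for p in lo.parts}
    total = sum(contigs[c].length for c in all_ids)
    if total == 0:
        return 0.0
    return sum(contigs[c].length for c in anchored_ids) / total


@dataclass
class EvalReport:
    n50: int
    total_bases: int
    n_objects: int
    join_precision: float
    join_recall: float
    orientation_accuracy: float
    misjoins: int
    anchored_fraction: float
    per_chromosome_rho: dict[str, Optional[float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n50": self.n50,
            "total_bases": self.total_bases,
            "n_objects": self.n_objects,
            "join_precision": self.join_precision,
            "join_recall": self.join_recall,
            "orientation_accuracy": self.orientation_accuracy,
            "misjoins": self.misjoins,
            "anchored_fraction": self.anchored_fraction,
            "per_chromosome_rho": self.per_chromosome_rho,
            "flags": self.flags,
        }


def evaluate_assembly(
    scaffold_layouts: Sequence[ScaffoldLayout],
    pseudomolecule_layouts: Sequence[ScaffoldLayout],
    contigs: dict[str, Contig],
    true_adjacencies: Sequence[Adjacency],
    per_chromosome_rho: Optional[dict[str, Optional[float]]] = None,
) -> EvalReport:
    """Bundle the standard metrics of one run into a report."""
    from .io import layout_sequence

    lengths = [len(layout_sequence(lo, contigs)) for lo in scaffold_layouts]
    acc = join_accuracy(scaffold_layouts, true_adjacencies)
    return EvalReport(
        n50=n50(lengths),
        total_bases=sum(lengths),
        n_objects=len(lengths),
        join_precision=acc["precision"],
        join_recall=acc["recall"],
        orientation_accuracy=acc["orientation_accuracy"],
        misjoins=acc["misjoins"],
        anchored_fraction=anchored_fraction(
            pseudomolecule_layouts, scaffold_layouts, contigs
        ),
        per_chromosome_rho=per_chromosome_rho or {},
        flags=acc["flags"],
    )
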