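"""The Bayesian core of the scaffolder.

Each read pair whose mates map to two different contigs is evidence for one
join hypothesis: (contig A end, contig B end, relative orientation).  The pair
is modelled as a mixture — with probability c_i (the product of the two mates'
MAPQ-derived correctness probabilities) it is a correctly mapped fragment
whose outer span follows the library's insert-size distribution
N(mu, sigma^2); with probability 1 - c_i it is mapping noise whose implied
span is uniform over a window W.  The per-pair Bayes factor in favour of the
join being real is therefore

    f_i = c_i * N(d_i; mu, sigma^2) * W + (1 - c_i)

where d_i is the pair's implied outer span at the bundle's gap estimate.  The
cumulative Bayes factor B = prod f_i updates the prior pi to the posterior
pi*B / (pi*B + 1 - pi).  Bundles are scored per library and fused across
libraries by multiplying Bayes factors before applying the prior once.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .io import Contig, Library, ReadPairAlignment, MateAlignment

logger = logging.getLogger(__name__)

HEAD = "head"
TAIL = "tail"


@dataclass
class ModelParams:
    """All tunable constants of the link model and its downstream consumers.

    prior_pi
        Prior probability that a candidate contig-end adjacency is real.
    noise_window_sigmas
        The noise window is W = insert_mu + this * insert_sigma per library.
    consistency_sigmas
        Pairs implying an outer span beyond insert_mu + this * insert_sigma
        from any admissible gap are discarded as inconsistent.
    min_pairs / bac_min_pairs
        Minimum supporting pairs per bundle (scarce BAC-end libraries get the
        lower floor).
    posterior_threshold
        Acceptance cutoff for a join.
    max_overlap
        Most negative allowed gap; ``None`` means the library's read length.
    min_fit_pairs
        Same-contig pairs needed before the declared insert profile is
        replaced by a robust fit.
    """

    prior_pi: float = 0.01
    posterior_threshold: float = 0.99
    min_pairs: int = 2
    bac_min_pairs: int = 1
    noise_window_sigmas: float = 3.0
    consistency_sigmas: float = 4.0
    max_overlap: Optional[int] = None
    min_fit_pairs: int = 50
    # scaffolder
    repeat_cov_factor: float = 2.5
    max_degree: int = 3
    # anchoring
    chimera_cm_window: float = 20.0
    discord_eps: float = 0.01
    pseudo_gap: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.prior_pi < 1:
            raise ValueError("prior_pi must be in (0, 1)")
        if not 0 < self.posterior_threshold < 1:
            raise ValueError("posterior_threshold must be in (0, 1)")
        if self.noise_window_sigmas <= 0:
            raise ValueError("noise_window_sigmas must be positive")

    def noise_window(self, library: Library) -> float:
        return library.insert_mu + self.noise_window_sigmas * library.insert_sigma

    def overlap_limit(self, library: Library) -> int:
        return self.max_overlap if self.max_overlap is not None else library.read_len

    def min_pairs_for(self, library: Library) -> int:
        return self.bac_min_pairs if library.is_bac else self.min_pairs


@dataclass
class LinkBundle:
    """All read pairs supporting one (end A, end B, orientation) hypothesis."""

    contig_a: str
    end_a: str  # HEAD or TAIL
    contig_b: str
    end_b: str
    library_ids: tuple[str, ...]
    pairs: list[ReadPairAlignment]
    flank_sums: list[float]  # s_i: summed flank distance of pair i to the two ends
    posterior: Optional[float] = None
    gap_hat: Optional[float] = None
    gap_sd: Optional[float] = None
    log_bf: Optional[float] = None

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.contig_a, self.end_a, self.contig_b, self.end_b)

    @property
    def rel_orientation(self) -> str:
        """Joined-orientation class, e.g. 'tail-head' = A+ then B+."""
        return f"{self.end_a}-{self.end_b}"

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def correctness_mass(self) -> float:
        # pairs may be placeholders when a bundle was rehydrated from a table
        return sum(pair_correctness(p) for p in self.pairs if p is not None)


def mapq_to_prob(q: float) -> float:
    """Phred MAPQ to P(placement correct) = 1 - 10^(-q/10)."""
    if q < 0:
        raise ValueError(f"negative mapping quality {q}")
    return 1.0 - 10.0 ** (-q / 10.0)


def pair_correctness(pair: ReadPairAlignment) -> float:
    """Probability both mates are placed correctly."""
    return mapq_to_prob(pair.mate1.mapq) * mapq_to_prob(pair.mate2.mapq)


# ---------------------------------------------------------------------------
# insert-size estimation
# ---------------------------------------------------------------------------


def _mate_direction(mate: MateAlignment, library: Library) -> str:
    """Which way the mate 'points' along its contig ('right' or 'left').

    For innie libraries a forward-strand mate points right (its partner lies
    beyond the contig tail); outie libraries are mirrored.
    """
    right = mate.strand == "+"
    if library.orientation == "outie":
        right = not right
    return "right" if right else "left"


def _mate_end_flank(
    mate: MateAlignment, contig_len: int, library: Library
) -> tuple[str, float]:
    """(contig end implicated, flank distance contributing to the outer span)."""
    if _mate_direction(mate, library) == "right":
        return TAIL, float(contig_len - mate.pos)
    return HEAD, float(mate.pos + mate.aln_len)


def outer_span(pair: ReadPairAlignment) -> int:
    """Outer distance of a same-contig pair."""
    m1, m2 = pair.mate1, pair.mate2
    left = min(m1.pos, m2.pos)
    right = max(m1.pos + m1.aln_len, m2.pos + m2.aln_len)
    return right - left


def _same_contig_consistent(pair: ReadPairAlignment, library: Library) -> bool:
    """Both mates on one contig in the library's expected relative orientation."""
    m1, m2 = pair.mate1, pair.mate2
    if m1.contig_id != m2.contig_id or m1.strand == m2.strand:
        return False
    leftmost = m1 if m1.pos <= m2.pos else m2
    expected = "+" if library.orientation == "innie" else "-"
    return leftmost.strand == expected


def estimate_insert_distribution(
    alignments: Sequence[ReadPairAlignment],
    library: Library,
    min_fit_pairs: int = 50,
) -> tuple[float, float, int]:
    """Robust (median, scaled-MAD) fit of a library's insert-size profile.

    Uses same-contig orientation-consistent pairs only.  With fewer than
    ``min_fit_pairs`` observations the declared library values are kept; a
    zero MAD floors sigma at 1.0.  Returns (mu, sigma, n_pairs_used).
    """
    spans = np.array(
        [
            outer_span(p)
            for p in alignments
            if p.library_id == library.id and _same_contig_consistent(p, library)
        ],
        dtype=float,
    )
    if spans.size < min_fit_pairs:
        logger.warning(
            "library %s: only %d same-contig pairs (< %d); keeping declared "
            "insert profile", library.id, spans.size, min_fit_pairs,
        )
        return library.insert_mu, library.insert_sigma, int(spans.size)
    mu = float(np.median(spans))
    mad = float(np.median(np.abs(spans - mu)))
    sigma = max(1.4826 * mad, 1.0)
    return mu, sigma, int(spans.size)


def fit_libraries(
    alignments: Sequence[ReadPairAlignment],
    libraries: dict[str, Library],
    params: ModelParams,
) -> dict[str, Library]:
    """Return libraries with insert profiles re-fitted from the data."""
    fitted = {}
    for lib_id, lib in libraries.items():
        mu, sigma, _n = estimate_insert_distribution(
            alignments, lib, params.min_fit_pairs
        )
        fitted[lib_id] = replace(lib, insert_mu=mu, insert_sigma=sigma)
    return fitted


# ---------------------------------------------------------------------------
# bundling
# ---------------------------------------------------------------------------


def bundle_links(
    alignments: Sequence[ReadPairAlignment],
    contigs: dict[str, Contig],
    libraries: dict[str, Library],
    params: ModelParams,
) -> list[LinkBundle]:
    """Group cross-contig pairs into per-library join hypotheses.

    Pairs implying an outer span unreachable from any admissible gap
    (> mu + consistency_sigmas * sigma even at the maximum overlap) are
    discarded; bundles below the library's minimum pair count are dropped.
    Same-contig pairs never enter a bundle.
    """
    groups: dict[tuple, tuple[list[ReadPairAlignment], list[float]]] = {}
    for pair in alignments:
        m1, m2 = pair.mate1, pair.mate2
        if m1.contig_id == m2.contig_id:
            continue
        lib = libraries[pair.library_id]
        end1, flank1 = _mate_end_flank(m1, contigs[m1.contig_id].length, lib)
        end2, flank2 = _mate_end_flank(m2, contigs[m2.contig_id].length, lib)
        s = flank1 + flank2
        limit = (
            lib.insert_mu
            + params.consistency_sigmas * lib.insert_sigma
            + params.overlap_limit(lib)
        )
        if s > limit:
            continue
        if m1.contig_id <= m2.contig_id:
            key = (m1.contig_id, end1, m2.contig_id, end2, lib.id)
        else:
            key = (m2.contig_id, end2, m1.contig_id, end1, lib.id)
        entry = groups.setdefault(key, ([], []))
        entry[0].append(pair)
        entry[1].append(s)

    bundles = []
    for (ca, ea, cb, eb, lib_id), (pairs, flanks) in sorted(groups.items()):
        if len(pairs) < params.min_pairs_for(libraries[lib_id]):
            continue
        bundles.append(
            LinkBundle(ca, ea, cb, eb, (lib_id,), pairs, flanks)
        )
    return bundles


# ---------------------------------------------------------------------------
# gap estimation and posterior
# ---------------------------------------------------------------------------


def estimate_gap(
    bundle: LinkBundle, library: Library, params: ModelParams
) -> tuple[float, float]:
    """Gap-size MLE under the Normal insert model.

    Maximizing sum_i log N(s_i + g; mu, sigma^2) gives the closed form
    g = mu - mean(s_i), clipped at the maximum allowed overlap; the standard
    error is sigma / sqrt(k).
    """
    if not bundle.pairs:
        raise ValueError("cannot estimate a gap from an empty bundle")
    g = library.insert_mu - float(np.mean(bundle.flank_sums))
    g = max(g, -float(params.overlap_limit(library)))
    sd = library.insert_sigma / math.sqrt(len(bundle.pairs))
    return g, sd


def link_log_bayes_factor(
    bundle: LinkBundle, library: Library, params: ModelParams,
    gap: Optional[float] = None,
) -> float:
    """log of the cumulative Bayes factor B = prod_i f_i at the gap estimate."""
    if gap is None:
        gap = bundle.gap_hat
        if gap is None:
            gap, _ = estimate_gap(bundle, library, params)
    W = params.noise_window(library)
    log_bf = 0.0
    for pair, s in zip(bundle.pairs, bundle.flank_sums):
        c = pair_correctness(pair)
        d = s + gap
        like = norm.pdf(d, loc=library.insert_mu, scale=library.insert_sigma)
        f = c * like * W + (1.0 - c)
        log_bf += math.log(max(f, 1e-300))
    return log_bf


def posterior_from_log_bf(log_bf: float, prior_pi: float) -> float:
    """pi*B / (pi*B + 1 - pi), computed stably on the log-odds scale."""
    log_odds = math.log(prior_pi) - math.log1p(-prior_pi) + log_bf
    return float(expit(log_odds))


def link_posterior(
    bundle: LinkBundle, library: Library, params: ModelParams
) -> float:
    """Posterior probability that the bundle's join is a true adjacency.

    A bundle with no supporting pairs carries no evidence (B = 1) and returns
    the prior exactly.
    """
    if not bundle.pairs:
        logger.warning("bundle %s: no supporting pairs; returning prior", bundle.key)
        return params.prior_pi
    return posterior_from_log_bf(
        link_log_bayes_factor(bundle, library, params), params.prior_pi
    )


def _fuse(per_lib: list[tuple[LinkBundle, Library]], params: ModelParams) -> LinkBundle:
    """Fuse same-end-pair bundles across libraries.

    Bayes factors multiply (the prior is applied once); gap estimates combine
    by inverse-variance weighting, which is the joint Normal MLE.
    """
    first = per_lib[0][0]
    pairs: list[ReadPairAlignment] = []
    flanks: list[float] = []
    lib_ids: list[str] = []
    log_bf = 0.0
    wsum = 0.0
    gsum = 0.0
    for b, lib in per_lib:
        pairs.extend(b.pairs)
        flanks.extend(b.flank_sums)
        lib_ids.extend(b.library_ids)
        log_bf += b.log_bf
        w = len(b.pairs) / lib.insert_sigma ** 2
        wsum += w
        gsum += w * b.gap_hat
    fused = LinkBundle(
        first.contig_a, first.end_a, first.contig_b, first.end_b,
        tuple(lib_ids), pairs, flanks,
        gap_hat=gsum / wsum,
        gap_sd=1.0 / math.sqrt(wsum),
        log_bf=log_bf,
        posterior=posterior_from_log_bf(log_bf, params.prior_pi),
    )
    return fused


def score_links(
    alignments: Sequence[ReadPairAlignment],
    contigs: dict[str, Contig],
    libraries: dict[str, Library],
    params: ModelParams,
    refit_inserts: bool = True,
) -> list[LinkBundle]:
    """Full link-model pass: fit inserts, bundle, estimate gaps, score, fuse.

    Returns one scored bundle per (end A, end B) hypothesis, platform evidence
    merged, sorted by (posterior desc, pair count desc, correctness mass desc,
    contig ids).
    """
    if refit_inserts:
        libraries = fit_libraries(alignments, libraries, params)
    per_lib = bundle_links(alignments, contigs, libraries, params)
    for b in per_lib:
        lib = libraries[b.library_ids[0]]
        b.gap_hat, b.gap_sd = estimate_gap(b, lib, params)
        b.log_bf = link_log_bayes_factor(b, lib, params)
        b.posterior = posterior_from_log_bf(b.log_bf, params.prior_pi)
    by_key: dict[tuple, list[tuple[LinkBundle, Library]]] = {}
    for b in per_lib:
        by_key.setdefault(b.key, []).append((b, libraries[b.library_ids[0]]))
    fused = [_fuse(group, params) for group in by_key.values()]
    fused.sort(
        key=lambda b: (
            -b.posterior, -b.n_pairs, -b.correctness_mass,
            b.contig_a, b.end_a, b.contig_b, b.end_b,
        )
    )
    return fused
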