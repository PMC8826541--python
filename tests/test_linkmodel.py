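"""Link model: MAPQ conversion, insert fitting, bundling, posterior and gap MLE."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from baylink import io, linkmodel as lm
from baylink import scaffold, simulate


def make_pair(pid, c1, p1, s1, q1, c2, p2, s2, q2, lib="mp", aln_len=100):
    return io.ReadPairAlignment(
        pid, lib,
        io.MateAlignment(c1, p1, s1, q1, aln_len),
        io.MateAlignment(c2, p2, s2, q2, aln_len),
    )


MP = io.Library("mp", 3000, 300, "innie", 100)
LIBS = {"mp": MP}


# ---------------------------------------------------------------------------
# MAPQ
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("q, p", [(0, 0.0), (10, 0.9), (60, 0.999999)])
def test_mapq_phred_conversion(q, p):
    assert lm.mapq_to_prob(q) == pytest.approx(p, abs=1e-12)


def test_mapq_negative_rejected_and_monotone():
    with pytest.raises(ValueError):
        lm.mapq_to_prob(-1)
    qs = [lm.mapq_to_prob(q) for q in range(0, 80, 5)]
    assert all(a < b for a, b in zip(qs, qs[1:]))
    assert all(0 <= p < 1 for p in qs)


# ---------------------------------------------------------------------------
# insert-size estimation
# ---------------------------------------------------------------------------


def _same_contig_pairs(spans, contig="X", lib="mp"):
    # innie pair: forward mate at 0, reverse mate ending at span
    return [
        make_pair(f"p{i}", contig, 0, "+", 40, contig, s - 100, "-", 40, lib=lib)
        for i, s in enumerate(spans)
    ]


def test_insert_fit_median_and_scaled_mad():
    pairs = _same_contig_pairs([2900, 3000, 3100])
    mu, sigma, n = lm.estimate_insert_distribution(pairs, MP, min_fit_pairs=3)
    assert (mu, n) == (3000, 3)
    assert sigma == pytest.approx(148.26)


def test_insert_fit_degenerate_sigma_floor():
    pairs = _same_contig_pairs([500] * 5)
    mu, sigma, _ = lm.estimate_insert_distribution(pairs, MP, min_fit_pairs=3)
    assert (mu, sigma) == (500, 1.0)


def test_insert_fit_keeps_declared_values_when_underpowered(caplog):
    pairs = _same_contig_pairs([2900, 3100])
    mu, sigma, n = lm.estimate_insert_distribution(pairs, MP, min_fit_pairs=3)
    assert (mu, sigma, n) == (MP.insert_mu, MP.insert_sigma, 2)


# ---------------------------------------------------------------------------
# bundling
# ---------------------------------------------------------------------------

CONTIGS = {
    "A": io.Contig("A", "A" * 5000),
    "B": io.Contig("B", "C" * 5000),
}


def test_bundling_groups_same_hypothesis(params):
    # both pairs imply tail(A) <-> head(B), same orientation
    pairs = [
        make_pair("p1", "A", 4500, "+", 40, "B", 1900, "-", 40),
        make_pair("p2", "A", 4300, "+", 40, "B", 2100, "-", 40),
    ]
    bundles = lm.bundle_links(pairs, CONTIGS, LIBS, params)
    assert len(bundles) == 1
    b = bundles[0]
    assert b.key == ("A", lm.TAIL, "B", lm.HEAD)
    assert b.n_pairs == 2


def test_conflicting_orientations_make_separate_bundles(params):
    # one pair forward (tail-head), one reversed (tail-tail): two candidate
    # hypotheses, both below min_pairs=2, so both are dropped
    pairs = [
        make_pair("p1", "A", 4500, "+", 40, "B", 1900, "-", 40),
        make_pair("p2", "A", 4500, "+", 40, "B", 3000, "+", 40),
    ]
    assert lm.bundle_links(pairs, CONTIGS, LIBS, params) == []
    relaxed = lm.ModelParams(min_pairs=1)
    assert len(lm.bundle_links(pairs, CONTIGS, LIBS, relaxed)) == 2


def test_same_contig_pairs_never_bundle(params):
    pairs = _same_contig_pairs([3000, 3000, 2900])
    assert lm.bundle_links(pairs, {"X": io.Contig("X", "G" * 4000)}, LIBS, params) == []


def test_inconsistent_span_pairs_discarded(params):
    # implied span beyond mu + 4 sigma + max_overlap even at full overlap
    pairs = [
        make_pair("p1", "A", 100, "+", 40, "B", 2000, "-", 40),  # s = 7000
        make_pair("p2", "A", 50, "+", 40, "B", 2100, "-", 40),
    ]
    assert lm.bundle_links(pairs, CONTIGS, LIBS, params) == []


# ---------------------------------------------------------------------------
# posterior
# ---------------------------------------------------------------------------


def test_zero_evidence_returns_prior_exactly(params):
    b = lm.LinkBundle("A", lm.TAIL, "B", lm.HEAD, ("mp",), [], [])
    for pi in (0.01, 0.1, 0.5):
        p = lm.ModelParams(prior_pi=pi)
        assert lm.link_posterior(b, MP, p) == pytest.approx(pi, abs=1e-15)
        assert lm.posterior_from_log_bf(0.0, pi) == pytest.approx(pi, abs=1e-15)


def test_single_perfect_pair_worked_example(params):
    """One pair, c ~ 1, implied span exactly mu: the Bayes factor is
    N(mu; mu, 300^2) * 3900 = 5.187 and the posterior 0.0498.

    The expected value is recomputed here with independent direct-space
    arithmetic rather than the package's log-space path.
    """
    pair = make_pair("p", "A", 0, "+", 10_000, "B", 0, "-", 10_000)
    b = lm.LinkBundle("A", lm.TAIL, "B", lm.HEAD, ("mp",), [pair], [3000.0])
    post = lm.posterior_from_log_bf(
        lm.link_log_bayes_factor(b, MP, params, gap=0.0), 0.01
    )
    # independent oracle: plain probability arithmetic
    c = (1 - 10 ** (-1000)) ** 2
    f = c * (1 / (300 * math.sqrt(2 * math.pi))) * 3900 + (1 - c)
    expected = 0.01 * f / (0.01 * f + 0.99)
    assert f == pytest.approx(5.187, abs=2e-3)
    assert post == pytest.approx(expected, abs=1e-12)
    assert post == pytest.approx(0.0498, abs=1e-4)


def test_posterior_monotone_in_consistent_evidence(params):
    def bundle(k):
        pairs = [make_pair(f"p{i}", "A", 0, "+", 40, "B", 0, "-", 40)
                 for i in range(k)]
        return lm.LinkBundle("A", lm.TAIL, "B", lm.HEAD, ("mp",),
                             pairs, [3000.0] * k)
    posts = [lm.link_posterior(bundle(k), MP, params) for k in (1, 2, 5)]
    assert posts[0] < posts[1] < posts[2]


def _random_bundle(rng, max_pairs=6):
    k = int(rng.integers(1, max_pairs + 1))
    pairs, flanks = [], []
    for i in range(k):
        q1, q2 = int(rng.integers(0, 61)), int(rng.integers(0, 61))
        pairs.append(make_pair(f"p{i}", "A", 0, "+", q1, "B", 0, "-", q2))
        flanks.append(float(rng.uniform(200, 3800)))
    return lm.LinkBundle("A", lm.TAIL, "B", lm.HEAD, ("mp",), pairs, flanks)


def test_log_space_matches_direct_space_oracle(params):
    """The log-space posterior agrees with naive direct-space multiplication
    to 1e-9 for bundles of up to six pairs."""
    rng = np.random.default_rng(17)
    W = params.noise_window(MP)
    for _ in range(200):
        b = _random_bundle(rng)
        gap, _ = lm.estimate_gap(b, MP, params)
        post = lm.posterior_from_log_bf(
            lm.link_log_bayes_factor(b, MP, params, gap=gap), params.prior_pi
        )
        # direct-space oracle
        B = 1.0
        for pair, s in zip(b.pairs, b.flank_sums):
            c = lm.pair_correctness(pair)
            d = s + gap
            B *= c * norm.pdf(d, MP.insert_mu, MP.insert_sigma) * W + (1 - c)
        expected = params.prior_pi * B / (params.prior_pi * B + 1 - params.prior_pi)
        assert post == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# gap MLE
# ---------------------------------------------------------------------------


def test_gap_closed_form_worked_example(params):
    pairs = [make_pair(f"p{i}", "A", 0, "+", 40, "B", 0, "-", 40) for i in range(2)]
    b = lm.LinkBundle("A", lm.TAIL, "B", lm.HEAD, ("mp",), pairs, [2500.0, 2700.0])
    gap, sd = lm.estimate_gap(b, MP, params)
    assert gap == pytest.approx(400.0)
    assert sd == pytest.approx(300 / math.sqrt(2))


def test_gap_clipped_at_max_overlap():
    pair = make_pair("p", "A", 0, "+", 40, "B", 0, "-", 40)
    b = lm.LinkBundle("A", lm.TAIL, "B", lm.HEAD, ("mp",), [pair], [3500.0])
    gap, _ = lm.estimate_gap(b, MP, lm.ModelParams(max_overlap=100))
    assert gap == -100.0


def test_gap_of_empty_bundle_is_an_error(params):
    b = lm.LinkBundle("A", lm.TAIL, "B", lm.HEAD, ("mp",), [], [])
    with pytest.raises(ValueError):
        lm.estimate_gap(b, MP, params)


def test_gap_mle_matches_grid_search_oracle(params):
    """The closed form agrees with 1-D grid maximization of the summed
    log-likelihood within one base across random bundles."""
    rng = np.random.default_rng(29)
    for _ in range(100):
        b = _random_bundle(rng)
        gap, _ = lm.estimate_gap(b, MP, params)
        lo = -params.overlap_limit(MP)
        hi = MP.insert_mu + 4 * MP.insert_sigma
        grid = np.arange(lo, hi + 0.25, 0.25)
        ll = np.zeros_like(grid)
        for s in b.flank_sums:
            ll += norm.logpdf(s + grid, MP.insert_mu, MP.insert_sigma)
        assert abs(gap - grid[np.argmax(ll)]) <= 1.0


# ---------------------------------------------------------------------------
# calibration on simulation
# ---------------------------------------------------------------------------


def test_true_joins_score_higher_than_false_joins_on_average():
    """With mismapping on, bundles supporting true adjacencies have a higher
    mean posterior than spurious bundles (mate-pair library only, so every
    non-adjacent hypothesis is mapping noise)."""
    sc = simulate.clean_scenario(
        seed=11, chromosome_length=120_000, n_contigs_per_chromosome=8,
        n_markers_per_chromosome=4, n_holdout_per_chromosome=0,
        mismap_rate=0.05, bac_coverage=0.0,
    )
    params = lm.ModelParams(min_pairs=1)
    bundles = lm.score_links(sc.alignments, sc.contigs, sc.libraries, params)
    truth_pairs = {
        frozenset((a[0], b[0])) for a, b in sc.truth.true_adjacencies()
    }
    true_post = [b.posterior for b in bundles
                 if frozenset((b.contig_a, b.contig_b)) in truth_pairs]
    false_post = [b.posterior for b in bundles
                  if frozenset((b.contig_a, b.contig_b)) not in truth_pairs]
    assert true_post and false_post
    assert np.mean(true_post) > np.mean(false_post)
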