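"""Anchoring: marker placement, chimera surgery, ordering/orientation, colinearity."""

import numpy as np
import pytest

from baylink import anchor, io, linkmodel as lm


def dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture()
def scaffold_world():
    """Two scaffolds of two contigs each with known sequence."""
    rng = np.random.default_rng(5)
    contigs = {
        "c0": io.Contig("c0", dna(rng, 400)),
        "c1": io.Contig("c1", dna(rng, 300)),
        "c2": io.Contig("c2", dna(rng, 350)),
        "c3": io.Contig("c3", dna(rng, 250)),
    }
    layouts = [
        io.ScaffoldLayout("s1", [
            io.LayoutPart("c0", "+", gap_after=50.0, join_posterior=0.995),
            io.LayoutPart("c1", "-"),
        ]),
        io.ScaffoldLayout("s2", [
            io.LayoutPart("c2", "+", gap_after=40.0, join_posterior=0.999),
            io.LayoutPart("c3", "+"),
        ]),
    ]
    return contigs, layouts


# ---------------------------------------------------------------------------
# marker placement
# ---------------------------------------------------------------------------


def test_unique_sequence_marker_placed_at_offset(scaffold_world):
    contigs, layouts = scaffold_world
    probe = contigs["c2"].sequence[100:121]  # 21-mer inside scaffold s2
    gmap = io.GeneticMap([io.Marker("m", "2", 3.0, seq=probe)])
    (p,) = anchor.place_markers(gmap, layouts, contigs)
    assert (p.status, p.scaffold_id, p.scaffold_pos) == ("placed", "s2", 100)


def test_multi_hit_marker_is_ambiguous(scaffold_world):
    contigs, layouts = scaffold_world
    contigs = dict(contigs)
    # duplicate a 21-mer of c0 into c3 so the marker hits two scaffolds
    probe = contigs["c0"].sequence[10:31]
    contigs["c3"] = io.Contig("c3", probe + contigs["c3"].sequence[21:])
    gmap = io.GeneticMap([io.Marker("m", "1", 1.0, seq=probe)])
    (p,) = anchor.place_markers(gmap, layouts, contigs)
    assert p.status == "ambiguous"


def test_reverse_strand_hit_and_zero_hits(scaffold_world):
    contigs, layouts = scaffold_world
    probe = io.revcomp(contigs["c2"].sequence[100:121])
    gmap = io.GeneticMap([
        io.Marker("fwd_on_minus", "2", 1.0, seq=probe),
        io.Marker("absent", "2", 2.0, seq="ACGT" * 8),
    ])
    placements = {p.marker_id: p for p in anchor.place_markers(gmap, layouts, contigs)}
    assert placements["fwd_on_minus"].status == "placed"
    assert placements["fwd_on_minus"].scaffold_pos == 100
    assert placements["absent"].status == "unplaced"


def test_coordinate_marker_lift_through_minus_contig(scaffold_world):
    contigs, layouts = scaffold_world
    # c1 is '-' in s1 at offset 400 + 50 = 450; lifted base of offset o is
    # start + (len - 1 - o)
    gmap = io.GeneticMap([io.Marker("m", "1", 2.0, contig_id="c1", offset=20)])
    (p,) = anchor.place_markers(gmap, layouts, contigs)
    assert (p.scaffold_id, p.scaffold_pos) == ("s1", 450 + 300 - 1 - 20)


def test_coordinate_marker_on_unknown_contig_unplaced(scaffold_world):
    contigs, layouts = scaffold_world
    gmap = io.GeneticMap([io.Marker("m", "1", 2.0, contig_id="nope", offset=0)])
    (p,) = anchor.place_markers(gmap, layouts, contigs)
    assert p.status == "unplaced"


# ---------------------------------------------------------------------------
# chimera surgery
# ---------------------------------------------------------------------------


def chimeric_world():
    """One scaffold of four contigs whose markers disagree on linkage group."""
    rng = np.random.default_rng(9)
    contigs = {f"k{i}": io.Contig(f"k{i}", dna(rng, 1000)) for i in range(4)}
    layout = io.ScaffoldLayout("s1", [
        io.LayoutPart("k0", "+", gap_after=20.0, join_posterior=0.9999),
        io.LayoutPart("k1", "+", gap_after=20.0, join_posterior=0.991),  # weakest
        io.LayoutPart("k2", "+", gap_after=20.0, join_posterior=0.9995),
        io.LayoutPart("k3", "+"),
    ])
    gmap = io.GeneticMap([
        io.Marker("a", "1", 0.0, contig_id="k0", offset=100),
        io.Marker("b", "1", 3.0, contig_id="k0", offset=900),
        io.Marker("c", "2", 0.0, contig_id="k3", offset=100),
        io.Marker("d", "2", 4.0, contig_id="k3", offset=800),
    ])
    return contigs, [layout], gmap


def test_chimera_split_at_lowest_posterior_join(params):
    contigs, layouts, gmap = chimeric_world()
    before = sum(c.length for c in contigs.values())
    revised, breaks, unresolvable = anchor.detect_and_break_chimeras(
        layouts, gmap, contigs, params
    )
    assert unresolvable == set()
    assert len(breaks) == 1 and breaks[0].join_posterior == 0.991
    assert {tuple(lo.contig_ids()) for lo in revised} == {
        ("k0", "k1"), ("k2", "k3")
    }
    after = sum(
        contigs[c].length for lo in revised for c in lo.contig_ids()
    )
    assert after == before  # breaking never loses sequence


def test_concordant_markers_do_not_break(params):
    contigs, layouts, _ = chimeric_world()
    gmap = io.GeneticMap([
        io.Marker("a", "1", 0.0, contig_id="k0", offset=100),
        io.Marker("b", "1", 2.0, contig_id="k1", offset=500),
        io.Marker("c", "1", 4.5, contig_id="k3", offset=100),
    ])
    revised, breaks, unresolvable = anchor.detect_and_break_chimeras(
        layouts, gmap, contigs, params
    )
    assert breaks == [] and unresolvable == set()
    assert len(revised) == 1


def test_conflict_inside_single_contig_is_unresolvable(params):
    rng = np.random.default_rng(13)
    contigs = {"solo": io.Contig("solo", dna(rng, 2000))}
    layouts = [io.ScaffoldLayout("s1", [io.LayoutPart("solo", "+")])]
    gmap = io.GeneticMap([
        io.Marker("a", "1", 0.0, contig_id="solo", offset=100),
        io.Marker("b", "2", 0.0, contig_id="solo", offset=1800),
    ])
    revised, breaks, unresolvable = anchor.detect_and_break_chimeras(
        layouts, gmap, contigs, params
    )
    assert breaks == [] and unresolvable == {"s1"}


def test_large_same_lg_discordance_triggers_break(params):
    contigs, layouts, _ = chimeric_world()
    # cm regresses by 30 cM against the ascending trend between k1 and k2
    gmap = io.GeneticMap([
        io.Marker("a", "1", 10.0, contig_id="k0", offset=100),
        io.Marker("b", "1", 40.0, contig_id="k1", offset=500),
        io.Marker("c", "1", 5.0, contig_id="k2", offset=500),
        io.Marker("d", "1", 42.0, contig_id="k3", offset=500),
    ])
    revised, breaks, _ = anchor.detect_and_break_chimeras(
        layouts, gmap, contigs, params
    )
    assert breaks and breaks[0].reason == "cm-discordant"


# ---------------------------------------------------------------------------
# ordering and orientation
# ---------------------------------------------------------------------------


def placements_for(scaffold_markers):
    out = []
    for sid, markers in scaffold_markers.items():
        for mid, lg, cm, pos in markers:
            out.append(anchor.MarkerPlacement(mid, lg, cm, anchor.PLACED, sid, pos))
    return out


def single_contig_layouts(ids, length=1000):
    rng = np.random.default_rng(3)
    contigs = {f"x{i}": io.Contig(f"x{i}", dna(rng, length)) for i in ids}
    layouts = [
        io.ScaffoldLayout(f"s{i}", [io.LayoutPart(f"x{i}", "+")]) for i in ids
    ]
    return contigs, layouts


def test_scaffolds_ordered_by_mean_cm(params):
    contigs, layouts = single_contig_layouts(range(3))
    gmap = io.GeneticMap([io.Marker(f"m{i}", "1", float(i), seq="ACGT" * 8)
                          for i in range(3)])
    placements = placements_for({
        "s0": [("p0", "1", 25.0, 100), ("p1", "1", 25.0, 800)],
        "s1": [("p2", "1", 10.0, 100)],
        "s2": [("p3", "1", 40.0, 100), ("p4", "1", 40.0, 900)],
    })
    pseudos, unanchored = anchor.order_and_orient(
        layouts, placements, gmap, contigs, params
    )
    (pm,) = pseudos
    assert pm.scaffold_ids() == ["s1", "s0", "s2"]
    assert unanchored == []


def test_orientation_from_cm_slope_sign(params):
    contigs, layouts = single_contig_layouts(range(2), length=100_000)
    gmap = io.GeneticMap([io.Marker("m", "1", 0.0, seq="ACGT" * 8)])
    placements = placements_for({
        "s0": [("a", "1", 30.0, 1000), ("b", "1", 12.0, 80_000)],  # descending
        "s1": [("c", "1", 35.0, 500)],
    })
    pseudos, _ = anchor.order_and_orient(layouts, placements, gmap, contigs, params)
    (pm,) = pseudos
    entries = dict((sid, (o, conf)) for sid, o, conf in pm.entries)
    assert entries["s0"] == ("-", "two_plus_markers")
    assert entries["s1"] == ("+", "single_marker")


def test_unmarked_scaffolds_are_unanchored(params):
    contigs, layouts = single_contig_layouts(range(2))
    gmap = io.GeneticMap([io.Marker("m", "1", 0.0, seq="ACGT" * 8)])
    placements = placements_for({"s0": [("a", "1", 5.0, 10)]})
    pseudos, unanchored = anchor.order_and_orient(
        layouts, placements, gmap, contigs, params
    )
    assert pseudos[0].scaffold_ids() == ["s0"]
    assert unanchored == ["s1"]
    # anchoring partition: every scaffold is in exactly one of the two sets
    assert sorted(pseudos[0].scaffold_ids() + unanchored) == ["s0", "s1"]


# ---------------------------------------------------------------------------
# colinearity
# ---------------------------------------------------------------------------


def colinearity_of(cms):
    """Run the QC on one single-contig chromosome whose markers sit at
    increasing physical positions with the given cM values."""
    rng = np.random.default_rng(21)
    seq = dna(rng, (len(cms) + 2) * 40)
    contigs = {"c": io.Contig("c", seq)}
    chrom = [io.ScaffoldLayout("chr1", [io.LayoutPart("c", "+")])]
    markers = [
        io.Marker(f"m{i}", "1", cm, seq=seq[40 * (i + 1):40 * (i + 1) + 31])
        for i, cm in enumerate(cms)
    ]
    (res,) = anchor.colinearity_check(
        chrom, io.GeneticMap(markers), contigs, lm.ModelParams()
    )
    return res


def test_perfectly_colinear_markers_give_rho_one():
    res = colinearity_of([float(i) for i in range(10)])
    assert res.rho == pytest.approx(1.0)
    assert res.discordant == []


def test_adjacent_swap_gives_rho_point_nine():
    """Ranks 1,3,2,4,5 against 1..5: sum d^2 = 2, rho = 1 - 12/120 = 0.9,
    verified against the closed-form rank formula."""
    cms = [1.0, 3.0, 2.0, 4.0, 5.0]
    res = colinearity_of(cms)
    d2 = sum((a - b) ** 2 for a, b in zip([1, 3, 2, 4, 5], [1, 2, 3, 4, 5]))
    expected = 1 - 6 * d2 / (5 * (5 ** 2 - 1))
    assert res.rho == pytest.approx(expected) == pytest.approx(0.9)


def test_too_few_markers_leave_rho_undefined():
    res = colinearity_of([0.0, 1.0])
    assert res.rho is None and res.n_markers == 2


def test_discordant_marker_listed():
    res = colinearity_of([0.0, 1.0, 2.0, 50.0, 3.0, 4.0, 5.0])
    assert "m3" in res.discordant
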