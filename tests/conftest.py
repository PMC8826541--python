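"""Shared fixtures: small simulated scenarios and a full standard-conditions run."""

import time

import pytest

from baylink import anchor, evaluate, linkmodel, scaffold, simulate


@pytest.fixture()
def params():
    return linkmodel.ModelParams()


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced dataset (2 x 120 kb, 8 contigs each) for fast module tests."""
    return simulate.clean_scenario(
        seed=3,
        chromosome_length=120_000,
        n_contigs_per_chromosome=8,
        n_markers_per_chromosome=6,
        n_holdout_per_chromosome=0,
        mismap_rate=0.0,
    )


def run_full_pipeline(scenario, params=None):
    """Drive all stages on a scenario; returns every intermediate product."""
    params = params or linkmodel.ModelParams()
    bundles = linkmodel.score_links(
        scenario.alignments, scenario.contigs, scenario.libraries, params
    )
    masked = scaffold.detect_repeats(
        scenario.contigs, scenario.alignments, bundles, params
    )
    layouts, rejections = scaffold.build_scaffolds(
        bundles, scenario.contigs, params, masked
    )
    revised, breaks, unresolvable = anchor.detect_and_break_chimeras(
        layouts, scenario.gmap, scenario.contigs, params
    )
    placements = anchor.place_markers(scenario.gmap, revised, scenario.contigs)
    pseudos, unanchored = anchor.order_and_orient(
        revised, placements, scenario.gmap, scenario.contigs, params,
        exclude=unresolvable,
    )
    by_id = {lo.id: lo for lo in revised}
    chrom_layouts = [
        anchor.pseudomolecule_layout(pm, by_id) for pm in pseudos if pm.entries
    ]
    colinearity = anchor.colinearity_check(
        chrom_layouts, scenario.gmap, scenario.contigs, params
    )
    accuracy = evaluate.join_accuracy(
        layouts, scenario.truth.true_adjacencies()
    )
    return {
        "bundles": bundles,
        "masked": masked,
        "layouts": layouts,
        "rejections": rejections,
        "revised": revised,
        "breaks": breaks,
        "unresolvable": unresolvable,
        "placements": placements,
        "pseudomolecules": pseudos,
        "unanchored": unanchored,
        "chromosome_layouts": chrom_layouts,
        "colinearity": colinearity,
        "accuracy": accuracy,
    }


@pytest.fixture(scope="session")
def clean_run():
    """Full pipeline on the standard study conditions (seed 1): 2 x 500 kb
    chromosomes, 40 contigs, mate pairs 3000±300 at 20x, BAC-like 30k±3k at
    0.5x, 30 anchoring markers, 2% mismapping."""
    t0 = time.monotonic()
    scenario = simulate.clean_scenario(seed=1)
    result = run_full_pipeline(scenario)
    result["scenario"] = scenario
    result["elapsed_s"] = time.monotonic() - t0
    return result
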