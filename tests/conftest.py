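"""Shared fixtures: simulated bundles and a pipeline driver."""

from __future__ import annotations

import pytest

from mapfuse import fixtures, scaffolder


def run_pipeline(bundle, params: scaffolder.ScaffoldParams | None = None):
    """Run junction resolution and render everything, like the CLI does."""
    plans, singles, decisions = scaffolder.build_scaffolds(
        bundle.contigs, bundle.key, bundle.contig_maps, bundle.anchor_maps,
        bundle.alignments, params or scaffolder.ScaffoldParams(),
    )
    all_plans = plans + scaffolder.singleton_plans(singles, bundle.key, bundle.contigs)
    records = {p.name: scaffolder.render_plan_sequence(p, bundle.contigs)
               for p in all_plans}
    return plans, singles, decisions, all_plans, records


@pytest.fixture(scope="session")
def clean_bundle():
    """Desk-scale fixture, zero label noise, all junction classes present."""
    return fixtures.simulate(fixtures.FixtureSpec(seed=3, label_noise_sd=0.0))


@pytest.fixture(scope="session")
def clean_result(clean_bundle):
    return run_pipeline(clean_bundle)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Same design with realistic anchor sizing noise."""
    return fixtures.simulate(fixtures.FixtureSpec(seed=11, label_noise_sd=0.003))


@pytest.fixture(scope="session")
def noisy_result(noisy_bundle):
    return run_pipeline(noisy_bundle)
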