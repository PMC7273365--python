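import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cliffminer import pipeline as pl
from cliffminer import ps_library, synthetic_fixtures as sf


@pytest.fixture(scope="session")
def ps_patterns():
    return ps_library.load_ps_definitions(ps_library.starter_library_path())


@pytest.fixture(scope="session")
def fixture_runner(ps_patterns, tmp_path_factory):
    """Generate a seeded fixture, run the full pipeline on it, return both."""

    def _run(seed, corrupt=False, **spec_kwargs):
        spec = sf.FixtureSpec(seed=seed, **spec_kwargs)
        table, truth = sf.generate_fixture(spec, ps_patterns)
        if corrupt:
            table = sf.corrupt_fixture(table, seed=seed)
        path = tmp_path_factory.mktemp("fix") / "activities.tsv"
        table.to_csv(path, sep="\t", index=False)
        result = pl.run_pipeline(
            pl.RunConfig(activities_path=path), ps_patterns=ps_patterns
        )
        return result, truth

    return _run


def pair_keys(result):
    return {
        (p.target_id, *sorted((p.a.compound_id, p.b.compound_id)), p.pair_type)
        for p in result.pairs
    }


def cliff_keys(result):
    return {
        (
            e.cliff.pair.target_id,
            *sorted((e.cliff.pair.a.compound_id, e.cliff.pair.b.compound_id)),
            tuple(sorted(e.cliff.categories)),
            e.extension_status,
        )
        for e in result.cliffs
    }
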