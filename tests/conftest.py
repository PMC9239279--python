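import pytest

from snodkit.pipeline import run_pipeline, stage_seed
from snodkit.simulate import CommunityConfig, generate_community


def small_config(seed: int, **overrides) -> CommunityConfig:
    """A reduced community (3 groups, 12 families) for fast stage tests."""
    kwargs = dict(
        n_groups=3,
        genomes_per_group=(3, 5, 2),
        n_core_families=12,
        n_specific_per_group=1,
        n_hgt_events=1,
        n_clones=1,
        seed=seed,
    )
    kwargs.update(overrides)
    return CommunityConfig(**kwargs)


@pytest.fixture(scope="session")
def community():
    """Shared small community with every planted feature."""
    return generate_community(small_config(seed=11))


@pytest.fixture(scope="session")
def pipeline_result():
    """Shared end-to-end pipeline run on the small community."""
    return run_pipeline(config=small_config(seed=stage_seed(7, "community")),
                        seed=7, n_boot=25, n_jack=25)
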