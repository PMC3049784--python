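import pytest

from engraftlogic.pipeline import RunConfig, run_pipeline
from engraftlogic.simulate import PlantedDesign, RegionSpec, UP_G0, UP_G1


@pytest.fixture(scope="session")
def replica_report(tmp_path_factory):
    """One full pipeline run on the shipped replica design, shared by tests."""
    out = tmp_path_factory.mktemp("replica")
    return run_pipeline(RunConfig(seed=0, out_dir=str(out)))


@pytest.fixture
def tiny_design():
    """10 features: 2 engraftment-G0, 1 engraftment-G1, 1 cell-cycle, 6 null."""
    return PlantedDesign(
        n_features=10,
        regions=(
            RegionSpec((("BM", UP_G0), ("MPB", UP_G0)), 2),
            RegionSpec((("BM", UP_G1), ("MPB", UP_G1)), 1),
            RegionSpec((("BM", UP_G0), ("MPB", UP_G0), ("UCB", UP_G0)), 1),
        ),
        effect_size=2.0,
        noise_sd=0.0,
        replicates_per_group=3,
    )


def flipped(design: PlantedDesign) -> PlantedDesign:
    """The same design with every planted direction negated."""
    regions = tuple(
        RegionSpec(
            directions=tuple((t, -d) for t, d in r.directions),
            count=r.count,
            priority=r.priority,
        )
        for r in design.regions
    )
    return PlantedDesign(
        n_features=design.n_features,
        regions=regions,
        effect_size=design.effect_size,
        noise_sd=design.noise_sd,
        replicates_per_group=design.replicates_per_group,
        baseline_log2_mean=design.baseline_log2_mean,
        baseline_log2_sd=design.baseline_log2_sd,
        feature_prefix=design.feature_prefix,
    )
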