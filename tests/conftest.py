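import warnings

import pytest

from metatriage.abundance import median_ratio_size_factors, tpm_table
from metatriage.annotate import TierConfig, cascade_annotate
from metatriage.simulate import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def scenario():
    """Default multi-kingdom scenario, fixed seed, shared read-only."""
    return generate_scenario(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def scenario_calls(scenario):
    """Cascade annotation of the default scenario using ground-truth DE
    flags (the fallback tiers only apply to DE contigs)."""
    de_flags = {
        cid: t.de_state != "EE" for cid, t in scenario.truth.contigs.items()
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cascade_annotate(
            scenario.contigs.ids(),
            scenario.hits_by_tier,
            scenario.self_scores,
            TierConfig(),
            de_flags,
        )


@pytest.fixture(scope="session")
def scenario_abundance(scenario):
    factors = median_ratio_size_factors(scenario.counts)
    table = tpm_table(scenario.counts, scenario.lengths)
    return factors, table
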