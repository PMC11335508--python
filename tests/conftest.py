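import pytest

from piload.pipeline import run_pipeline
from piload.synthetic import GeneratorConfig, generate_registry

STAGES = ("trial_type", "study_type", "pg_thesis", "country", "pi_missing")


def noise_free_config(n_pis: int = 50, seed: int = 7, **overrides) -> GeneratorConfig:
    """A generator config with every corruption process switched off: unique
    clean names, one stable email per PI, no decoys, no sabotage."""
    base = dict(
        n_pis=n_pis,
        seed=seed,
        variant_process_rates={
            p: 0.0
            for p in (
                "honorific_add",
                "initialize_given_names",
                "typo_edit1",
                "token_swap",
                "case_change",
            )
        },
        evidence_coverage={"email": 1.0, "phone": 0.0, "fax": 0.0, "affiliation": 0.0, "postal": 0.0},
        email_stability=1.0,
        multi_name_rate=0.0,
        ineligible_record_rate={k: 0.0 for k in STAGES},
        sabotage_rates={"missing_start": 0.0, "zero_duration": 0.0},
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def default_registry():
    """200 investigators under the generator's default (noisy) conditions."""
    return generate_registry(GeneratorConfig(n_pis=200, seed=123))


@pytest.fixture(scope="session")
def default_pipeline(default_registry):
    records, _ = default_registry
    return run_pipeline(records)
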