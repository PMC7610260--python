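import numpy as np
import pytest

import fingerdx as fx


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast 30/30 cohort with 40 bins, 4 planted at 3-fold."""
    planted = (fx.PlantedBin(3, "up", 3.0), fx.PlantedBin(11, "down", 3.0),
               fx.PlantedBin(25, "up", 3.0), fx.PlantedBin(38, "down", 3.0))
    cfg = fx.CohortConfig(n_controls=30, n_cases=30, n_bins=40,
                          planted_bins=planted, seed=42)
    return fx.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_trained_sn(small_cohort):
    """A small SN trained on log intensities (shared across read-only tests)."""
    import dataclasses

    X = np.log(small_cohort.fingerprints.values)
    arch = dataclasses.replace(fx.arch_for_width(40), fc_layers=(16, 8),
                               dropout_rate=0.2)
    model = fx.build_model(arch)
    model.fit(X, small_cohort.labels,
              cfg=fx.TrainConfig(seed=7, max_epochs=60, early_stop_patience=60,
                                 weight_decay=0.3))
    return model, X, small_cohort.labels


def study_cohort_config(effect_size: float = 2.0, seed: int = 0,
                        clinical_spec=None) -> fx.CohortConfig:
    """The full-scale study conditions: 172/172, 881 bins, 20 planted bins."""
    kwargs = {}
    if clinical_spec is not None:
        kwargs["clinical_spec"] = clinical_spec
    return fx.CohortConfig(
        n_controls=172, n_cases=172, n_bins=881,
        planted_bins=fx.default_planted_bins(effect_size=effect_size, seed=seed),
        tic_log_sd=0.25, missing_rate=0.05, seed=1000 + seed, **kwargs)
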