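"""Shared fixtures.

The expensive multi-experiment fits are session-scoped so the fitting,
discrimination and acceptance tests reuse one set of results.
"""

from __future__ import annotations

import pytest

from kinwfi.fitting import FitSpec, fit, compare_models
from kinwfi.synthetic_data import NoiseSpec, make_study


@pytest.fixture(scope="session")
def clean_study():
    """Noise-free reference study: observed yields equal the truth curves."""
    return make_study(noise=NoiseSpec(distribution="none"))


@pytest.fixture(scope="session")
def noisy_study():
    """Reference study with band-level truncated-normal noise, seed 0."""
    return make_study(noise=NoiseSpec(seed=0))


@pytest.fixture(scope="session")
def clean_borderline_fit(clean_study):
    """Borderline model fitted to the noise-free training experiments."""
    return fit(FitSpec("borderline", clean_study.training, n_starts=4))


@pytest.fixture(scope="session")
def noisy_comparison(noisy_study):
    """All three candidate models fitted to the noisy training set.

    Returns ``(comparison_table, {model_name: FitResult}, study)``.
    """
    specs = [
        FitSpec(
            name,
            noisy_study.training,
            n_starts=4 if name == "borderline" else 2,
        )
        for name in ("borderline", "sn1", "sn2")
    ]
    table, results = compare_models(specs, held_out=noisy_study.extrapolation)
    return table, results, noisy_study
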