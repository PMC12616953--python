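import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_ratios():
    from fretquant.reference import reference_ratios

    return reference_ratios()


@pytest.fixture(scope="session")
def ref_ratios_with_rp(ref_ratios):
    from fretquant.reference import reference_rp

    return dataclasses.replace(ref_ratios, r_p=reference_rp())


@pytest.fixture(scope="session")
def clean_dual_population(ref_ratios, ref_ratios_with_rp):
    """Small noise-free, dropout-free dual-sensor population with ground truth."""
    from fretquant.simulate import (
        PopulationSpec,
        ekaren4_like_sensor,
        generate_population,
        rekar_like_sensor,
    )

    clean = dict(
        noise_sd=0.0,
        dropout_prob_per_frame=0.0,
        expression_lognormal_sigma=0.0,
        peak_lognormal_sigma=0.0,
    )
    spec = PopulationSpec(
        sensors={
            # identical kinetics for both sensors so amplitude ratios are exact
            "REKAR67": rekar_like_sensor(undershoot_depth=0.0, **clean),
            "EKAREN4": ekaren4_like_sensor(**clean),
        },
        n_cells=4,
        n_technical_replicates=1,
        n_experimental_replicates=1,
        seed=11,
        dual_sensor=True,
    )
    ratios = {"REKAR67": ref_ratios, "EKAREN4": ref_ratios_with_rp}
    tracks, truth = generate_population(spec, ratios)
    return spec, ratios, tracks, truth


def random_valid_ratios(rng: np.random.Generator):
    """A random ratio set satisfying the invertibility conditions."""
    from fretquant.optics import SpectralRatios

    return SpectralRatios(
        r_xt=float(rng.uniform(0.0, 2.0)),
        r_chan=float(rng.uniform(0.01, 1.0)),
        r_fret=float(rng.uniform(0.01, 1.0)),
    )
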