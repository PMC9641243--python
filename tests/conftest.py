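import numpy as np
import pytest

from fluxkin.gating import GatingScheme
from fluxkin.kinetics import DoubleLogisticFit
from fluxkin.synthetic_data import (
    KineticGroundTruth,
    default_subset_specs,
    generate_event_stream,
)


@pytest.fixture(scope="session")
def reference_truth() -> KineticGroundTruth:
    """A typical activation curve: rise to ~2.2x baseline, settle at ~1.6x."""
    return KineticGroundTruth(
        S=100.0, A1=120.0, r1=0.06, tau1=180.0, A2=60.0, r2=0.015, tau2=420.0
    )


@pytest.fixture(scope="session")
def reference_fit(reference_truth) -> DoubleLogisticFit:
    g = reference_truth
    return DoubleLogisticFit(
        S=g.S, A1=g.A1, r1=g.r1, tau1=g.tau1, A2=g.A2, r2=g.r2, tau2=g.tau2,
        rss=0.0, converged=True, n_bins=204,
    )


@pytest.fixture(scope="session")
def default_scheme() -> GatingScheme:
    return GatingScheme(
        thresholds={"CD19": 100.0, "IgD": 100.0, "CD27": 100.0, "CD25": 100.0},
        loading_threshold=10.0,
    )


@pytest.fixture(scope="session")
def medium_stream():
    """One 100k-event synthetic acquisition with the default panel."""
    return generate_event_stream(default_subset_specs(), 100_000, seed=20240301)
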