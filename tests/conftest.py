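import pytest

from egdloc import (
    EmissionSpec,
    SamplingPlan,
    build_frame_truth,
    emit_predictions,
    simulate_trajectory,
    table1_fixture,
)
from egdloc.synthetic import default_confusion, default_trajectory_spec


@pytest.fixture(scope="session")
def table1_manifest():
    """Synthetic manifest matching the reference corpus class counts."""
    return table1_fixture()


@pytest.fixture(scope="session")
def default_procedure():
    """One simulated procedure at the stated-world defaults, seed 1."""
    spec = default_trajectory_spec(seed=1)
    intervals, frames = simulate_trajectory(spec)
    return spec, intervals, frames


@pytest.fixture(scope="session")
def default_stream(default_procedure):
    """Raw confusion-corrupted prediction stream over the default procedure."""
    spec, intervals, frames = default_procedure
    emission = EmissionSpec(default_confusion(0.8), seed=2)
    preds = emit_predictions(frames, SamplingPlan(fps=spec.fps), emission)
    truth = build_frame_truth(intervals, spec.fps, len(frames))
    return preds, truth
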