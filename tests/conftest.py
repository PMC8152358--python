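import numpy as np
import pandas as pd
import pytest

from cpforage import hmm, synthetic


@pytest.fixture(scope="session")
def world():
    return synthetic.World.default()


@pytest.fixture(scope="session")
def truth():
    return synthetic.TruthParams()


@pytest.fixture(scope="session")
def hmm_truth(truth):
    """HMMParams equal to the simulator's movement truth."""
    return hmm.HMMParams(
        step_mean=truth.step_gamma[:, 0].copy(),
        step_sd=truth.step_gamma[:, 1].copy(),
        turn_mu=truth.turn_vonmises[:, 0].copy(),
        turn_kappa=truth.turn_vonmises[:, 1].copy(),
        transition=truth.transition_matrix.copy(),
        initial=truth.stationary_distribution(),
    )


@pytest.fixture(scope="session")
def small_tracks(world, truth):
    spec = synthetic.TripSpec(
        start=pd.Timestamp("2017-06-01 06:00:00", tz="UTC"), duration_h=2.0
    )
    birds = synthetic.default_birds(4, spec)
    return synthetic.generate_tracks(world, truth, birds, seed=7)


def make_trip(x, y, t0="2017-06-01 00:00:00", dt_s=30.0, trip_id="t1", bird_id="b1"):
    """Build a Trip directly from projected coordinates (test helper)."""
    from cpforage.preprocess import Trip

    x = np.asarray(x, dtype=float)
    ts = pd.Timestamp(t0, tz="UTC") + pd.to_timedelta(np.arange(x.size) * dt_s, unit="s")
    fixes = pd.DataFrame({"timestamp": ts, "x": x, "y": np.asarray(y, dtype=float)})
    fixes["bird_id"] = bird_id
    return Trip(
        trip_id=trip_id,
        bird_id=bird_id,
        fixes=fixes,
        departure_time=ts[0],
        arrival_time=ts[-1],
        complete=True,
    )
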