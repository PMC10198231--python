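import numpy as np
import pandas as pd
import pytest

from tremormpp.signal_model import (
    BackgroundModel,
    EpochSchedule,
    EpochSpec,
    MotionTrace,
    TremorModel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def background():
    return BackgroundModel()


@pytest.fixture
def deterministic_background():
    """No per-animal jitter: clean calibration checks."""
    return BackgroundModel(fraction_sd=0.0)


@pytest.fixture
def deterministic_tremor():
    return TremorModel(animal_sd=0.0, epoch_sd=0.0)


@pytest.fixture
def short_schedule():
    """Fast 3-epoch schedule (B, H1, E1) at 120 s for pipeline tests."""
    return EpochSchedule(
        (
            EpochSpec("B", 120.0),
            EpochSpec("H1", 120.0, 300.0),
            EpochSpec("E1", 120.0, 600.0),
        )
    )


def make_trace(samples, fs=128.0, **meta):
    defaults = dict(animal_id="a0", genotype="WT", drug="none", dose=0.0, epoch="B")
    defaults.update(meta)
    return MotionTrace(fs, np.asarray(samples, dtype=float), **defaults)


@pytest.fixture
def sine_trace():
    t = np.arange(900 * 128) / 128.0
    return make_trace(np.sin(2 * np.pi * 12.0 * t))


def synthetic_mpp_table(rng, doses=(0.0, 1.0), n_per_dose=6, epochs=("B", "H1", "E1"),
                        animal_sd=2.0, resid_sd=1.0, effects=None):
    """Tidy MPP-style table from an explicit random-intercept model (test oracle)."""
    effects = effects or {}
    rows = []
    for di, dose in enumerate(doses):
        for a in range(n_per_dose):
            aid = f"d{di}a{a:02d}"
            u = rng.normal(0.0, animal_sd)
            for ep in epochs:
                mu = 50.0 + effects.get((dose, ep), 0.0)
                rows.append(
                    dict(
                        animal_id=aid,
                        genotype="WT",
                        drug="probe",
                        dose=dose,
                        epoch=ep,
                        mpp=mu + u + rng.normal(0.0, resid_sd),
                    )
                )
    return pd.DataFrame(rows)
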