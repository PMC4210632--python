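import numpy as np
import pandas as pd
import pytest

from salmoarray.qc import ExpressionMatrix, floor_intensities
from salmoarray.simulate import (
    ExperimentDesign,
    NoiseModel,
    RawIntensityData,
    TranscriptArchitecture,
    build_design,
    make_architectures,
    simulate_intensities,
)

ZERO_NOISE = dict(biological_sd=0.0, technical_sd=0.0, flag_failure_rate=0.0)


def raw_from_matrices(sample, reference, design, flags=None):
    """Assemble a RawIntensityData from plain arrays for hand-built cases."""
    cols = design.array_ids
    idx = [f"p{i}" for i in range(np.asarray(sample).shape[0])]
    sample = pd.DataFrame(np.asarray(sample, dtype=float), index=idx, columns=cols)
    reference = pd.DataFrame(np.asarray(reference, dtype=float), index=idx, columns=cols)
    if flags is None:
        flags = pd.DataFrame(True, index=idx, columns=cols)
    else:
        flags = pd.DataFrame(np.asarray(flags, dtype=bool), index=idx, columns=cols)
    return RawIntensityData(sample=sample, reference=reference, flags=flags, design=design, truth=())


def log_ratio_expr(raw: RawIntensityData) -> ExpressionMatrix:
    """Floored log2(sample/reference) without the lowess step (no dye bias)."""
    from salmoarray.qc import log_ratios

    return log_ratios(raw)


@pytest.fixture(scope="session")
def design6() -> ExperimentDesign:
    return build_design(6)


@pytest.fixture(scope="session")
def design2() -> ExperimentDesign:
    return build_design(2)


@pytest.fixture(scope="session")
def noiseless_raw(design6) -> RawIntensityData:
    """Deterministic data with one gene per mode plus a null, no noise."""
    archs = [
        TranscriptArchitecture("gAdd", ("gAdd_p1",), 8.0, 1.0, "additive"),
        TranscriptArchitecture("gMat", ("gMat_p1",), 8.0, 1.0, "maternal_dominant"),
        TranscriptArchitecture("gPat", ("gPat_p1",), 8.0, 1.0, "paternal_dominant"),
        TranscriptArchitecture("gOver", ("gOver_p1",), 8.0, 1.0, "overdominant", overdominance_shift=1.0),
        TranscriptArchitecture("gNull", ("gNull_p1", "gNull_p2"), 9.0, 0.0, "additive"),
    ]
    return simulate_intensities(design6, archs, NoiseModel(**ZERO_NOISE, seed=0))


@pytest.fixture(scope="session")
def noisy_expr(design6) -> ExpressionMatrix:
    """A mid-size noisy panel used by several statistical tests."""
    truth = make_architectures(400, effect_size=1.0, null_fraction=0.5, seed=21)
    raw = simulate_intensities(design6, truth, NoiseModel(seed=22))
    return log_ratio_expr(raw)
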