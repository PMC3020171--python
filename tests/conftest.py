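import numpy as np
import pytest

from nirsmap import (FINGER_TAPPING_PROTOCOL, DesignMatrix, OpticalConstants,
                     ProtocolSpec, build_design)


@pytest.fixture(scope="session")
def paper_protocol() -> ProtocolSpec:
    """42 s preparation + 10 x (21 s task + 30 s rest) at 1.81 Hz."""
    return FINGER_TAPPING_PROTOCOL


@pytest.fixture(scope="session")
def paper_design(paper_protocol) -> DesignMatrix:
    return build_design(paper_protocol)


@pytest.fixture(scope="session")
def short_protocol() -> ProtocolSpec:
    """100 s / 200-sample block design for fast estimator tests."""
    return ProtocolSpec(preparation_s=10, n_sessions=3, task_s=10, rest_s=20,
                        sampling_rate_hz=2.0)


@pytest.fixture(scope="session")
def optical_constants() -> OpticalConstants:
    return OpticalConstants(distance_mm=20.0)


@pytest.fixture()
def random_design() -> DesignMatrix:
    """Well-conditioned 200 x 5 synthetic regression design.

    Four standard-normal columns plus a constant; every leading submatrix
    from row 5 on is well conditioned, so the recursive-OLS limit is testable
    from the first degree of freedom.
    """
    rng = np.random.default_rng(12345)
    H = np.column_stack([rng.normal(size=(200, 4)), np.ones(200)])
    return DesignMatrix(H, ["task", "x2", "x3", "x4", "baseline"], 2.0)
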