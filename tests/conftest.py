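import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stagescan import ExpressionMatrix, SampleAnnotation

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """6 genes x 6 samples, two groups of 3, genes g1-g3 shifted up in A."""
    rng = np.random.default_rng(42)
    data = rng.normal(6.0, 1.0, size=(6, 6))
    data[:3, :3] += 3.0
    genes = [f"g{i}" for i in range(1, 7)]
    samples = [f"s{i}" for i in range(1, 7)]
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples))


@pytest.fixture
def toy_annotations() -> list[SampleAnnotation]:
    return [
        SampleAnnotation(f"s{i}", "A" if i <= 3 else "B") for i in range(1, 7)
    ]
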