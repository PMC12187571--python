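import numpy as np
import pandas as pd
import pytest

from markernom import ExpressionMatrix, TruthParams, generate_multiomics


@pytest.fixture(scope="session")
def bundle42():
    """Default synthetic bundle, seed 42 — shared across test modules."""
    return generate_multiomics(seed=42)


@pytest.fixture(scope="session")
def wide_bundle():
    """Bundle with 32 target-entity samples for correlation-signature tests."""
    return generate_multiomics(TruthParams(samples_per_entity=32, seed=7))


@pytest.fixture()
def tiny_expr():
    """3 genes x 6 samples, two entities, deterministic values."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(6, 1, (3, 6)),
        index=["gA", "gB", "gC"],
        columns=[f"s{i}" for i in range(6)],
    )
    labels = pd.Series(["T"] * 3 + ["M"] * 3, index=values.columns)
    return ExpressionMatrix(values=values, entity_labels=labels)
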