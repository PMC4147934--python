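import numpy as np
import pandas as pd
import pytest

import prosig as ps

# One default synthetic cohort, scored and assigned once per session: several
# end-to-end checks (correction effect, recovery, clustering) share it.
DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_params():
    return ps.CohortSimulationParams(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_run(default_params):
    """Full pipeline artifacts for the default cohort."""
    X, metadata, truth = ps.simulate_cohort(default_params)
    refs = ps.make_reference_from_truth(default_params)
    signatures = ps.score_cohort(X, truth.gene_sets)
    md = {m.sample_id: m for m in metadata}
    corrected = ps.correct_cohort(signatures, md)
    return {
        "params": default_params,
        "X": X,
        "metadata": metadata,
        "md": md,
        "truth": truth,
        "refs": refs,
        "signatures": signatures,
        "corrected": corrected,
    }


@pytest.fixture
def tiny_refs():
    """Four nearly orthogonal reference rows over 15 gene sets."""
    rng = np.random.default_rng(3)
    sets = [f"set{i:02d}" for i in range(1, 16)]
    base = 0.1 * rng.standard_normal((4, 15))
    for i in range(4):
        base[i, 3 * i : 3 * i + 3] += 1.0
    base = np.clip(base, -1, 1)
    df = pd.DataFrame(base, index=["BP-E/P/Pr", "BP-ERG", "GP1", "GP2"], columns=sets)
    return ps.ReferenceSubtypes(
        df,
        prognosis={"BP-E/P/Pr": "bad", "BP-ERG": "bad", "GP1": "good", "GP2": "good"},
    )
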