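"""Shared fixtures.

``benchmark_sweep`` runs the full synthetic ablation study once per session
(three replicate seeds; stage 1 shared across arms) and is reused by the
end-to-end, ablation and loss-trajectory tests; it is the expensive fixture
of the suite (a few minutes of CPU).
"""

import pytest

from atacgda.pipeline import ablation_study


@pytest.fixture(scope="session")
def benchmark_sweep():
    return ablation_study(base_seed=0, n_seeds=3, lams=(0.0, 1.0, 10.0))
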