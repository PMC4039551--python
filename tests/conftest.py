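import pytest

from clustermerge import TrialDesign


@pytest.fixture
def base_design() -> TrialDesign:
    """The reference trial: 80 clusters of 20, ICC 0.05, total variance 1,
    powered at 80% for an effect of 0.2 at two-sided alpha 0.05."""
    return TrialDesign(delta=0.2, sigma_b2=0.05, sigma_w2=0.95, alpha=0.05, target_power=0.8, lam=1.0, m=20, c=80, w=0.0)
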