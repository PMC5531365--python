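import numpy as np
import pytest

from shortscreen.synth import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def recovery_spec() -> CohortSpec:
    """A well-targeted 8-item instrument for parameter-recovery checks:
    step thresholds within ~±2 logits of the trait mean, all categories
    observable at moderate n."""
    locs = [-0.8, -0.5, -0.2, 0.0, 0.2, 0.4, 0.6]
    delta = [np.array([-1.0, -0.35, 0.35, 1.0]) + l for l in locs]
    delta.append(np.array([-0.6, 0.6]) + 0.8)
    return CohortSpec(
        n=500, delta=delta, symptom_intercepts=np.zeros(10), seed=1
    )


@pytest.fixture(scope="session")
def recovery_cohort(recovery_spec):
    return generate_cohort(recovery_spec)


@pytest.fixture(scope="session")
def sample2_cohort():
    """A sample-2-like synthetic cohort (n=369, 11 symptoms)."""
    from shortscreen.synth import default_specs

    _, s2 = default_specs(seed=7)
    return generate_cohort(s2)


def centered_true_delta(spec: CohortSpec) -> np.ndarray:
    """True step thresholds on the JMLE identification scale (mean item
    location zero)."""
    flat = np.concatenate(spec.delta)
    return flat - np.mean([np.mean(d) for d in spec.delta])
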