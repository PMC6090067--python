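import pytest

import swa_brainage as sb


@pytest.fixture(scope="session")
def separated_profiles():
    """Strongly separated six-class cohort at the published group sizes."""
    return sb.simulate_profiles(sb.well_separated_spec(seed=1))


@pytest.fixture(scope="session")
def null_cohort():
    """Factory for cohorts where all six groups share one distribution."""

    def make(seed: int, n_per_class: int = 9):
        base = sb.default_cohort_spec(1.0, seed=seed)
        lab0 = sb.ClassLabel(6, False)
        mu, cov = base.means[lab0], base.covariances[lab0]
        spec = sb.CohortSpec(
            counts={lab: n_per_class for lab in sb.CANONICAL_LABELS},
            means={lab: mu.copy() for lab in sb.CANONICAL_LABELS},
            covariances={lab: cov.copy() for lab in sb.CANONICAL_LABELS},
            seed=seed,
        )
        return sb.simulate_profiles(spec)

    return make


@pytest.fixture()
def tiny_epoch_spec():
    """Three-mouse cohort spec for epoch-level simulation."""
    return sb.default_cohort_spec(
        1.0,
        seed=3,
        counts={sb.ClassLabel(6, False): 2, sb.ClassLabel(24, True): 1},
    )
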