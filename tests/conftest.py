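import numpy as np
import pytest

from escalape import blrm, pkpd, synth


@pytest.fixture(scope="session")
def study_fixtures():
    return synth.make_study_fixtures()


@pytest.fixture(scope="session")
def q3w(study_fixtures):
    return study_fixtures[0]


@pytest.fixture(scope="session")
def qw(study_fixtures):
    return study_fixtures[1]


@pytest.fixture(scope="session")
def q3w_prior(q3w):
    return blrm.reference_prior(q3w.ref_dose_mg)


@pytest.fixture(scope="session")
def qw_prior(qw):
    return blrm.reference_prior(qw.ref_dose_mg)


@pytest.fixture(scope="session")
def q3w_rules(q3w):
    return blrm.EscalationRules(cap_threshold_mg=q3w.cap_threshold_mg)


@pytest.fixture(scope="session")
def qw_rules(qw):
    return blrm.EscalationRules(cap_threshold_mg=qw.cap_threshold_mg)


@pytest.fixture(scope="session")
def q3w_posterior(q3w_prior, q3w):
    return blrm.fit_posterior(q3w_prior, list(q3w.cohorts))


@pytest.fixture(scope="session")
def qw_posterior(qw_prior, qw):
    return blrm.fit_posterior(qw_prior, list(qw.cohorts))


@pytest.fixture(scope="session")
def study_like_pkpd():
    return pkpd.study_like_parameters()


def point_mass_grid(log_alpha: float, log_beta: float, ref_dose_mg: float = 720.0):
    """Posterior concentrated (numerically) on a single parameter point."""
    la = np.array([log_alpha, log_alpha + 1e-9])
    lb = np.array([log_beta, log_beta + 1e-9])
    w = np.zeros((2, 2))
    w[0, 0] = 1.0
    return blrm.PosteriorGrid(la, lb, w, ref_dose_mg=ref_dose_mg)


@pytest.fixture
def make_point_mass():
    return point_mass_grid
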