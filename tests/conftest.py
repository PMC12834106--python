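import pytest

from rulemem.cal import CALParams, simulate
from rulemem.task import build_structure, generate_main_sequence

# deterministic test agents centred on the study's fitted group means
RULE_PARAMS = CALParams(gamma=-1.2, omega=-3.0, rho_i=0.87, rho_a=0.08,
                        lam=-4.5, lam_r=0.0, lam_nr=0.0)
MEMORY_PARAMS = CALParams(gamma=3.5, omega=-4.5, rho_i=0.1, rho_a=0.01,
                          lam=-0.9, lam_r=1.45, lam_nr=0.66)
NONLEARNER_PARAMS = CALParams(gamma=3.8, omega=-4.9, rho_i=0.02, rho_a=0.005,
                              lam=-4.8, lam_r=0.0, lam_nr=0.0)


@pytest.fixture(scope="session")
def rb_structure():
    return build_structure("RB", irrelevant_dim=2, polarity=0)


@pytest.fixture(scope="session")
def u_structure():
    return build_structure("U", polarity=0)


@pytest.fixture(scope="session")
def rb_sequence(rb_structure):
    return generate_main_sequence(rb_structure, seed=7)


@pytest.fixture(scope="session")
def u_sequence(u_structure):
    return generate_main_sequence(u_structure, seed=8)


def _first_solving_trace(params, structure, n_tries=12):
    for k in range(n_tries):
        seq = generate_main_sequence(structure, seed=50 + k)
        tr = simulate(params, seq, seed=900 + k)
        if tr["solved"].iloc[-1] == 1:
            return tr, seq
    raise RuntimeError("no solving agent found in the attempted seeds")


@pytest.fixture(scope="session")
def solved_rb_trace(rb_structure):
    """(trace, sequence) of a rule-profile agent that solved the RB task."""
    return _first_solving_trace(RULE_PARAMS, rb_structure)


@pytest.fixture(scope="session")
def solved_u_trace(u_structure):
    """(trace, sequence) of a memory-profile agent that solved the U task."""
    return _first_solving_trace(MEMORY_PARAMS, u_structure)
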