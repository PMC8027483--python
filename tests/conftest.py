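import pytest

from mtpb.physical_model import (
    BufferSpec,
    MicrotubuleSpec,
    PermittivityModel,
)
from mtpb.pb_solver import SolverOptions


@pytest.fixture(scope="session")
def mt():
    """The standard 13-protofilament microtubule geometry."""
    return MicrotubuleSpec.default()


@pytest.fixture(scope="session")
def smt():
    """Subtilisin-digested microtubule: same walls, no C-termini."""
    return MicrotubuleSpec.default(include_ct=False)


@pytest.fixture(scope="session")
def perm_full():
    return PermittivityModel(mode="full")


@pytest.fixture(scope="session")
def perm_const():
    return PermittivityModel(mode="constant")


@pytest.fixture(scope="session")
def fast_opts():
    """Reduced grid for tests whose tolerances do not need n=2000."""
    return SolverOptions(n_grid=800)


@pytest.fixture(scope="session")
def buffer_160():
    return BufferSpec.kcl(160.0)


@pytest.fixture(scope="session")
def buffer_10uM():
    return BufferSpec.kcl(0.01)


@pytest.fixture(scope="session")
def solved_160(mt, perm_full):
    """All three sub-problems solved at the BRB80 ionic strength."""
    from mtpb.pipeline import solve_structure

    return solve_structure(BufferSpec.kcl(160.0), perm_full)


@pytest.fixture(scope="session")
def solved_10uM(mt, perm_full):
    from mtpb.pipeline import solve_structure

    return solve_structure(BufferSpec.kcl(0.01), perm_full)
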