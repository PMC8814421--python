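import numpy as np
import pytest

from cisquant import Background, MotifLibrary, PWM, pwm_log_odds
from cisquant.synthetic_motifs import demo_library


@pytest.fixture(scope="session")
def toy_pwm() -> PWM:
    """Width-2 matrix: col 1 prefers A (0.7), col 2 prefers G (0.7)."""
    return PWM(
        motif_id="TOY2",
        factor_name="toy",
        counts=np.array(
            [[0.7, 0.1], [0.1, 0.1], [0.1, 0.7], [0.1, 0.1]]
        ),
    )


@pytest.fixture(scope="session")
def toy_lom(toy_pwm):
    """Log-odds form of the toy matrix: no pseudocount, uniform background."""
    return pwm_log_odds(toy_pwm, Background.uniform(), pseudocount=0.0)


@pytest.fixture(scope="session")
def library() -> MotifLibrary:
    """The package's synthetic six-factor demonstration library."""
    return demo_library()


@pytest.fixture()
def jaspar_file(tmp_path):
    path = tmp_path / "motifs.jaspar"
    path.write_text(
        ">M001 ONEHOT\n"
        "A [ 10 0 ]\n"
        "C [ 0 0 ]\n"
        "G [ 0 10 ]\n"
        "T [ 0 0 ]\n"
        ">M002 SECOND\n"
        "A [1 2 3]\n"
        "C [1 2 3]\n"
        "G [1 2 3]\n"
        "T [1 2 3]\n"
    )
    return path
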