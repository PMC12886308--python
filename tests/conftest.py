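import numpy as np
import pytest

import jawlever as jl


@pytest.fixture
def textbook():
    """Single perpendicular-muscle jaw with closed-form bite forces."""
    return jl.make_textbook_specimen()


@pytest.fixture
def specimen():
    """One representative synthetic specimen."""
    return jl.make_specimen(42)


@pytest.fixture
def open_specimen():
    """Synthetic specimen posed with the mouth 20 degrees open."""
    return jl.make_specimen(42, gape_deg=20.0)


def statics_oracle_bite_forces(lm, muscle_forces) -> np.ndarray:
    """Independent 2D rigid-body statics solution.

    ``muscle_forces`` is a list of (muscle, applied force magnitude N)
    pairs.  Forces are laid out as explicit 2D vectors along each
    insertion->origin line; torques about the jaw joint come from the z
    component of r x F, and the tooth reaction balances the summed torque
    over the outlever.  Shares no code with the lever engine beyond
    landmark lookup.
    """
    aq = lm.point("7")
    total_torque = 0.0
    for m, f in muscle_forces:
        ins = lm.point(m.insertion_id)
        org = lm.point(m.origin_id)
        u = (org - ins) / np.linalg.norm(org - ins)
        fvec = f * u
        r = ins - aq
        total_torque += r[0] * fvec[1] - r[1] * fvec[0]
    out = []
    for tip in lm.tooth_tips:
        out.append(abs(total_torque) / np.linalg.norm(tip - aq))
    return np.array(out)
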