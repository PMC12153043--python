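import numpy as np
import pytest

import diatomgel as dg
from diatomgel.ptv import detect_stack, displacement_field, link_trajectories

# Geometry shared by the cavity-field fixtures: an inclusion growing from
# 50 to 60 um in the middle of a 512 px / 500 um field of view.
A0, A1 = 50.0, 60.0
CENTER = (250.0, 250.0)
DELTA = A1**3 - A0**3


def analytic_radial_strain(r):
    """Closed-form eps_rr = du_r/dr of the incompressible cavity field."""
    r = np.asarray(r, dtype=float)
    return r**2 / (r**3 + DELTA) ** (2.0 / 3.0) - 1.0


@pytest.fixture(scope="session")
def growth_params():
    return dg.GrowthParams()


@pytest.fixture(scope="session")
def bead_chain():
    """Rendered cavity-field bead stack plus the measured PTV chain.

    One moderately dense stack (2000 beads over 500 x 500 um) shared by the
    detection, linking, displacement-profile and strain tests.
    """
    cfg = dg.SimConfig(seed=11)
    field = dg.CavityField(a0=A0, a1=A1, center=CENTER)
    stack, truth = dg.gen_bead_stack(field, cfg, n_frames=20, n_beads=2000,
                                     min_sep_px=6)
    frames = detect_stack(stack, cfg.px_size, min_separation=3, threshold=0.2)
    traj = link_trajectories(frames, max_disp=1.5)
    vectors = displacement_field(traj, 0, 19)
    return {
        "cfg": cfg,
        "field": field,
        "stack": stack,
        "truth": truth,
        "frames": frames,
        "traj": traj,
        "vectors": vectors,
    }
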