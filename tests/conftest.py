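import numpy as np
import pandas as pd
import pytest

from nanoswitch.calibration import CalibrationCurve, evaluate_sigmoid
from nanoswitch.kinetics import KineticParams


@pytest.fixture
def params():
    return KineticParams()


def normalized_hill_curve(ec50=1030.0, zero_conc=125.0, unity_conc=506.0):
    """Slope-1 Hill curve re-expressed on the anchor-normalized scale.

    With f(C) = C/(EC50+C), S(C) = (f(C)-f(lo))/(f(hi)-f(lo)) is itself a
    four-parameter logistic with the same EC50 and n=1; this computes its
    plateaus in closed form.  Used as an exact oracle for strategy tests.
    """
    f = lambda c: c / (ec50 + c)
    delta = f(unity_conc) - f(zero_conc)
    s_min = -f(zero_conc) / delta
    s_max = s_min + 1.0 / delta
    return CalibrationCurve(S_min=s_min, S_max=s_max, EC50_pM=ec50, n=1.0)


def make_records(curve, injections, anchor_concs=(125.0, 506.0),
                 n_intervals=8, raw_scale=1.0, raw_offset=2.0,
                 noise_sd=0.0, drift=None, seed=0):
    """Synthetic experiment record table with known ground truth.

    ``injections``: list of (concentration_pM, role).  Raw activity is an
    affine transform of the curve's signal, optionally drifted and noised.
    """
    rng = np.random.default_rng(seed)
    rows = []
    t = 0.0
    for k, (conc, role) in enumerate(injections):
        for i in range(n_intervals):
            tm = t + 0.5 + i
            s = evaluate_sigmoid(curve, conc)
            a = raw_offset + raw_scale * s
            if drift is not None:
                a *= drift(tm)
            if noise_sd:
                a += rng.normal(0.0, noise_sd)
            rows.append((tm, k, role, conc, 0, 1, a))
        t += n_intervals
    return pd.DataFrame(rows, columns=["t_min", "injection_index", "role",
                                       "true_conc_pM", "counts", "n_particles",
                                       "activity"])
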