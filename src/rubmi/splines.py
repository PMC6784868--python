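"""Cubic B-spline basis for the age pattern of mean BMI.

The same centred basis is used by the synthetic-data generator (to perturb
country age patterns) and by the trend model (global age curve plus shrunken
country deviations), so a well-specified recovery test exercises one code
path against the other.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

DEFAULT_KNOTS = (30.0, 45.0, 60.0)
DEFAULT_BOUNDARY = (18.0, 85.0)
REF_AGE = 40.0


def bspline_basis(
    x,
    knots=DEFAULT_KNOTS,
    boundary=DEFAULT_BOUNDARY,
    ref_age: float | None = REF_AGE,
) -> np.ndarray:
    """Cubic B-spline design matrix at ages ``x``, optionally centred.

    Centring subtracts the basis row at ``ref_age`` so the spline contributes
    zero at the reference age; the level is then carried entirely by the
    model intercept, which keeps the two identifiable.
    """
    x = np.clip(np.asarray(x, dtype=float), boundary[0], boundary[1])
    t = np.r_[
        np.repeat(boundary[0], 4), np.asarray(knots, dtype=float), np.repeat(boundary[1], 4)
    ]
    # design_matrix is strict about the right endpoint; nudge it inside.
    xe = np.minimum(x, boundary[1] - 1e-9)
    B = BSpline.design_matrix(xe, t, 3).toarray()
    if ref_age is not None:
        Bref = BSpline.design_matrix(
            np.array([min(ref_age, boundary[1] - 1e-9)]), t, 3
        ).toarray()
        B = B - Bref
    return B
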