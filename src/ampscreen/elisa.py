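"""Four-parameter logistic (4PL) calibration of ELISA standard curves.

Absorbance as a function of analyte concentration x is modelled as

    f(x) = d + (a - d) / (1 + (x / c) ** b)

with lower/zero-dose response ``a``, saturating response ``d``, inflection
concentration ``c`` (where f(c) = (a + d) / 2) and Hill slope ``b``. The
inverse of the fitted curve converts sample absorbances to concentrations;
it is defined only strictly between the asymptotes, and callers receive a
flag for out-of-range absorbances rather than an extrapolated value.

The standard assay design is a twofold dilution series of purified analyte
(e.g. TNF-alpha from 31.25 to 2000 pg/mL) measured in duplicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, InputError


def four_pl(x, a: float, d: float, c: float, b: float):
    """Evaluate the 4PL curve at concentration(s) ``x``."""
    x = np.asarray(x, dtype=float)
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass(frozen=True)
class FourPLFit:
    """A fitted 4PL calibration curve with its inverse."""

    lower_asymptote: float  # a: response at zero dose
    upper_asymptote: float  # d: saturating response
    inflection: float       # c, pg/mL
    hill_slope: float       # b
    rmse: float
    n_points: int

    def response(self, concentration):
        """Predicted absorbance at the given concentration(s)."""
        return four_pl(concentration, self.lower_asymptote,
                       self.upper_asymptote, self.inflection, self.hill_slope)

    def concentration(self, absorbance: float) -> tuple[float, bool]:
        """Invert the curve: absorbance -> (concentration pg/mL, in_range).

        Returns ``(nan, False)`` when the absorbance lies outside the open
        interval between the asymptotes, where the curve has no inverse.
        """
        a, d = self.lower_asymptote, self.upper_asymptote
        lo, hi = min(a, d), max(a, d)
        if not lo < absorbance < hi:
            return float("nan"), False
        ratio = (a - d) / (absorbance - d) - 1.0
        return float(self.inflection * ratio ** (1.0 / self.hill_slope)), True


def fit_four_pl(standard_concentrations, absorbances) -> FourPLFit:
    """Least-squares 4PL fit to standard wells.

    ``standard_concentrations`` and ``absorbances`` are parallel sequences;
    replicate wells simply repeat a concentration. Requires at least five
    distinct positive concentrations and a monotone dose-response trend.
    """
    x = np.asarray(standard_concentrations, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("concentrations and absorbances must be parallel 1-D")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise InputError("standards contain non-finite values")
    if np.any(x <= 0):
        raise InputError("standard concentrations must be > 0")
    distinct = np.unique(x)
    if distinct.size < 5:
        raise FitError("need >= 5 distinct standard concentrations")

    # mean response per concentration, used for trend checks and start values
    means = np.array([y[x == cx].mean() for cx in distinct])
    increasing = means[-1] > means[0]
    if np.ptp(means) <= 0:
        raise FitError("degenerate standards: flat response")

    a0 = float(means[0] if increasing else means[-1])
    d0 = float(means[-1] if increasing else means[0])
    c0 = float(np.exp(np.mean(np.log(distinct))))
    b0 = 1.0 if increasing else -1.0
    try:
        params, _ = curve_fit(four_pl, x, y, p0=(a0, d0, c0, b0), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    a, d, c, b = (float(v) for v in params)
    if c <= 0 or not np.isfinite([a, d, c, b]).all():
        raise FitError("4PL fit produced non-physical parameters")

    # monotonicity over the standards' range: d(f)/dx keeps one sign there
    grid = np.geomspace(distinct[0], distinct[-1], 101)
    resp = four_pl(grid, a, d, c, b)
    diffs = np.diff(resp)
    if not (np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12)):
        raise FitError("fitted 4PL curve is not monotone over the standards")

    rmse = float(np.sqrt(np.mean((four_pl(x, a, d, c, b) - y) ** 2)))
    return FourPLFit(a, d, c, b, rmse, int(x.size))
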