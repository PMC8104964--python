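"""Amplicon observation-efficiency calibration and length-bias correction.

PCR amplification and sequencing favour short templates, so when a Cas9 cut
produces large deletions the edited (shorter) amplicons are over-represented
in read counts relative to their molar abundance. This module estimates that
bias from spike-in pools of fragments with known starting composition and
uses it to rescale read counts onto a common (wild-type) length scale.

The model: each fragment i of a pool is observed with a length-dependent
efficiency e_i, so its read fraction is

    m_i = e_i * s_i / sum_j e_j * s_j

where s_i is its starting molar fraction. Fixing the efficiency of a
designated reference fragment to 1 makes the system identifiable; log2(e)
is then regressed on fragment length, and the slope (log2 units per bp)
drives the correction

    count_corr = count * 2 ** (slope * (l_WT - l_read)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .errors import FitError, InputError, InvalidPoolError, NumericalError

#: Default per-bp log2 observation-efficiency slope used when no calibration
#: pools are available. Empirically determined for a MiSeq two-round PCR
#: library preparation on 146-539 bp amplicons; negative because longer
#: templates amplify and sequence less efficiently.
DEFAULT_SLOPE_LOG2_PER_BP = -0.014356

#: Fragment lengths (bp) of the standard five-member calibration pool design.
DEFAULT_POOL_LENGTHS = (146, 249, 349, 447, 539)

#: Length (bp) of the fragment whose efficiency is fixed to 1.
DEFAULT_REFERENCE_LENGTH = 447

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class CalibrationPool:
    """A spike-in pool: fragments of known length and starting composition.

    Parameters
    ----------
    fragment_lengths
        Distinct fragment lengths in bp.
    starting_fractions
        Molar fractions before library preparation (``s_i``); must sum to 1.
    measured_fractions
        Read-count fractions after sequencing (``m_i``); must sum to 1.
    reference_index
        Index of the fragment whose observation efficiency is fixed to 1.
    pool_id
        Free-text identifier.
    """

    fragment_lengths: tuple[int, ...]
    starting_fractions: tuple[float, ...]
    measured_fractions: tuple[float, ...]
    reference_index: int
    pool_id: str = "pool"

    def __post_init__(self) -> None:
        n = len(self.fragment_lengths)
        if n < 2:
            raise InputError("calibration pool needs at least two fragments")
        if len(self.starting_fractions) != n or len(self.measured_fractions) != n:
            raise InputError("fragment_lengths, starting_fractions and "
                             "measured_fractions must have equal length")
        if len(set(self.fragment_lengths)) != n:
            raise InputError("fragment lengths must be distinct within a pool")
        if not 0 <= self.reference_index < n:
            raise InputError("reference_index out of range")
        s = np.asarray(self.starting_fractions, dtype=float)
        m = np.asarray(self.measured_fractions, dtype=float)
        if np.any(s <= 0):
            raise InputError("all starting fractions must be > 0")
        if np.any(m < 0):
            raise InputError("measured fractions must be >= 0")
        for name, v in (("starting", s), ("measured", m)):
            if abs(v.sum() - 1.0) > 1e-6:
                raise InputError(f"{name} fractions must sum to 1 (got {v.sum():.9f})")

    @classmethod
    def from_counts(cls, fragment_lengths, starting_fractions, read_counts,
                    reference_index, pool_id="pool") -> "CalibrationPool":
        """Build a pool from raw read counts, normalizing to fractions."""
        counts = np.asarray(read_counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise InputError(f"pool {pool_id!r}: no reads")
        s = np.asarray(starting_fractions, dtype=float)
        return cls(tuple(int(x) for x in fragment_lengths),
                   tuple(s / s.sum()), tuple(counts / total),
                   reference_index, pool_id)


@dataclass(frozen=True)
class EfficiencySet:
    """Observation efficiencies solved for one pool, aligned to its fragments."""

    efficiencies: tuple[float, ...]
    pool_id: str = "pool"


@dataclass(frozen=True)
class BiasModel:
    """Fitted exponential length-bias model: log2(e) = intercept + slope * length."""

    slope_log2_per_bp: float
    intercept_log2: float = 0.0
    n_points: int = 0
    r_squared: float = float("nan")

    @classmethod
    def identity(cls) -> "BiasModel":
        """A no-op model: slope 0, every correction factor exactly 1."""
        return cls(0.0, 0.0, 0, float("nan"))

    @classmethod
    def fixed(cls, slope: float = DEFAULT_SLOPE_LOG2_PER_BP) -> "BiasModel":
        """A model with a caller-supplied slope and no fit diagnostics."""
        return cls(float(slope), 0.0, 0, float("nan"))


def solve_observation_efficiencies(pool: CalibrationPool) -> EfficiencySet:
    """Solve the per-fragment observation efficiencies of one pool.

    Sets the reference fragment's efficiency to 1 and solves the remaining
    n-1 linear equations

        (m_i - 1) e_i s_i + m_i * sum_{j != i, ref} e_j s_j = -m_i * s_ref

    exactly (dense solve). The solution satisfies
    ``m_i = e_i s_i / sum_j e_j s_j`` to within 1e-9.

    Raises
    ------
    NumericalError
        If the system is singular (e.g. a fragment with s_i > 0 received
        zero reads, which carries no efficiency information).
    InvalidPoolError
        If any solved efficiency is <= 0; such pools are reported rather
        than silently clipped so that bad measurements stay visible.
    """
    s = np.asarray(pool.starting_fractions, dtype=float)
    m = np.asarray(pool.measured_fractions, dtype=float)
    ref = pool.reference_index
    n = len(s)
    if np.any(m == 0):
        raise NumericalError(
            f"pool {pool.pool_id!r}: fragment(s) "
            f"{[i for i in range(n) if m[i] == 0]} have zero measured "
            "fraction with nonzero starting fraction; system is singular")

    free = [i for i in range(n) if i != ref]
    a = np.empty((n - 1, n - 1))
    b = np.empty(n - 1)
    for row, i in enumerate(free):
        for col, j in enumerate(free):
            a[row, col] = (m[i] - 1.0) * s[i] if j == i else m[i] * s[j]
        b[row] = -m[i] * s[ref]
    try:
        e_free = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(f"pool {pool.pool_id!r}: singular system: {exc}") from exc

    e = np.ones(n)
    e[free] = e_free
    if np.any(e <= 0):
        raise InvalidPoolError(
            f"pool {pool.pool_id!r}: non-positive solved efficiency "
            f"{e.tolist()}; measurements are inconsistent with the model")

    # Self-consistency: the forward model must reproduce the measurements.
    m_back = e * s / np.dot(e, s)
    if not np.allclose(m_back, m, atol=1e-8, rtol=1e-8):
        raise NumericalError(
            f"pool {pool.pool_id!r}: solved efficiencies do not reproduce "
            "measured fractions")
    return EfficiencySet(tuple(e), pool.pool_id)


def fit_length_bias(pools: list[tuple[CalibrationPool, EfficiencySet]]) -> BiasModel:
    """Pool (length, log2 efficiency) points across pools and fit OLS.

    Reference fragments contribute their pinned point (log2 e = 0) like any
    other; points are unweighted. At least two distinct lengths are required.
    """
    lengths: list[float] = []
    log2e: list[float] = []
    for pool, effs in pools:
        if len(effs.efficiencies) != len(pool.fragment_lengths):
            raise InputError("efficiency set does not match its pool")
        for length, e in zip(pool.fragment_lengths, effs.efficiencies):
            if e <= 0:
                raise InputError("efficiencies must be > 0 to take log2")
            lengths.append(float(length))
            log2e.append(float(np.log2(e)))
    if len(set(lengths)) < 2:
        raise FitError("need >= 2 distinct fragment lengths to fit a slope")

    x = sm.add_constant(np.asarray(lengths))
    fit = sm.OLS(np.asarray(log2e), x).fit()
    intercept, slope = fit.params
    if len(lengths) <= 2 or fit.centered_tss <= 1e-300:
        rsq = 1.0  # perfect by construction (or flat: nothing to explain)
    else:
        rsq = float(fit.rsquared)
    return BiasModel(float(slope), float(intercept), len(lengths), rsq)


def correct_count(count: float, l_wt: int, l_read: int, bias: BiasModel) -> float:
    """Rescale a read count for the length difference to the WT amplicon.

    ``count_corr = count * 2 ** (slope * (l_WT - l_read))``. With the
    (negative) fitted slope this down-weights reads from shortened amplicons,
    undoing their observation advantage. Identity when lengths are equal or
    the slope is 0.
    """
    if l_wt <= 0 or l_read <= 0:
        raise InputError("amplicon lengths must be positive")
    if count < 0:
        raise InputError("count must be non-negative")
    return count * 2.0 ** (bias.slope_log2_per_bp * (l_wt - l_read))
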