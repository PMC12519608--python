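"""Restricted cubic spline (RCS) bases.

The same truncated-power RCS construction is used in two places: on log
time, to model the baseline log cumulative cause-specific hazard of a
flexible parametric survival model, and on (logit) predicted risk, to smooth
calibration curves.  A basis with ``M`` knots has ``M - 1`` columns; the
first column is the identity (linear) term and each remaining column is the
restricted truncated cubic for one interior knot, so the fitted function is
linear beyond the boundary knots with continuous value, first and second
derivative at every interior knot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KnotVector", "make_knots", "rcs_basis", "rcs_deriv_basis"]


@dataclass(frozen=True)
class KnotVector:
    """Ordered knot locations; first and last are the boundary knots."""

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if k.size < 2:
            raise ValueError("knot vector needs at least 2 knots")
        if not np.all(np.diff(k) > 0):
            raise ValueError("degenerate knot vector: knots must be strictly increasing")
        object.__setattr__(self, "knots", tuple(float(v) for v in k))

    @property
    def boundary(self) -> tuple[float, float]:
        return self.knots[0], self.knots[-1]

    @property
    def interior(self) -> tuple[float, ...]:
        return self.knots[1:-1]

    @property
    def n_basis(self) -> int:
        """Number of basis columns (knots minus one)."""
        return len(self.knots) - 1

    def __len__(self) -> int:
        return len(self.knots)


def make_knots(
    values: np.ndarray,
    n_interior: int,
    boundary_percentiles: tuple[float, float] = (5.0, 95.0),
) -> KnotVector:
    """Place knots at percentiles of ``values``.

    Boundary knots sit at the requested percentiles; interior knots at
    equally spaced percentiles in between (linear interpolation between
    order statistics throughout).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot place knots on empty data")
    lo, hi = boundary_percentiles
    if not (0 <= lo < hi <= 100):
        raise ValueError("boundary percentiles must satisfy 0 <= lo < hi <= 100")
    pcts = np.linspace(lo, hi, n_interior + 2)
    knots = np.percentile(values, pcts, method="linear")
    if np.unique(knots).size != knots.size:
        raise ValueError("degenerate knot vector: too few distinct values for requested knots")
    return KnotVector(tuple(knots))


def _interior_terms(x: np.ndarray, knots: KnotVector, deriv: bool) -> list[np.ndarray]:
    kmin, kmax = knots.boundary
    span = kmax - kmin
    cols = []
    for kj in knots.interior:
        lam = (kmax - kj) / span
        if deriv:
            col = (
                3.0 * np.clip(x - kj, 0.0, None) ** 2
                - lam * 3.0 * np.clip(x - kmin, 0.0, None) ** 2
                - (1.0 - lam) * 3.0 * np.clip(x - kmax, 0.0, None) ** 2
            )
        else:
            col = (
                np.clip(x - kj, 0.0, None) ** 3
                - lam * np.clip(x - kmin, 0.0, None) ** 3
                - (1.0 - lam) * np.clip(x - kmax, 0.0, None) ** 3
            )
        cols.append(col)
    return cols


def rcs_basis(x: np.ndarray, knots: KnotVector) -> np.ndarray:
    """Evaluate the RCS basis at ``x``: shape (len(x), len(knots) - 1).

    Column 0 is ``x`` itself; column j is the restricted truncated cubic
    (x-k_j)^3_+ - lam_j (x-k_min)^3_+ - (1-lam_j)(x-k_max)^3_+ with
    lam_j = (k_max-k_j)/(k_max-k_min) for interior knot k_j.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return np.column_stack([x, *_interior_terms(x, knots, deriv=False)])


def rcs_deriv_basis(x: np.ndarray, knots: KnotVector) -> np.ndarray:
    """Elementwise derivative of :func:`rcs_basis` with respect to ``x``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return np.column_stack([np.ones_like(x), *_interior_terms(x, knots, deriv=True)])
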