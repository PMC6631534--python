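"""One-parameter bifurcation analysis in β-TrCP under sustained TNF.

The stimulated (TNF = 1) steady state is continued over a log-spaced
β-TrCP grid; stability follows from the eigenvalues of the analytic
Jacobian (stable iff every real part is negative). A Hopf point is a
parameter value at which the leading conjugate pair crosses the imaginary
axis while all other eigenvalues keep negative real parts; crossings are
bracketed on the coarse branch and refined by bisection on the leading
real part. Between the two Hopf points the steady state is unstable and a
stable limit cycle carries the dynamics; cycles are characterized by long
simulation — amplitude envelope from the post-transient extrema, period
from the dominant discrete-Fourier frequency with quadratic bin
interpolation (cross-checkable against mean peak-to-peak intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .model import NM_PER_UM, ParameterSet, StateVector, Stimulus, state_from_x14, _jac14
from .simulate import (
    SteadyStateError,
    Trajectory,
    solve_steady_state,
    stimulated_response,
)
from .measures import detect_peaks

__all__ = [
    "BranchPoint",
    "SteadyStateBranch",
    "HopfPoint",
    "LimitCycleSummary",
    "NoLimitCycleError",
    "steady_state_branch",
    "find_hopf_points",
    "limit_cycle_summary",
    "bisect_real_part_crossing",
    "dft_period",
]

#: |Re λ| certification bound for the critical pair at a Hopf point (1/s,
#: the model's rate units)
HOPF_RE_TOL = 1.0e-6
#: default branch grid size over [5e-5, 2] nM
BRANCH_GRID_SIZE = 200
#: default search range (nM)
SEARCH_RANGE_NM = (5.0e-5, 2.0)


class NoLimitCycleError(RuntimeError):
    """The long-run trajectory converges to a point instead of a cycle."""


@dataclass
class BranchPoint:
    """One record of the steady-state branch."""

    btrcp_nM: float
    state: StateVector
    eigenvalues: np.ndarray  # 14 complex eigenvalues, 1/s (model rate units)
    stable: bool

    @property
    def max_real_part(self) -> float:
        return float(np.max(self.eigenvalues.real))


@dataclass
class SteadyStateBranch:
    """Steady states, eigenvalues and stability labels over a β-TrCP grid."""

    points: list[BranchPoint]
    tnf: int
    gaps_nM: list[float] = field(default_factory=list)  # grid values lost by continuation

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, key):
        return self.points[key]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            row = {"btrcp_nM": p.btrcp_nM}
            row.update({s: v for s, v in p.state.to_dict().items()})
            row["nuclear_nfkb_nM"] = p.state["NFkBn"]  # per-nucleus, nM
            row["max_real_eig"] = p.max_real_part
            row["stability"] = "stable" if p.stable else "unstable"
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class HopfPoint:
    """A stability change of the stimulated steady state."""

    btrcp_nM: float
    critical_pair: tuple[complex, complex]  # 1/s
    bracket_width_nM: float

    @property
    def frequency_per_min(self) -> float:
        """|Im λ| of the critical pair, cycles per minute."""
        return abs(self.critical_pair[0].imag) * 60.0 / (2.0 * np.pi)


@dataclass
class LimitCycleSummary:
    """Envelope and period of the stable limit cycle at one β-TrCP value."""

    btrcp_nM: float
    env_min_nM: float   # min of nuclear NF-κB (whole-cell nM) over the cycle
    env_max_nM: float
    period_min: float   # min


def _eigs_at(params: ParameterSet, x_uM: np.ndarray, tnf: int,
             btrcp_nM: float) -> np.ndarray:
    b = Stimulus(tnf=tnf, btrcp_nM=btrcp_nM).btrcp_factor(0.0, params)
    return np.linalg.eigvals(_jac14(x_uM, params, float(tnf), b))


def steady_state_branch(
    params: ParameterSet,
    btrcp_grid_nM: np.ndarray | None = None,
    tnf: int = 1,
) -> SteadyStateBranch:
    """Continue the steady state over a strictly increasing β-TrCP grid.

    Each solve is seeded from the previous solution (natural-parameter
    continuation); the first point is obtained from long relaxation. Grid
    values where even a locally refined restart fails are recorded in
    ``gaps_nM`` and skipped with a warning rather than aborting the scan.
    """
    if btrcp_grid_nM is None:
        btrcp_grid_nM = np.logspace(np.log10(SEARCH_RANGE_NM[0]),
                                    np.log10(SEARCH_RANGE_NM[1]),
                                    BRANCH_GRID_SIZE)
    grid = np.asarray(btrcp_grid_nM, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("β-TrCP grid must be strictly increasing")
    points: list[BranchPoint] = []
    gaps: list[float] = []
    x_prev: np.ndarray | None = None
    for bv in grid:
        try:
            x = solve_steady_state(params, tnf, bv, x0_uM=x_prev,
                                   allow_integration_fallback=x_prev is None)
        except SteadyStateError:
            try:  # local refinement: relax from scratch at this value
                x = solve_steady_state(params, tnf, bv)
            except SteadyStateError:
                import warnings

                warnings.warn(f"continuation lost the branch at β-TrCP={bv:.4g} nM")
                gaps.append(bv)
                continue
        ev = _eigs_at(params, x, tnf, bv)
        points.append(BranchPoint(
            btrcp_nM=float(bv),
            state=state_from_x14(x, params),
            eigenvalues=ev,
            stable=bool(np.all(ev.real < 0)),
        ))
        x_prev = x
    return SteadyStateBranch(points=points, tnf=tnf, gaps_nM=gaps)


def bisect_real_part_crossing(
    leading_real_part: Callable[[float], float],
    lo: float,
    hi: float,
    rel_tol: float = 1.0e-3,
) -> float:
    """Bisect a sign change of ``leading_real_part`` on [lo, hi].

    Bisection runs on log-parameter (the natural scale of the scan) until
    the bracket's relative width drops below ``rel_tol``; the sign change
    must already be bracketed.
    """
    f_lo = leading_real_part(lo)
    f_hi = leading_real_part(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError("interval does not bracket a sign change")
    while (hi - lo) / hi > rel_tol:
        mid = float(np.sqrt(lo * hi))
        f_mid = leading_real_part(mid)
        if f_mid == 0.0:
            return mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return float(np.sqrt(lo * hi))


def find_hopf_points(
    params: ParameterSet,
    search_interval_nM: tuple[float, float] = SEARCH_RANGE_NM,
    n_coarse: int = BRANCH_GRID_SIZE,
    tnf: int = 1,
    rel_tol: float = 1.0e-3,
) -> list[HopfPoint]:
    """Locate stability changes of the stimulated steady state.

    A coarse branch brackets sign changes of the leading eigenvalue real
    part; each bracket is refined by bisection to relative width below
    ``rel_tol``. Returns points sorted by β-TrCP; an interval with no sign
    change yields an empty list.
    """
    lo_nM, hi_nM = search_interval_nM
    grid = np.logspace(np.log10(lo_nM), np.log10(hi_nM), n_coarse)
    branch = steady_state_branch(params, grid, tnf=tnf)
    pts = branch.points

    cache: dict[float, np.ndarray] = {p.btrcp_nM: _x_of(p, params) for p in pts}

    def leading(bv: float) -> float:
        # seed from the nearest solved value for robust continuation
        nearest = min(cache, key=lambda k: abs(np.log(k) - np.log(bv)))
        x = solve_steady_state(params, tnf, bv, x0_uM=cache[nearest])
        cache[bv] = x
        return float(np.max(_eigs_at(params, x, tnf, bv).real))

    hopf: list[HopfPoint] = []
    for p0, p1 in zip(pts[:-1], pts[1:]):
        r0, r1 = p0.max_real_part, p1.max_real_part
        if np.sign(r0) == np.sign(r1):
            continue
        b_star = bisect_real_part_crossing(leading, p0.btrcp_nM, p1.btrcp_nM,
                                           rel_tol=rel_tol)
        nearest = min(cache, key=lambda k: abs(np.log(k) - np.log(b_star)))
        x_star = solve_steady_state(params, tnf, b_star, x0_uM=cache[nearest])
        ev = _eigs_at(params, x_star, tnf, b_star)
        order = np.argsort(ev.real)[::-1]
        pair = (ev[order[0]], ev[order[1]])
        hopf.append(HopfPoint(
            btrcp_nM=float(b_star),
            critical_pair=(complex(pair[0]), complex(pair[1])),
            bracket_width_nM=float(rel_tol * b_star),
        ))
    return sorted(hopf, key=lambda h: h.btrcp_nM)


def _x_of(point: BranchPoint, params: ParameterSet) -> np.ndarray:
    from .model import SPECIES

    v = point.state.values / NM_PER_UM
    return np.delete(v, SPECIES.index("NFkB"))


def dft_period(t_min: np.ndarray, y: np.ndarray) -> float:
    """Period (min) from the dominant nonzero DFT frequency of a uniform
    series, with quadratic interpolation around the peak bin."""
    dt = float(t_min[1] - t_min[0])
    z = np.asarray(y, dtype=float) - float(np.mean(y))
    amp = np.abs(np.fft.rfft(z))
    freq = np.fft.rfftfreq(z.size, dt)
    k = int(np.argmax(amp[1:]) + 1)
    if 1 <= k < amp.size - 1:
        a, b, c = amp[k - 1], amp[k], amp[k + 1]
        denom = a - 2 * b + c
        shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
    else:
        shift = 0.0
    f = freq[k] + shift * (freq[1] - freq[0])
    if f <= 0:
        raise NoLimitCycleError("no dominant nonzero frequency found")
    return float(1.0 / f)


def limit_cycle_summary(
    params: ParameterSet,
    btrcp_nM: float,
    horizon_min: float = 10_000.0,
    transient_min: float = 2_000.0,
    dt_min: float = 0.5,
    min_amplitude_nM: float = 1.0e-2,
) -> LimitCycleSummary:
    """Characterize the stable limit cycle at one inter-Hopf β-TrCP value.

    Protocol: simulate the TNF step for ``horizon_min`` starting from the
    resting state, discard ``transient_min`` as transient, estimate the
    period from the detrended DFT (quadratic bin interpolation) and take
    the amplitude envelope over the last 10 full cycles. Nuclear NF-κB is
    whole-cell-equivalent nM. Raises :class:`NoLimitCycleError` with the
    measured decay rate if the oscillation has died out instead.
    """
    traj = stimulated_response(params, Stimulus(tnf=1, btrcp_nM=btrcp_nM),
                               t_final_min=horizon_min, dt_out_min=dt_min)
    m = traj.t_min >= transient_min
    t, y = traj.t_min[m], traj.nuclear_nfkb()[m]
    span = float(np.max(y) - np.min(y))
    if span < min_amplitude_nM:
        # quantify the residual decay over the post-transient window
        half = y[: y.size // 2], y[y.size // 2:]
        s0, s1 = np.ptp(half[0]), np.ptp(half[1])
        rate = (np.log(s0 / s1) / (t[-1] - t[0]) * 2.0) if s1 > 0 and s0 > 0 else np.inf
        raise NoLimitCycleError(
            f"no limit cycle at β-TrCP={btrcp_nM:.4g} nM: post-transient span "
            f"{span:.3e} nM < {min_amplitude_nM} nM (decay rate ≈ {rate:.3e}/min)"
        )
    period = dft_period(t, y)
    tail = t >= t[-1] - 10.0 * period
    return LimitCycleSummary(
        btrcp_nM=float(btrcp_nM),
        env_min_nM=float(np.min(y[tail])),
        env_max_nM=float(np.max(y[tail])),
        period_min=period,
    )


def peak_interval_period(t_min: np.ndarray, y: np.ndarray,
                         min_prominence: float = 1.0e-3) -> float:
    """Mean peak-to-peak interval (min) — independent cross-check of
    :func:`dft_period` on the same series."""
    peaks = detect_peaks(t_min, y, min_prominence=min_prominence)
    if len(peaks) < 3:
        raise NoLimitCycleError("too few peaks for a peak-interval period")
    times = np.array([p[0] for p in peaks])
    return float(np.mean(np.diff(times)))
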