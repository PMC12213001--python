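"""Per-trajectory movement indices.

Six statistics characterize each walking path:

* ``length`` (L): total path length, metres.
* ``net_displacement`` (D): Euclidean start-to-end distance, metres.
* ``TS``: straightness index D/L in [0, 1]; 1 for a perfectly directed walk.
* ``S2``: corrected sinuosity, ``2 * [p * ((1 + c)/(1 - c) + b**2)]**(-1/2)``
  where p is the mean step length, b the coefficient of variation of step
  length and c the mean cosine of turning angles.  Units rad * m**(-1/2);
  defined for constant-step-length paths, so it is evaluated on a
  rediscretized version of the trajectory.
* ``TE``: maximum expected displacement, ``c / (1 - c)``; dimensionless and
  scale-independent.  0 is maximally sinuous; straighter paths approach
  infinity.
* ``DC`` / ``SDDC``: mean and standard deviation of per-vertex directional
  change, the absolute turning angle in degrees divided by the forward time
  difference (degrees/second).

L, D, TS, DC and SDDC are computed on the raw (zero-step-cleaned) path; S2
and TE on the path rediscretized at the digitization resolution (default
0.05 m), since both are functionals of the turning-angle distribution of a
constant-step walk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateTrajectoryError, InvalidTrajectoryError
from .trajectory import StepSummary, TrajectoryPath, rediscretize, step_series, turning_angles

__all__ = [
    "MovementIndexSet",
    "path_length",
    "net_displacement",
    "straightness",
    "sinuosity2",
    "emax",
    "directional_change",
    "compute_all",
    "indices_table",
    "INDEX_COLUMNS",
]

#: Flag labels used in MovementIndexSet.flags
FLAG_STRAIGHT_LIMIT = "S2_straight_limit"      # c -> 1: S2 reported as its limit 0
FLAG_MAX_OSCILLATION = "S2_max_oscillation"    # c -> -1
FLAG_TE_INFINITE = "TE_infinite"               # c -> 1: TE unbounded
FLAG_SDDC_MISSING = "SDDC_missing"             # only one directional-change sample

DEFAULT_RESOLUTION = 0.05  # metres; digitization resolution of the traced paths

_C_TOL = 1e-12


@dataclass(frozen=True)
class MovementIndexSet:
    """The per-trajectory index bundle, with validity flags."""

    traj_id: str
    length: float
    net_displacement: float
    TS: float
    S2: float
    TE: float  # math.inf when flagged infinite
    DC: float
    SDDC: float  # nan when flagged missing
    flags: frozenset = field(default_factory=frozenset)

    def as_dict(self) -> dict:
        return {
            "traj_id": self.traj_id,
            "length_m": self.length,
            "net_displacement_m": self.net_displacement,
            "TS": self.TS,
            "S2": self.S2,
            "TE": self.TE,
            "DC_deg_s": self.DC,
            "SDDC_deg_s": self.SDDC,
            "flags": ";".join(sorted(self.flags)),
        }


INDEX_COLUMNS = [
    "traj_id", "length_m", "net_displacement_m", "TS", "S2", "TE",
    "DC_deg_s", "SDDC_deg_s", "flags",
]


def path_length(path: TrajectoryPath) -> float:
    """Total path length: the sum of Euclidean step lengths."""
    return float(path.step_lengths().sum())


def net_displacement(path: TrajectoryPath) -> float:
    """Euclidean distance between the first and last vertices."""
    return float(np.hypot(*(path.vertices[-1] - path.vertices[0])))


def straightness(path: TrajectoryPath) -> float:
    """Straightness index TS = D / L in [0, 1].

    Reliable as an efficiency measure for directed walks; a closed loop has
    TS = 0 and a straight path TS = 1.
    """
    L = path_length(path)
    if L <= 0:
        raise DegenerateTrajectoryError(f"{path.id}: zero path length")
    return net_displacement(path) / L


def sinuosity2(summary: StepSummary) -> tuple[float, frozenset]:
    """Corrected sinuosity S2 = 2 * [p * ((1+c)/(1-c) + b**2)]**(-1/2).

    Valid for a wide range of turning-angle distributions; for constant-step
    input b = 0.  Limit cases are flagged rather than raised: c -> 1 (a
    perfectly straight path) returns the limiting value 0; c -> -1 (maximal
    oscillation) returns the value with b carrying the whole denominator.
    """
    if len(summary.turning_angles) < 2:
        raise InvalidTrajectoryError("S2 needs at least 2 turning angles")
    p, b, c = summary.p, summary.b, summary.c
    flags: set = set()
    if c >= 1.0 - _C_TOL:
        return 0.0, frozenset({FLAG_STRAIGHT_LIMIT})
    if c <= -1.0 + _C_TOL:
        flags.add(FLAG_MAX_OSCILLATION)
    value = 2.0 / math.sqrt(p * ((1.0 + c) / (1.0 - c) + b * b))
    return value, frozenset(flags)


def emax(summary: StepSummary) -> tuple[float, frozenset]:
    """Maximum expected displacement TE = c / (1 - c).

    Monotonically increasing in the mean cosine c; flagged infinite for a
    perfectly straight path rather than capped at an arbitrary value.
    Negative c (anti-persistent walks) yields small negative values that are
    clipped to 0, the index floor.
    """
    if len(summary.turning_angles) < 1:
        raise InvalidTrajectoryError("TE needs at least 1 turning angle")
    c = summary.c
    if c >= 1.0 - _C_TOL:
        return math.inf, frozenset({FLAG_TE_INFINITE})
    return max(c / (1.0 - c), 0.0), frozenset()


def directional_change(path: TrajectoryPath) -> tuple[float, float, frozenset]:
    """Mean and SD of directional change, degrees per second.

    The angular change between successive displacement vectors at interior
    vertex i, in degrees, divided by the forward time difference
    t_{i+1} - t_i.  SDDC is the sample (ddof=1) standard deviation and is
    flagged missing (nan) when only one sample exists.
    """
    clean, _ = path.drop_zero_steps()
    if clean.n_vertices < 3:
        raise InvalidTrajectoryError(f"{path.id}: need >= 3 vertices for DC")
    angles = turning_angles(clean.displacements())
    dt = np.diff(clean.times)[1:]  # forward difference at each interior vertex
    dc = np.degrees(np.abs(angles)) / dt
    mean = float(dc.mean())
    if len(dc) < 2:
        return mean, math.nan, frozenset({FLAG_SDDC_MISSING})
    return mean, float(dc.std(ddof=1)), frozenset()


def compute_all(path: TrajectoryPath, R: float = DEFAULT_RESOLUTION) -> MovementIndexSet:
    """Compute the full index set for one trajectory.

    Length, D, TS, DC and SDDC come from the cleaned input path; S2 and TE
    from the path rediscretized at step ``R``.  All limit-case flags are
    propagated into ``flags``.
    """
    clean, _ = path.drop_zero_steps()
    L = path_length(clean)
    D = net_displacement(clean)
    TS = D / L
    DC, SDDC, dc_flags = directional_change(clean)
    const = rediscretize(clean, R)
    summary = step_series(const)
    S2, s2_flags = sinuosity2(summary)
    TE, te_flags = emax(summary)
    return MovementIndexSet(
        traj_id=path.id,
        length=L,
        net_displacement=D,
        TS=TS,
        S2=S2,
        TE=TE,
        DC=DC,
        SDDC=SDDC,
        flags=frozenset(dc_flags | s2_flags | te_flags),
    )


def indices_table(paths, R: float = DEFAULT_RESOLUTION) -> pd.DataFrame:
    """Index table for a collection of trajectories, one row per path."""
    rows = [compute_all(p, R).as_dict() for p in paths]
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)
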