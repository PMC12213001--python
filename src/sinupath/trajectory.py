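"""Planar walking trajectories: vertex sequences, step geometry and
rediscretization to constant step length.

A trajectory is an ordered sequence of 2-D vertices with strictly increasing
timestamps.  Coordinates are planar metric (metres); paths digitized from
field traces at a fixed spatial resolution are short enough that no geodesic
handling is needed.  Turning angles are signed, measured from each
displacement vector to the next via the two-argument arctangent of the cross
and dot products, which is numerically stable near 0 and pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateTrajectoryError,
    InvalidTrajectoryError,
    TimeOrderError,
    TooCoarseError,
)

__all__ = ["TrajectoryPath", "StepSummary", "step_series", "rediscretize"]


@dataclass(frozen=True)
class TrajectoryPath:
    """An ordered planar walking path.

    Parameters
    ----------
    id : str
        Trajectory label.
    vertices : (n, 2) ndarray
        x, y coordinates in metres.
    times : (n,) ndarray
        Seconds, strictly increasing.  If the raw data lack timestamps use
        :meth:`from_xy`, which assigns a uniform frame interval.
    meta : dict
        Free-form annotations (location, sex, censoring reason, ...).
    """

    id: str
    vertices: np.ndarray
    times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidTrajectoryError(
                f"{self.id}: vertices must be an (n, 2) array, got shape {v.shape}"
            )
        if len(v) < 2:
            raise InvalidTrajectoryError(f"{self.id}: fewer than 2 vertices")
        if len(t) != len(v):
            raise InvalidTrajectoryError(f"{self.id}: {len(t)} times for {len(v)} vertices")
        if not np.all(np.isfinite(v)):
            raise InvalidTrajectoryError(f"{self.id}: non-finite coordinate")
        if not np.all(np.isfinite(t)):
            raise InvalidTrajectoryError(f"{self.id}: non-finite timestamp")
        if np.any(np.diff(t) <= 0):
            raise TimeOrderError(f"{self.id}: timestamps not strictly increasing")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "times", t)

    @classmethod
    def from_xy(cls, id: str, x, y, t=None, frame_interval: float = 1.0,
                meta: dict | None = None) -> "TrajectoryPath":
        """Build a path from coordinate sequences; if ``t`` is None assign
        ``t_i = i * frame_interval`` (default 1 s per vertex)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if t is None:
            t = np.arange(len(x), dtype=float) * frame_interval
        return cls(id=id, vertices=np.column_stack([x, y]), times=np.asarray(t, float),
                   meta=meta or {})

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def displacements(self) -> np.ndarray:
        """(n-1, 2) array of successive displacement vectors."""
        return np.diff(self.vertices, axis=0)

    def step_lengths(self) -> np.ndarray:
        return np.hypot(*self.displacements().T)

    def drop_zero_steps(self) -> tuple["TrajectoryPath", int]:
        """Remove duplicate consecutive vertices (zero-length steps).

        Turning angles are undefined at zero displacement, so duplicated
        digitized points are removed before analysis.  Returns the cleaned
        path and the number of vertices dropped; the drop count is also
        recorded in ``meta['n_zero_steps_dropped']``.
        """
        keep = np.concatenate([[True], self.step_lengths() > 0.0])
        n_dropped = int((~keep).sum())
        if n_dropped == 0:
            return self, 0
        if keep.sum() < 2:
            raise DegenerateTrajectoryError(f"{self.id}: all steps have zero length")
        meta = dict(self.meta)
        meta["n_zero_steps_dropped"] = meta.get("n_zero_steps_dropped", 0) + n_dropped
        return (
            TrajectoryPath(self.id, self.vertices[keep], self.times[keep], meta),
            n_dropped,
        )


@dataclass(frozen=True)
class StepSummary:
    """Step-level statistics of a path.

    ``p`` (mean step length), ``b`` (coefficient of variation of step length)
    and ``c`` (mean cosine of turning angles) are the three moments entering
    the corrected sinuosity formula; ``c`` alone drives the maximum expected
    displacement.
    """

    n_steps: int
    step_lengths: np.ndarray
    turning_angles: np.ndarray  # signed, radians, in (-pi, pi]
    p: float
    b: float
    c: float
    n_zero_steps_dropped: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise DegenerateTrajectoryError("mean step length must be positive")


def turning_angles(displacements: np.ndarray) -> np.ndarray:
    """Signed angle from each displacement vector to the next.

    atan2(cross, dot) of consecutive vectors; result in (-pi, pi].
    """
    u, v = displacements[:-1], displacements[1:]
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dot = np.einsum("ij,ij->i", u, v)
    ang = np.arctan2(cross, dot)
    # map -pi to +pi so the half-open convention (-pi, pi] holds
    ang[ang == -np.pi] = np.pi
    return ang


def step_series(path: TrajectoryPath) -> StepSummary:
    """Extract step lengths, turning angles and their moments p, b, c.

    Zero-length steps (duplicate digitized points) are dropped first and the
    drop count recorded.  Requires at least 3 distinct vertices so that at
    least one turning angle exists.
    """
    clean, n_dropped = path.drop_zero_steps()
    if clean.n_vertices < 3:
        raise InvalidTrajectoryError(
            f"{path.id}: need >= 3 distinct vertices for turning angles"
        )
    disp = clean.displacements()
    lengths = np.hypot(*disp.T)
    angles = turning_angles(disp)
    p = float(lengths.mean())
    b = float(lengths.std(ddof=0) / p)
    c = float(np.cos(angles).mean())
    return StepSummary(
        n_steps=len(lengths),
        step_lengths=lengths,
        turning_angles=angles,
        p=p,
        b=b,
        c=c,
        n_zero_steps_dropped=n_dropped,
    )


def rediscretize(path: TrajectoryPath, R: float) -> TrajectoryPath:
    """Resample a path at constant step length ``R`` along its arc length.

    Output vertices lie on the input polyline (linear interpolation along arc
    length); every output step has length exactly ``R`` up to floating
    tolerance.  Any terminal remainder shorter than ``R`` is discarded rather
    than extrapolated, so the resampled length never exceeds the original and
    differs from it by less than ``R``.  Timestamps are interpolated linearly
    in arc length.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    clean, _ = path.drop_zero_steps()
    seg = clean.step_lengths()
    cumlen = np.concatenate([[0.0], np.cumsum(seg)])
    total = cumlen[-1]
    if total < R:
        raise TooCoarseError(
            f"{path.id}: step {R} exceeds total path length {total:.6g}"
        )
    n_steps = int(np.floor(total / R + 1e-12))
    s = np.arange(n_steps + 1, dtype=float) * R
    s[-1] = min(s[-1], total)  # guard against fp overshoot on the last target
    x = np.interp(s, cumlen, clean.vertices[:, 0])
    y = np.interp(s, cumlen, clean.vertices[:, 1])
    t = np.interp(s, cumlen, clean.times)
    # interpolated times can collide when a pause (zero arc length, positive
    # time) sits exactly at a sample point; nudge to keep t strictly increasing
    dt = np.diff(t)
    if np.any(dt <= 0):
        eps = max(1e-9, 1e-9 * abs(t[-1]))
        t = np.maximum.accumulate(t + np.arange(len(t)) * eps)
    meta = dict(clean.meta)
    meta["rediscretized_at"] = R
    return TrajectoryPath(path.id, np.column_stack([x, y]), t, meta)
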