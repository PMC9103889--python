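"""Stability filter: keep probe poses that moved less than 3 Å over 500 ps.

A pose at time t is "stable" when the probe's heavy-atom centroid moved
strictly less than the cutoff from its position one lag earlier, with
minimum-image correction so a periodic wrap is not mistaken for a jump.
No verdict exists for the first lag window of a run; environments falling
there are dropped from the filtered set and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profile import ResidueEnvironment
from .trajectory import Trajectory

__all__ = [
    "StabilityVerdict",
    "displacement_series",
    "stable_mask",
    "filter_environments",
]

DEFAULT_LAG_PS = 500.0
DEFAULT_CUTOFF = 3.0


@dataclass(frozen=True)
class StabilityVerdict:
    probe_id: str
    time: float
    displacement: float
    stable: bool
    lag: float


def _lag_frames(traj: Trajectory, lag: float) -> int:
    ratio = lag / traj.timestep
    n = int(round(ratio))
    if n < 1 or abs(ratio - n) > 1e-9:
        raise ValueError(
            f"lag {lag} ps is not a positive integer multiple of the "
            f"timestep {traj.timestep} ps"
        )
    return n


def _min_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


def displacement_series(
    traj: Trajectory, probe_id: str, lag: float = DEFAULT_LAG_PS
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid displacement of one probe copy over a fixed time lag.

    Returns ``(times, displacements)``; the series starts ``lag`` ps after
    the first snapshot (earlier frames have no reference position).
    """
    n_lag = _lag_frames(traj, lag)
    centroids = []
    for snap in traj.snapshots:
        probe = traj.probe(snap, probe_id)
        if probe is None:
            raise KeyError(f"probe {probe_id!r} missing at t={snap.time} ps")
        centroids.append(probe.heavy_centroid())
    cents = np.array(centroids)
    if len(cents) <= n_lag:
        return np.empty(0), np.empty(0)
    box = traj.snapshots[0].box
    delta = _min_image(cents[n_lag:] - cents[:-n_lag], box)
    times = np.array([s.time for s in traj.snapshots[n_lag:]])
    return times, np.linalg.norm(delta, axis=1)


def stable_mask(
    traj: Trajectory,
    lag: float = DEFAULT_LAG_PS,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[StabilityVerdict]:
    """Verdicts for every (probe, time) with a defined displacement.

    Stability is strict at the boundary: displacement exactly equal to the
    cutoff is unstable.
    """
    verdicts: list[StabilityVerdict] = []
    for probe_id in traj.probe_ids():
        times, disps = displacement_series(traj, probe_id, lag)
        for t, d in zip(times, disps):
            verdicts.append(
                StabilityVerdict(
                    probe_id=probe_id,
                    time=float(t),
                    displacement=float(d),
                    stable=bool(d < cutoff),
                    lag=lag,
                )
            )
    return verdicts


def filter_environments(
    environments: list[ResidueEnvironment],
    verdicts: list[StabilityVerdict],
) -> tuple[list[ResidueEnvironment], float, int]:
    """Keep environments whose probe was stable at that time.

    Returns ``(kept, removed_fraction, n_undefined)``; ``n_undefined``
    counts environments from the initial lag window, which carry no verdict
    and are excluded from the filtered set.  ``removed_fraction`` is over
    the environments that had a verdict (0.0 when none did).
    """
    by_key = {(v.probe_id, v.time): v for v in verdicts}
    kept: list[ResidueEnvironment] = []
    n_undefined = 0
    n_judged = 0
    for env in environments:
        verdict = by_key.get((env.probe_id, env.time))
        if verdict is None:
            n_undefined += 1
            continue
        n_judged += 1
        if verdict.stable:
            kept.append(env)
    removed_fraction = 1.0 - len(kept) / n_judged if n_judged else 0.0
    return kept, removed_fraction, n_undefined
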