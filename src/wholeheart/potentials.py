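"""Node potential assignment and isochronal maps.

Every mesh node is assigned the same standard action-potential curve,
offset in time by the node's local activation time; blocked nodes stay at
the resting value.  The default template is a parametric piecewise-linear
monophasic curve (fast upstroke, plateau, linear repolarization);
arbitrary sampled templates can be loaded from CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .conduction import ActivationMap
from .errors import ConfigurationError

__all__ = [
    "ActionPotentialTemplate",
    "PotentialMovie",
    "IsochroneMap",
    "make_default_template",
    "load_template_csv",
    "assign_node_potentials",
    "compute_isochrones",
    "BLOCKED_BAND",
]

#: Reserved isochrone band index for blocked nodes.
BLOCKED_BAND = -1


@dataclass
class ActionPotentialTemplate:
    """Sampled action-potential curve at a fixed time step.

    ``samples[k]`` is the amplitude at time ``k * dt`` ms; the curve starts
    and ends at ``resting``.  Evaluation outside the sampled support
    returns the resting value; non-integer offsets are linearly
    interpolated.
    """

    samples: np.ndarray
    dt: float
    resting: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float).ravel()
        if self.dt <= 0:
            raise ConfigurationError("template dt must be > 0")
        if len(self.samples) < 2:
            raise ConfigurationError("template needs >= 2 samples")
        for end, name in ((self.samples[0], "start"), (self.samples[-1], "end")):
            if abs(end - self.resting) > 1e-9 * max(1.0, np.ptp(self.samples)):
                raise ConfigurationError(
                    f"template must {name} at the resting value")

    @property
    def duration(self) -> float:
        return (len(self.samples) - 1) * self.dt

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        return np.interp(t, np.arange(len(self.samples)) * self.dt,
                         self.samples, left=self.resting, right=self.resting)


@dataclass
class PotentialMovie:
    """Node x time-sample amplitude matrix.

    ``data[i, k]`` is the amplitude of node ``node_ids[i]`` (or node ``i``
    when ``node_ids`` is None) at time ``start + k * dt`` ms.
    """

    data: np.ndarray
    dt: float
    start: float = 0.0
    resting: float = 0.0
    node_ids: Optional[np.ndarray] = None

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.start + self.dt * np.arange(self.n_samples)

    def restricted_to(self, node_ids) -> "PotentialMovie":
        """Sub-movie over the given node ids (rows must cover them)."""
        node_ids = np.asarray(node_ids, np.int64)
        if self.node_ids is None:
            rows = node_ids
        else:
            pos = {int(n): i for i, n in enumerate(self.node_ids)}
            rows = np.array([pos[int(n)] for n in node_ids], np.int64)
        return PotentialMovie(self.data[rows], self.dt, self.start,
                              self.resting, node_ids)


@dataclass
class IsochroneMap:
    """Per-node activation-time band: band = floor(t / interval)."""

    bands: np.ndarray
    interval_ms: float
    palette: str = "rainbow"

    @property
    def n_bands(self) -> int:
        finite = self.bands[self.bands != BLOCKED_BAND]
        return int(finite.max()) + 1 if len(finite) else 0


def make_default_template(upstroke_ms: float = 1.0, plateau_ms: float = 200.0,
                          repol_ms: float = 100.0, resting: float = -90.0,
                          peak: float = 10.0,
                          dt: float = 1.0) -> ActionPotentialTemplate:
    """Piecewise-linear monophasic template: rest -> peak -> plateau -> rest.

    Defaults mimic a ventricular action potential: 1 ms upstroke, 200 ms
    plateau, 100 ms repolarization, -90 to +10 amplitude (mV-like units);
    total duration 301 ms.
    """
    for name, v in (("upstroke_ms", upstroke_ms), ("plateau_ms", plateau_ms),
                    ("repol_ms", repol_ms)):
        if v <= 0:
            raise ConfigurationError(f"{name} must be > 0")
    duration = upstroke_ms + plateau_ms + repol_ms
    t = np.arange(0.0, duration + dt / 2, dt)
    if t[-1] < duration:
        t = np.append(t, duration)
    knots_t = [0.0, upstroke_ms, upstroke_ms + plateau_ms, duration]
    knots_v = [resting, peak, peak, resting]
    samples = np.interp(t, knots_t, knots_v)
    samples[0] = resting
    samples[-1] = resting
    return ActionPotentialTemplate(samples, dt, resting)


def load_template_csv(path: str) -> ActionPotentialTemplate:
    """Load a sampled template from a ``time_ms, amplitude`` CSV."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    t = df.iloc[:, 0].to_numpy(float)
    v = df.iloc[:, 1].to_numpy(float)
    dts = np.diff(t)
    if len(dts) == 0 or np.ptp(dts) > 1e-9 * dts.mean():
        raise ConfigurationError("template CSV must be uniformly sampled")
    return ActionPotentialTemplate(v, float(dts.mean()), float(v[0]))


def assign_node_potentials(amap: ActivationMap, tpl: ActionPotentialTemplate,
                           duration_ms: Optional[float] = None,
                           dt: Optional[float] = None,
                           start_ms: float = 0.0) -> PotentialMovie:
    """Offset the template by each node's activation time.

    ``movie(node, t) = tpl(t - activation(node))``; the resting value holds
    outside the template's support and for blocked nodes throughout.  When
    ``duration_ms`` is shorter than (max activation + template duration), a
    warning is issued (repolarization is cut off).
    """
    dt = tpl.dt if dt is None else float(dt)
    needed = amap.finite_max() + tpl.duration
    if duration_ms is None:
        duration_ms = needed
    elif duration_ms < needed:
        warnings.warn(
            f"movie duration {duration_ms} ms clips the template "
            f"(needs {needed:.1f} ms)", stacklevel=2)
    n_samples = int(np.floor(duration_ms / dt)) + 1
    times = start_ms + dt * np.arange(n_samples)
    act = np.where(amap.blocked, np.inf, amap.times)
    offsets = times[None, :] - act[:, None]
    offsets = np.where(np.isfinite(offsets), offsets, -1.0)  # -> resting
    data = tpl(offsets)
    data[amap.blocked] = tpl.resting
    return PotentialMovie(data, dt, start_ms, tpl.resting)


def compute_isochrones(amap: ActivationMap,
                       interval_ms: float = 10.0) -> IsochroneMap:
    """Half-open activation-time bands: band k covers [k*I, (k+1)*I).

    Blocked nodes carry the reserved band ``BLOCKED_BAND`` (-1).
    """
    if interval_ms <= 0:
        raise ConfigurationError("isochrone interval must be > 0")
    bands = np.where(
        amap.blocked, BLOCKED_BAND,
        np.floor(np.where(amap.blocked, 0.0, amap.times)
                 / interval_ms).astype(np.int64))
    return IsochroneMap(bands.astype(np.int64), float(interval_ms))
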