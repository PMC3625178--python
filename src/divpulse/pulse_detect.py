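"""Mode detection in the pairwise-distance distribution and time calibration.

The sample of all pairwise model-corrected distances among retained taxa is
smoothed with a Gaussian kernel density estimate (bandwidth 0.9*min(sd,
IQR/1.34)*n^(-1/5), the classic rule-of-thumb default of R's ``density``).
Local maxima of the smoothed density are diversification events; the event
intervals are delimited by the inter-mode minima and the grid ends.  A
substitution rate (or a named-split age) converts distances to absolute time,
and internal tree nodes are mapped to the event whose interval contains their
age.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .distmodels import DistanceMatrix
from .errors import BandwidthError, CalibrationError, DistanceError, MappingError
from .treebuild import BranchingTimes


@dataclass
class DistanceSample:
    """The x_i feeding the KDE: pairwise distances (subst/site) or ages (Ma)."""

    values: np.ndarray
    scale: str = "distance"  # 'distance' or 'time'

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("pairwise distances/ages must be >= 0")
        if self.scale not in ("distance", "time"):
            raise ValueError("scale must be 'distance' or 'time'")

    @property
    def n(self) -> int:
        return self.values.size


def collect_pairwise_sample(dm: DistanceMatrix, exclude=()) -> DistanceSample:
    """Upper-triangle distances of the retained taxa (excluded taxa dropped)."""
    exclude = set(exclude)
    unknown = exclude - set(dm.taxon_ids)
    if unknown:
        raise KeyError(f"excluded taxa not in matrix: {sorted(unknown)}")
    keep = [t for t in dm.taxon_ids if t not in exclude]
    if len(keep) < 3:
        raise ValueError("need >= 3 retained taxa for a pairwise sample")
    sub = dm.submatrix(keep)
    iu = np.triu_indices(len(keep), k=1)
    vals = sub.d[iu]
    if np.isnan(vals).any():
        raise DistanceError("retained taxa include undefined (saturated) pairs")
    return DistanceSample(vals, scale="distance")


@dataclass
class DensityCurve:
    """A density estimate on a uniform grid (step delta)."""

    x: np.ndarray
    f: np.ndarray
    h: float
    n: int
    scale: str = "distance"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.x.size != self.f.size or self.x.size < 3:
            raise ValueError("x and f must be equal-length grids of >= 3 points")
        steps = np.diff(self.x)
        if (steps <= 0).any() or not np.allclose(steps, steps[0], rtol=1e-8):
            raise ValueError("grid must be uniform and strictly increasing")

    @property
    def delta(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.f, self.x))

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"x": self.x, "density": self.f}).to_csv(
            path, sep="\t", index=False
        )


def nrd0_bandwidth(values: np.ndarray) -> float:
    """Rule-of-thumb bandwidth 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    v = np.asarray(values, dtype=float)
    sd = float(np.std(v, ddof=1))
    q75, q25 = np.percentile(v, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * v.size ** (-0.2)


def gaussian_kde(
    s: DistanceSample,
    bandwidth="nrd0",
    grid_n: int = 512,
    cut: float = 3.0,
) -> DensityCurve:
    """Gaussian KDE f(x) = (1/(n h)) sum K((x - x_i)/h) on a uniform grid.

    The grid spans [min - cut*h, max + cut*h], truncated below zero for
    distance/time scales; the truncated curve is renormalised to unit mass
    over the grid.
    """
    v = s.values
    if v.size < 2:
        raise ValueError("KDE needs at least 2 observations")
    if bandwidth == "nrd0":
        h = nrd0_bandwidth(v)
        if not h > 0:
            raise BandwidthError(
                "automatic bandwidth is 0 (degenerate sample); pass an explicit h"
            )
    else:
        h = float(bandwidth)
        if not h > 0:
            raise BandwidthError("bandwidth must be > 0")
    lo = v.min() - cut * h
    hi = v.max() + cut * h
    if s.scale in ("distance", "time"):
        lo = max(lo, 0.0)
    if hi <= lo:
        hi = lo + h
    x = np.linspace(lo, hi, grid_n)
    z = (x[:, None] - v[None, :]) / h
    f = np.exp(-0.5 * z * z).sum(axis=1) / (v.size * h * np.sqrt(2.0 * np.pi))
    mass = np.trapezoid(f, x)
    if mass <= 0:
        raise BandwidthError("density mass on the grid is zero; widen the bandwidth")
    return DensityCurve(x=x, f=f / mass, h=h, n=v.size, scale=s.scale)


@dataclass
class Event:
    peak: float
    lower: float
    upper: float
    peak_density: float


@dataclass
class EventSet:
    """Detected modes, ordered by descending peak coordinate (oldest first);
    intervals tile the grid range, sharing boundaries at inter-mode minima."""

    events: list[Event]
    scale: str
    delta: float
    bandwidth: float

    def __len__(self) -> int:
        return len(self.events)

    @property
    def peaks(self) -> np.ndarray:
        return np.array([e.peak for e in self.events])

    def to_json_dict(self) -> dict:
        return {
            "scale": self.scale,
            "delta": self.delta,
            "bandwidth": self.bandwidth,
            "events": [
                {
                    "peak": e.peak,
                    "interval": [e.lower, e.upper],
                    "peak_density": e.peak_density,
                }
                for e in self.events
            ],
        }


def _runs(f: np.ndarray):
    """Runs of equal consecutive values: list of (start, end) inclusive."""
    out = []
    start = 0
    for i in range(1, f.size):
        if f[i] != f[start]:
            out.append((start, i - 1))
            start = i
    out.append((start, f.size - 1))
    return out


def find_modes(curve: DensityCurve) -> EventSet:
    """Detect modes by the sign of the finite differences.

    An interior grid point x is a mode iff f(x) - f(x - delta) > 0 and
    f(x) - f(x + delta) > 0; plateaus collapse to their midpoint.  Grid
    endpoints count as modes when the curve falls away from them (a monotone
    tail would otherwise hide a boundary peak).
    """
    f = curve.f
    runs = _runs(f)
    mode_idx: list[int] = []
    for r, (a, b) in enumerate(runs):
        left_up = r == 0 or f[runs[r - 1][1]] < f[a]
        right_down = r == len(runs) - 1 or f[runs[r + 1][0]] < f[a]
        if left_up and right_down:
            mode_idx.append((a + b) // 2)
    # interval boundaries: minima between consecutive modes
    boundaries: list[float] = []
    for m1, m2 in zip(mode_idx[:-1], mode_idx[1:]):
        seg = f[m1 : m2 + 1]
        lo = seg.min()
        where = np.nonzero(seg == lo)[0]
        boundaries.append(float(curve.x[m1 + (where[0] + where[-1]) // 2]))
    events = []
    for k, m in enumerate(mode_idx):
        lower = boundaries[k - 1] if k > 0 else float(curve.x[0])
        upper = boundaries[k] if k < len(boundaries) else float(curve.x[-1])
        events.append(
            Event(peak=float(curve.x[m]), lower=lower, upper=upper, peak_density=float(f[m]))
        )
    events.sort(key=lambda e: -e.peak)
    for e in events:  # after the descending sort, re-orient intervals
        e.lower, e.upper = min(e.lower, e.upper), max(e.lower, e.upper)
    return EventSet(
        events=events, scale=curve.scale, delta=curve.delta, bandwidth=curve.h
    )


@dataclass
class CalibrationConfig:
    """Distance-to-time calibration.

    Exactly one of ``rate`` (substitutions/site/Ma) or a named split
    (``split_taxa`` on one side, ``split_age`` in Ma) must be given.
    ``pairwise_divisor`` is 2 when a pairwise distance accrues along two
    lineages (so pairwise time = MRCA age), 1 for the raw d/r convention.
    """

    rate: float | None = None
    split_taxa: tuple[str, ...] | None = None
    split_age: float | None = None
    pairwise_divisor: int = 2

    def __post_init__(self) -> None:
        has_rate = self.rate is not None
        has_split = self.split_taxa is not None or self.split_age is not None
        if has_rate == has_split:
            raise CalibrationError(
                "give exactly one of a substitution rate or a named-split calibration"
            )
        if has_rate and not self.rate > 0:
            raise CalibrationError("rate must be > 0")
        if has_split and (not self.split_taxa or not self.split_age or self.split_age <= 0):
            raise CalibrationError("named-split calibration needs taxa and an age > 0")
        if self.pairwise_divisor not in (1, 2):
            raise CalibrationError("pairwise_divisor must be 1 or 2")

    def resolve_rate(self, dm: DistanceMatrix | None = None, tree=None) -> float:
        """The substitution rate, solving the named split against ``dm`` if needed."""
        if self.rate is not None:
            return self.rate
        if dm is None:
            raise CalibrationError("named-split calibration needs a distance matrix")
        side_a = [t for t in dm.taxon_ids if t in set(self.split_taxa)]
        side_b = [t for t in dm.taxon_ids if t not in set(self.split_taxa)]
        if not side_a or not side_b:
            raise CalibrationError(
                "named-split bipartition is absent from the distance matrix"
            )
        if tree is not None:
            from .treebuild import _leafset_masks

            masks, order = _leafset_masks(tree)
            want = 0
            for t in side_a:
                want |= 1 << order[t]
            full = masks[tree.seed_node]
            if not any(m in (want, full ^ want) for m in masks.values()):
                raise CalibrationError("named split is not a bipartition of the tree")
        ia = [dm.taxon_ids.index(t) for t in side_a]
        ib = [dm.taxon_ids.index(t) for t in side_b]
        cross = dm.d[np.ix_(ia, ib)]
        if np.isnan(cross).any():
            raise CalibrationError("named split spans undefined distance entries")
        return float(cross.mean()) / (self.pairwise_divisor * self.split_age)


def calibrate(obj, cal: CalibrationConfig, dm: DistanceMatrix | None = None, tree=None):
    """Convert a DistanceSample or DensityCurve from distance to time scale:
    time = distance / (pairwise_divisor * rate)."""
    r = cal.resolve_rate(dm=dm, tree=tree)
    c = cal.pairwise_divisor * r
    if isinstance(obj, DistanceSample):
        return DistanceSample(obj.values / c, scale="time")
    if isinstance(obj, DensityCurve):
        return DensityCurve(obj.x / c, obj.f * c, h=obj.h / c, n=obj.n, scale="time")
    raise TypeError(f"cannot calibrate object of type {type(obj).__name__}")


@dataclass
class NodeEventMap:
    """Assignment of internal-node ages to detected events."""

    assignments: list[dict]  # {age, events: [idx...], shared: bool}
    event_counts: list[int]
    shared_counts: list[int]  # between adjacent event pairs (older, younger)
    n_unassigned: int

    def to_json_dict(self) -> dict:
        return {
            "event_node_counts": self.event_counts,
            "shared_node_counts": self.shared_counts,
            "n_unassigned": self.n_unassigned,
            "assignments": self.assignments,
        }


def map_nodes_to_events(
    bt: BranchingTimes, ev: EventSet, delta: float | None = None
) -> NodeEventMap:
    """Assign each internal node to the event whose interval contains its age.

    Nodes within ``delta`` of a boundary shared by two adjacent events are
    assigned to both with the shared flag; ``delta`` defaults to the KDE
    bandwidth (already on the time scale for a calibrated event set).
    """
    if len(ev) == 0:
        raise MappingError("empty event set")
    if delta is None:
        delta = ev.bandwidth
    # internal boundaries in descending-event order: boundary k separates
    # event k (older) from event k+1 (younger)
    inner = [ev.events[k].lower for k in range(len(ev) - 1)]
    assignments = []
    counts = [0] * len(ev)
    shared_counts = [0] * max(len(ev) - 1, 0)
    n_unassigned = 0
    for age in bt.ages:
        hit = [
            k
            for k, e in enumerate(ev.events)
            if e.lower <= age <= e.upper
        ]
        shared = False
        for k, b in enumerate(inner):
            if abs(age - b) <= delta:
                hit = [k, k + 1]
                shared = True
                shared_counts[k] += 1
                break
        if not hit:
            n_unassigned += 1
            assignments.append({"age": float(age), "events": [], "shared": False})
            continue
        if not shared:
            hit = hit[:1]  # deterministic: oldest containing event
        for k in hit:
            counts[k] += 1
        assignments.append({"age": float(age), "events": hit, "shared": shared})
    return NodeEventMap(
        assignments=assignments,
        event_counts=counts,
        shared_counts=shared_counts,
        n_unassigned=n_unassigned,
    )
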