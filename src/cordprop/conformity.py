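"""Slice-by-slice contour agreement metrics and their aggregation.

Two structure sets on the same grid are compared plane by plane with
five metrics:

* CI — conformity index, the Jaccard ratio area(a∩b)/area(a∪b);
* DBC — in-plane Euclidean distance between area centroids;
* DTC — distance to conformity: the mean, over the rasterised symmetric
  difference of the two regions, of the distance to the nearest point
  of their intersection;
* left–right and anterior–posterior dimension differences — signed
  differences of axis-aligned extents (test minus reference), with
  +x = patient left and +y = patient posterior.

Areas and centroids use exact polygon clipping (shapely); only the DTC
distances are rasterised, at 0.1 mm pitch.  Multiple polygons on one
slice are treated as their union.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .image_io import StructureSet

__all__ = [
    "SliceConformity",
    "MetricStats",
    "ConformitySummary",
    "ComparisonResult",
    "conformity_index",
    "distance_between_centres",
    "distance_to_conformity",
    "dimension_differences",
    "compare_structure_sets",
    "aggregate",
    "interobserver_analysis",
    "boxplot_stats",
]

METRICS = ("ci", "dtc", "dbc", "lr_diff", "ap_diff")
DTC_RASTER_MM = 0.1


def _as_region(geom):
    """Normalise input (polygon-vertex array, list of arrays, shapely) to a region."""
    if isinstance(geom, (Polygon,)) or hasattr(geom, "geom_type"):
        region = geom
    elif isinstance(geom, np.ndarray):
        region = Polygon(geom)
    else:
        polys = [p if hasattr(p, "geom_type") else Polygon(np.asarray(p)) for p in geom]
        region = unary_union([p if p.is_valid else p.buffer(0) for p in polys])
    if not region.is_valid:
        region = region.buffer(0)
    if region.is_empty or region.area == 0:
        raise ValueError("empty region on slice")
    return region


def conformity_index(a, b) -> float:
    """Jaccard ratio of two slice regions, 1.0 iff identical."""
    ra, rb = _as_region(a), _as_region(b)
    union = ra.union(rb).area
    return ra.intersection(rb).area / union if union > 0 else 0.0


def distance_between_centres(a, b) -> float:
    """In-plane Euclidean distance between area centroids (mm)."""
    ca, cb = _as_region(a).centroid, _as_region(b).centroid
    return float(np.hypot(ca.x - cb.x, ca.y - cb.y))


def dimension_differences(a, b) -> tuple[float, float]:
    """Signed bounding-box extent differences (test minus reference), mm.

    Returns (left–right difference, anterior–posterior difference),
    i.e. differences of x- and y-extents in the DICOM patient frame.
    """
    ba, bb = _as_region(a).bounds, _as_region(b).bounds
    lr = (ba[2] - ba[0]) - (bb[2] - bb[0])
    ap = (ba[3] - ba[1]) - (bb[3] - bb[1])
    return float(lr), float(ap)


def _raster_masks(ra, rb, pitch):
    minx = min(ra.bounds[0], rb.bounds[0]) - 2 * pitch
    miny = min(ra.bounds[1], rb.bounds[1]) - 2 * pitch
    maxx = max(ra.bounds[2], rb.bounds[2]) + 2 * pitch
    maxy = max(ra.bounds[3], rb.bounds[3]) + 2 * pitch
    xs = np.arange(minx + pitch / 2, maxx, pitch)
    ys = np.arange(miny + pitch / 2, maxy, pitch)
    gx, gy = np.meshgrid(xs, ys)
    in_a = shapely.intersects_xy(ra, gx.ravel(), gy.ravel()).reshape(gx.shape)
    in_b = shapely.intersects_xy(rb, gx.ravel(), gy.ravel()).reshape(gx.shape)
    return in_a, in_b


def distance_to_conformity(a, b, pitch: float = DTC_RASTER_MM) -> float:
    """Mean distance (mm) from the disagreement region to the agreement region.

    The two regions are rasterised at ``pitch``; over pixels of the
    symmetric difference, the Euclidean distance to the nearest pixel of
    the intersection is averaged.  Identical regions give 0.  If the
    intersection is empty the distance is taken to the other region
    instead (each disputed pixel to the nearest pixel of the region it
    does not belong to).
    """
    ra, rb = _as_region(a), _as_region(b)
    if ra.equals(rb):
        return 0.0
    in_a, in_b = _raster_masks(ra, rb, pitch)
    inter = in_a & in_b
    sym = (in_a | in_b) & ~inter
    if not sym.any():
        return 0.0
    if inter.any():
        dist = ndimage.distance_transform_edt(~inter) * pitch
        return float(dist[sym].mean())
    # disjoint regions: distance from each region's pixels to the other region
    dist_to_b = ndimage.distance_transform_edt(~in_b) * pitch
    dist_to_a = ndimage.distance_transform_edt(~in_a) * pitch
    vals = np.concatenate([dist_to_b[in_a], dist_to_a[in_b]])
    return float(vals.mean())


# ---------------------------------------------------------------------------
# Slice-wise comparison
# ---------------------------------------------------------------------------

@dataclass
class SliceConformity:
    """All five agreement metrics for one matched slice pair."""

    z: float
    ci: float
    dtc: float
    dbc: float
    lr_diff: float
    ap_diff: float
    dtc_flagged: bool = False  # true when the slice intersection was empty


@dataclass
class ComparisonResult:
    """Matched-slice records plus bookkeeping of unmatched slices."""

    records: list[SliceConformity]
    unmatched_test: list[float] = field(default_factory=list)
    unmatched_reference: list[float] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def compare_structure_sets(
    test: StructureSet,
    reference: StructureSet,
    slice_tolerance: float | None = None,
) -> ComparisonResult:
    """Compare two structure sets slice by slice.

    Slices are matched when their z planes agree within
    ``slice_tolerance`` (default: half the smallest reference slice
    gap).  Slices present on only one side are listed as unmatched, not
    scored.

    Raises
    ------
    ValueError
        If no slice pair matches.
    """
    t_slices, r_slices = test.slices(), reference.slices()
    r_zs = np.array(sorted(r_slices))
    if slice_tolerance is None:
        gaps = np.diff(r_zs)
        slice_tolerance = float(gaps[gaps > 1e-6].min()) / 2 if len(gaps) else 1.5

    records = []
    matched_r: set[float] = set()
    unmatched_t = []
    for zt in sorted(t_slices):
        j = int(np.argmin(np.abs(r_zs - zt)))
        zr = float(r_zs[j])
        if abs(zr - zt) <= slice_tolerance and zr not in matched_r:
            a = [c.points for c in t_slices[zt]]
            b = [c.points for c in r_slices[zr]]
            ra, rb = _as_region(a), _as_region(b)
            lr, ap = dimension_differences(ra, rb)
            records.append(
                SliceConformity(
                    z=zt,
                    ci=conformity_index(ra, rb),
                    dtc=distance_to_conformity(ra, rb),
                    dbc=distance_between_centres(ra, rb),
                    lr_diff=lr,
                    ap_diff=ap,
                    dtc_flagged=not ra.intersects(rb),
                )
            )
            matched_r.add(zr)
        else:
            unmatched_t.append(zt)
    unmatched_r = [z for z in r_slices if z not in matched_r]
    if not records:
        raise ValueError("no matched slices between test and reference structure sets")
    return ComparisonResult(records, unmatched_t, unmatched_r)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class MetricStats:
    median: float
    mean: float
    sd: float | None
    se_mean: float | None
    se_median: float | None


@dataclass
class ConformitySummary:
    """Per-metric summary statistics with statistical uncertainties.

    ``se_mean`` is SD/sqrt(n); ``se_median`` is a seeded-bootstrap
    standard error of the median.  With a single record the SD and both
    uncertainties are reported as None.
    """

    stats: dict[str, MetricStats]
    n_slices: int
    n_scans: int = 1

    def __getitem__(self, metric: str) -> MetricStats:
        return self.stats[metric]


def aggregate(
    records: list[SliceConformity],
    n_scans: int = 1,
    bootstrap: int = 2000,
    seed: int = 0,
) -> ConformitySummary:
    """Aggregate slice records into medians/means/SDs with uncertainties."""
    records = list(records)
    if not records:
        raise ValueError("no records to aggregate")
    rng = np.random.default_rng(seed)
    n = len(records)
    stats = {}
    for metric in METRICS:
        vals = np.array([getattr(r, metric) for r in records], dtype=float)
        med, mean = float(np.median(vals)), float(vals.mean())
        if n > 1:
            sd = float(vals.std(ddof=1))
            se_mean = sd / np.sqrt(n)
            boots = np.median(
                vals[rng.integers(0, n, size=(bootstrap, n))], axis=1
            )
            se_median = float(boots.std(ddof=1))
        else:
            sd = se_mean = se_median = None
        stats[metric] = MetricStats(med, mean, sd, se_mean, se_median)
    return ConformitySummary(stats, n_slices=n, n_scans=n_scans)


def boxplot_stats(values) -> dict[str, float]:
    """Mean, median, quartiles and extremes of a value set."""
    vals = np.asarray(list(values), dtype=float)
    return {
        "mean": float(vals.mean()),
        "median": float(np.median(vals)),
        "q1": float(np.percentile(vals, 25)),
        "q3": float(np.percentile(vals, 75)),
        "min": float(vals.min()),
        "max": float(vals.max()),
    }


# ---------------------------------------------------------------------------
# Inter-observer analysis
# ---------------------------------------------------------------------------

@dataclass
class InterobserverResult:
    """All-pairs comparison of observers contouring the same scans.

    ``pair_means`` holds, for each unordered observer pair (i < j), the
    mean of each metric over matched slices with observer i as test and
    j as reference (symmetric metrics are orientation-free; signed ones
    flip sign for the reversed orientation).  ``per_observer`` averages
    each observer's N-1 comparisons, oriented with that observer as
    test.  ``mean_of_pairs`` is the plain average of the pairwise
    values — 15 of them for six observers.
    """

    n_observers: int
    pair_means: dict[tuple[int, int], dict[str, float]]
    per_observer: list[dict[str, float]]
    mean_of_pairs: dict[str, float]
    excluded: list[int] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_means)


_SIGNED = {"lr_diff", "ap_diff"}


def interobserver_analysis(contour_sets: list[StructureSet]) -> InterobserverResult:
    """Compare every observer with every other on a common frame.

    Raises
    ------
    ValueError
        If fewer than two observers remain after excluding any with no
        overlapping slices.
    """
    n = len(contour_sets)
    if n < 2:
        raise ValueError("need at least two observers")
    pair_means: dict[tuple[int, int], dict[str, float]] = {}
    excluded: set[int] = set()
    for i, j in itertools.combinations(range(n), 2):
        try:
            result = compare_structure_sets(contour_sets[i], contour_sets[j])
        except ValueError:
            excluded.update((i, j))
            continue
        pair_means[(i, j)] = {
            m: float(np.mean([getattr(r, m) for r in result.records])) for m in METRICS
        }
    # an observer is excluded only if it matched no one at all
    matched = {k for pair in pair_means for k in pair}
    excluded -= matched
    if len(matched) < 2:
        raise ValueError("fewer than two observers share overlapping slices")

    per_observer = []
    for o in range(n):
        vals: dict[str, list[float]] = {m: [] for m in METRICS}
        for (i, j), means in pair_means.items():
            if o == i:
                for m in METRICS:
                    vals[m].append(means[m])
            elif o == j:
                for m in METRICS:
                    vals[m].append(-means[m] if m in _SIGNED else means[m])
        per_observer.append(
            {m: (float(np.mean(v)) if v else float("nan")) for m, v in vals.items()}
        )
    mean_of_pairs = {
        m: float(np.mean([pm[m] for pm in pair_means.values()])) for m in METRICS
    }
    return InterobserverResult(
        n_observers=n,
        pair_means=pair_means,
        per_observer=per_observer,
        mean_of_pairs=mean_of_pairs,
        excluded=sorted(excluded),
    )
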