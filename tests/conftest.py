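"""Shared fixtures: random shape generators, independent oracles,
and a small session-wide synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest
from matplotlib.path import Path as MplPath
from shapely.geometry import MultiPolygon, Polygon

from lgequant import SynthSpec, generate_cohort, load_cohort


# ---------------------------------------------------------------------------
# random shape generators (simple by construction)


def star_polygon(rng, center=(8.0, 8.0), r_mean=5.0, n_vertices=12, irregularity=0.5):
    """Star-convex polygon with random radii: simple, never self-intersecting."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = r_mean * (1.0 + irregularity * (rng.uniform(size=n_vertices) - 0.5))
    pts = [
        (center[0] + r * np.cos(a), center[1] + r * np.sin(a))
        for a, r in zip(angles, radii)
    ]
    poly = Polygon(pts)
    assert poly.is_valid
    return poly


def holed_polygon(rng, center=(8.0, 8.0), r_mean=6.0):
    """Star polygon with a scaled-down copy of itself as a hole."""
    outer = star_polygon(rng, center, r_mean, n_vertices=14, irregularity=0.4)
    inner_coords = [
        (center[0] + 0.45 * (x - center[0]), center[1] + 0.45 * (y - center[1]))
        for x, y in outer.exterior.coords
    ]
    poly = Polygon(outer.exterior.coords, [inner_coords[::-1]])
    assert poly.is_valid
    return poly


def convex_polygon(rng, center=(8.0, 8.0), r=4.0, n_vertices=10):
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    pts = [(center[0] + r * np.cos(a), center[1] + r * np.sin(a)) for a in angles]
    return Polygon(pts)


# ---------------------------------------------------------------------------
# independent oracles


def shoelace_area(polygon) -> float:
    """Signed-area shoelace sum over exterior minus holes (no shapely)."""

    def ring_area(coords):
        xy = np.asarray(coords, dtype=float)
        x, y = xy[:, 0], xy[:, 1]
        return 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))

    polys = polygon.geoms if isinstance(polygon, MultiPolygon) else [polygon]
    total = 0.0
    for p in polys:
        total += ring_area(p.exterior.coords)
        for hole in p.interiors:
            total -= ring_area(hole.coords)
    return total


def _point_in_polygon(polygon, pts: np.ndarray) -> np.ndarray:
    """Point-in-(multi)polygon via matplotlib ray casting, per ring:
    inside the exterior and outside every hole."""
    polys = polygon.geoms if isinstance(polygon, MultiPolygon) else [polygon]
    out = np.zeros(len(pts), dtype=bool)
    for p in polys:
        hit = MplPath(np.asarray(p.exterior.coords)).contains_points(pts)
        for hole in p.interiors:
            hit &= ~MplPath(np.asarray(hole.coords)).contains_points(pts)
        out |= hit
    return out


def _stratified_offsets(k: int) -> np.ndarray:
    """k*k stratified antithetic sample offsets inside a unit pixel.

    One jittered point plus its within-subcell mirror per subcell: a
    plain k*k midpoint grid aliases on edges whose slope is a small
    rational (error up to 1/(2k) per pixel), while the antithetic
    stratified estimate stays well inside the comparison tolerance for
    any edge direction.  Jitter is fixed, so the oracle is deterministic.
    """
    jr = np.random.default_rng(12345)
    base = np.indices((k, k)).reshape(2, -1).T[:, ::-1] / k
    jit = jr.uniform(0.0, 1.0 / k, size=(k * k, 2))
    return np.vstack([base + jit, base + (1.0 / k - jit)]) - 0.5


def supersample_weights(polygon, bounds, k: int = 64) -> np.ndarray:
    """Per-pixel coverage fractions by k×k stratified sub-sampling.

    Independent of the analytic clipping implementation: pure
    point-in-polygon counting on a dense deterministic sample.
    """
    r0, r1, c0, c1 = bounds
    nr, nc = r1 - r0 + 1, c1 - c0 + 1
    offs = _stratified_offsets(k)
    out = np.zeros((nr, nc))
    for i in range(nr):
        centers = np.column_stack(
            [np.arange(c0, c1 + 1, dtype=float), np.full(nc, float(r0 + i))]
        )
        pts = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 2)
        inside = _point_in_polygon(polygon, pts)
        out[i] = inside.reshape(nc, len(offs)).mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# session cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """2-case (one with artifacts), 3-slice synthetic cohort on disk."""
    out = tmp_path_factory.mktemp("cohort")
    spec = SynthSpec(slices_per_case=3)
    generate_cohort(spec, n_cases=2, artifact_fraction=0.5, seed=7, out_dir=out)
    cohort, cases = load_cohort(out)
    return {"dir": out, "cohort": cohort, "cases": cases, "spec": spec}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
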