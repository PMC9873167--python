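"""Ternary coordinates, confidence regions and delimited table output.

A three-part composition maps to barycentric coordinates in an equilateral
triangle with vertex order PA - SB - sleep: PA at the origin, SB at (1, 0),
sleep at (1/2, sqrt(3)/2).  The 95% confidence boundary of a compositional
mean is a normal-approximation ellipse fitted to bootstrap replicate means
in ilr space, discretised, back-transformed, and mapped to ternary
coordinates (a convex hull over the replicates is available as an
alternative construction).

All table output is deterministic: fixed column order, fixed precision,
UTF-8 comma-separated text with a header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull

from .coda_core import DEFAULT_BASIS, IlrBasis, ilr, ilr_inverse
from .errors import InvalidCompositionError, UsageError

logger = logging.getLogger(__name__)

SQRT3_2 = np.sqrt(3.0) / 2.0


def ternary_coords(comp) -> np.ndarray:
    """Barycentric plot coordinates of one or many (pa, sb, sleep) compositions.

    ``x = p_sb + p_sleep / 2``, ``y = sqrt(3)/2 * p_sleep`` on proportions;
    vertices map to the triangle corners.
    """
    arr = np.asarray(comp, dtype=float)
    if np.any(arr < 0) or np.any(arr.sum(axis=-1) <= 0):
        raise InvalidCompositionError("ternary coordinates need non-negative parts with positive sum")
    p = arr / arr.sum(axis=-1, keepdims=True)
    x = p[..., 1] + p[..., 2] / 2.0
    y = SQRT3_2 * p[..., 2]
    return np.stack([x, y], axis=-1)


def ternary_to_proportions(xy) -> np.ndarray:
    """Inverse of :func:`ternary_coords` (returns proportions summing to 1)."""
    arr = np.asarray(xy, dtype=float)
    p_sleep = arr[..., 1] / SQRT3_2
    p_sb = arr[..., 0] - p_sleep / 2.0
    p_pa = 1.0 - p_sb - p_sleep
    return np.stack([p_pa, p_sb, p_sleep], axis=-1)


@dataclass(frozen=True)
class ConfidenceRegion:
    """Closed confidence boundary for a compositional mean."""

    compositions: np.ndarray  # (n_points, 3), closed to the total
    ternary: np.ndarray       # (n_points, 2)
    method: str
    degenerate: bool = False


def mean_confidence_region(
    replicate_means,
    basis: IlrBasis = DEFAULT_BASIS,
    level: float = 0.95,
    n_points: int = 200,
    method: str = "ellipse",
    total: float = 24.0,
) -> ConfidenceRegion:
    """Confidence boundary from bootstrap replicate mean compositions.

    ``method='ellipse'`` (default): normal-approximation ellipse in ilr
    space at the given level; ``method='hull'``: convex hull of the
    replicate cloud.  Zero-variance replicates yield a degenerate point
    region with a logged notice.
    """
    reps = np.atleast_2d(np.asarray(replicate_means, dtype=float))
    if reps.shape[0] < 50:
        raise UsageError(f"need >= 50 replicate means, got {reps.shape[0]}")
    if n_points < 100:
        raise UsageError("n_points must be >= 100 for a usable boundary")
    z = ilr(reps, basis)
    centre = z.mean(axis=0)
    cov = np.cov(z, rowvar=False)

    if np.trace(cov) < 1e-14:
        logger.info("replicate means are degenerate; returning a point region")
        pts = np.tile(centre, (n_points, 1))
        comps = ilr_inverse(pts, basis, total)
        return ConfidenceRegion(comps, ternary_coords(comps), method, degenerate=True)

    if method == "ellipse":
        evals, evecs = np.linalg.eigh(cov)
        evals = np.clip(evals, 0.0, None)
        radius = np.sqrt(stats.chi2.ppf(level, df=2))
        t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=True)
        circle = np.stack([np.cos(t), np.sin(t)], axis=1)
        pts = centre + radius * circle @ np.diag(np.sqrt(evals)) @ evecs.T
    elif method == "hull":
        hull = ConvexHull(z)
        cycle = np.append(hull.vertices, hull.vertices[0])
        pts = z[cycle]
    else:
        raise UsageError(f"unknown confidence-region method {method!r}")
    comps = ilr_inverse(pts, basis, total)
    return ConfidenceRegion(comps, ternary_coords(comps), method)


# --------------------------------------------------------------------- #
# delimited table output


def _round_numeric(df: pd.DataFrame, precision: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(precision)
    return out


def render_ls_means(ls_means: pd.DataFrame, path=None, precision: int = 2) -> pd.DataFrame:
    """Adjusted-means table (one row per variable/category/wave), rounded.

    Compositions are reported to ``precision`` decimals of an hour (default
    0.01 h).  Writes CSV when ``path`` is given; empty input yields a
    header-only file with a logged warning.
    """
    cols = ["variable", "category", "wave", "n", "pct", "pa_h", "sb_h", "sleep_h"]
    cols += [c for c in ls_means.columns if c.endswith(("_ci_low", "_ci_high"))]
    if ls_means.empty:
        logger.warning("no adjusted means to render")
        out = pd.DataFrame(columns=cols)
    else:
        out = _round_numeric(ls_means[[c for c in cols if c in ls_means.columns]], precision)
    if path is not None:
        out.to_csv(path, index=False)
    return out


def render_changes(changes: pd.DataFrame, path=None, precision: int = 2) -> pd.DataFrame:
    """Between-wave change table (min/day, default 0.01 min precision)."""
    if changes.empty:
        logger.warning("no change estimates to render")
        out = changes.copy()
    else:
        out = _round_numeric(changes, precision)
    if path is not None:
        out.to_csv(path, index=False)
    return out


def render_means(means: pd.DataFrame, path=None, precision: int = 2) -> pd.DataFrame:
    """Whole-sample compositional means per wave, rounded."""
    out = _round_numeric(means, precision)
    if path is not None:
        out.to_csv(path, index=False)
    return out


def render_ternary_points(compositions: pd.DataFrame, path=None) -> pd.DataFrame:
    """Ternary plot coordinates for a table with pa_h/sb_h/sleep_h columns."""
    xy = ternary_coords(compositions[["pa_h", "sb_h", "sleep_h"]].to_numpy())
    out = compositions.copy()
    out["ternary_x"] = xy[..., 0]
    out["ternary_y"] = xy[..., 1]
    if path is not None:
        out.to_csv(path, index=False)
    return out
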