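"""Aitchison-geometry primitives for the 24-hour time-use composition.

A day is described by the hours spent in physical activity (PA), sedentary
behaviour (SB) and sleep.  These three parts are strictly positive and sum to
24 h, so they live on the 2-simplex and carry only relative information.  All
statistics in this package are computed in isometric log-ratio (ilr)
coordinates — an orthonormal log-ratio map from the simplex to R^2 — and
back-transformed to hours for reporting.

The module provides:

* :func:`close` — rescale raw parts to a fixed total (closure);
* :class:`IlrBasis`, :func:`make_pivot_basis`, :func:`rotated_basis`,
  :func:`random_basis` — orthonormal contrast matrices; every reported
  quantity downstream is invariant to the basis choice;
* :func:`ilr` / :func:`ilr_inverse` — the coordinate map and its inverse;
* :func:`compositional_mean` — closed weighted geometric means, the centre of
  a compositional sample;
* :func:`variation_matrix` — pairwise log-ratio variances and the total
  variance summarising compositional dispersion.

Functions accept single compositions or stacked arrays of shape ``(n, 3)``.
Zeros are never imputed here: strict positivity is an input contract, and
zero-part days are excluded upstream (see :mod:`timeuse_coda.diary`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, EstimationError, InvalidCompositionError, UsageError

PART_LABELS: tuple[str, str, str] = ("pa", "sb", "sleep")
PART_COLUMNS: tuple[str, str, str] = ("pa_h", "sb_h", "sleep_h")
DAY_HOURS: float = 24.0

_ORTHO_TOL = 1e-10


def close(parts, total: float = DAY_HOURS) -> np.ndarray:
    """Rescale non-negative parts proportionally so they sum to ``total``.

    The last part is set by subtraction so the sum is exact in floating
    point.  Zeros pass through (strict positivity is enforced downstream by
    exclusion, not here); an all-zero vector is invalid.
    """
    arr = np.asarray(parts, dtype=float)
    if arr.shape[-1] < 2:
        raise InvalidCompositionError("a composition needs at least two parts")
    if np.any(arr < 0):
        raise InvalidCompositionError("parts must be non-negative")
    s = arr.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise InvalidCompositionError("all parts are zero: no composition can be formed")
    if total <= 0:
        raise InvalidCompositionError(f"total must be positive, got {total}")
    out = arr * (total / s)
    out[..., -1] = total - out[..., :-1].sum(axis=-1)
    return out


@dataclass(frozen=True)
class IlrBasis:
    """Orthonormal log-ratio contrast defining ilr coordinates.

    ``matrix`` has one row per part (in :data:`PART_LABELS` order) and one
    column per coordinate; columns are unit-norm, mutually orthogonal and sum
    to zero, so ``z = ln(x) @ matrix`` equals the projection of the centred
    log-ratio vector onto the contrast.
    """

    matrix: np.ndarray
    name: str = "custom"
    partition: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...] | None = None
    labels: tuple[str, ...] = PART_LABELS

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels) - 1):
            raise ConfigurationError(
                f"contrast matrix must be {len(self.labels)}x{len(self.labels) - 1}, got {m.shape}"
            )
        if not np.allclose(m.T @ m, np.eye(m.shape[1]), atol=1e-8):
            raise ConfigurationError("contrast columns must be orthonormal")
        if not np.allclose(m.sum(axis=0), 0.0, atol=1e-8):
            raise ConfigurationError("contrast columns must sum to zero")
        object.__setattr__(self, "matrix", m)

    @property
    def n_coordinates(self) -> int:
        return self.matrix.shape[1]


def make_pivot_basis(part_order: tuple[str, ...] = PART_LABELS) -> IlrBasis:
    """Pivot-coordinate ilr basis for a sequential binary partition.

    For order ``(x1, x2, x3)`` the coordinates are
    ``z1 = sqrt(2/3) * ln(x1 / sqrt(x2*x3))`` and
    ``z2 = sqrt(1/2) * ln(x2 / x3)``.  ``part_order`` may be any permutation
    of :data:`PART_LABELS`; the contrast rows are returned in canonical
    (pa, sb, sleep) order so the basis applies directly to stored arrays.
    """
    if len(part_order) != 3 or len(set(part_order)) != 3:
        raise ConfigurationError(f"part_order must be 3 distinct labels, got {part_order!r}")
    if set(part_order) != set(PART_LABELS):
        raise ConfigurationError(f"unknown part labels in {part_order!r}; expected {PART_LABELS}")
    v_seq = np.array(
        [
            [np.sqrt(2.0 / 3.0), 0.0],
            [-np.sqrt(1.0 / 6.0), np.sqrt(0.5)],
            [-np.sqrt(1.0 / 6.0), -np.sqrt(0.5)],
        ]
    )
    v = np.zeros((3, 2))
    for seq_pos, label in enumerate(part_order):
        v[PART_LABELS.index(label)] = v_seq[seq_pos]
    partition = (
        ((part_order[0],), (part_order[1], part_order[2])),
        ((part_order[1],), (part_order[2],)),
    )
    return IlrBasis(matrix=v, name=f"pivot:{','.join(part_order)}", partition=partition)


def rotated_basis(basis: IlrBasis, angle: float, reflect: bool = False) -> IlrBasis:
    """Rotate (optionally reflect) a basis in coordinate space.

    Any valid 2-D ilr basis is an orthogonal rotation/reflection of any
    other, so this enumerates the full family for invariance checks.
    """
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    if reflect:
        rot = rot @ np.array([[1.0, 0.0], [0.0, -1.0]])
    return IlrBasis(matrix=basis.matrix @ rot, name=f"{basis.name}|rot{angle:.4f}{'r' if reflect else ''}")


def random_basis(rng: np.random.Generator) -> IlrBasis:
    """A random valid ilr basis (random rotation/reflection of the pivot)."""
    return rotated_basis(
        make_pivot_basis(), angle=float(rng.uniform(0.0, 2.0 * np.pi)), reflect=bool(rng.integers(2))
    )


DEFAULT_BASIS = make_pivot_basis()


def _check_positive(arr: np.ndarray, labels: tuple[str, ...] = PART_LABELS) -> None:
    if np.any(arr <= 0):
        bad = np.argwhere(np.atleast_2d(arr) <= 0)
        part = labels[bad[0][-1]]
        raise InvalidCompositionError(
            f"ilr requires strictly positive parts; part '{part}' is zero or negative"
        )


def ilr(comp, basis: IlrBasis = DEFAULT_BASIS) -> np.ndarray:
    """Isometric log-ratio coordinates of one or many compositions.

    Accepts shape ``(3,)`` or ``(n, 3)``; returns ``(2,)`` or ``(n, 2)``.
    The result does not depend on the closure total (log-ratios are
    scale-free).
    """
    arr = np.asarray(comp, dtype=float)
    _check_positive(arr, basis.labels)
    return np.log(arr) @ basis.matrix


def ilr_inverse(coords, basis: IlrBasis = DEFAULT_BASIS, total: float = DAY_HOURS) -> np.ndarray:
    """Map ilr coordinates back to a composition closed to ``total``."""
    z = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(z)):
        raise UsageError("ilr coordinates must be finite")
    return close(np.exp(z @ basis.matrix.T), total=total)


def _normalised_weights(n: int, weights) -> np.ndarray:
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise UsageError(f"weights must have shape ({n},), got {w.shape}")
        if np.any(w < 0):
            raise UsageError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise EstimationError("weights must not all be zero")
        w = w / total
    return w


def compositional_mean(data, weights=None, total: float = DAY_HOURS) -> np.ndarray:
    """Weighted compositional mean: closed per-part weighted geometric means.

    Equivalently (and exactly, a property the test-suite asserts) the
    inverse-ilr of the weighted arithmetic mean of the ilr coordinates under
    any valid basis.
    """
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    if arr.shape[0] == 0:
        raise EstimationError("cannot compute the compositional mean of an empty set")
    _check_positive(arr)
    w = _normalised_weights(arr.shape[0], weights)
    return close(np.exp(w @ np.log(arr)), total=total)


@dataclass(frozen=True)
class VariationMatrix:
    """Pairwise log-ratio variances t_ij = var(ln(x_i / x_j)).

    ``total_variance`` is the sum of the upper-triangle entries (the "sum of
    the unique elements" convention used for the headline dispersion figure);
    ``total_variance_normalised`` is the textbook 1/(2D)-normalised variant,
    exposed for interoperability.
    """

    matrix: np.ndarray
    labels: tuple[str, ...] = PART_LABELS
    total_variance: float = field(init=False)
    total_variance_normalised: float = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        d = m.shape[0]
        object.__setattr__(self, "total_variance", float(m[np.triu_indices(d, k=1)].sum()))
        object.__setattr__(self, "total_variance_normalised", float(m.sum() / (2.0 * d)))


def variation_matrix(data, weights=None) -> VariationMatrix:
    """Weighted variation matrix of a compositional sample.

    Weights follow the frequency-weights convention (normalised to sum one,
    no small-sample correction).  Requires at least two observations.
    """
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    if arr.shape[0] < 2:
        raise EstimationError("variation matrix needs at least 2 compositions")
    _check_positive(arr)
    w = _normalised_weights(arr.shape[0], weights)
    logs = np.log(arr)
    d = arr.shape[1]
    out = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            lr = logs[:, i] - logs[:, j]
            mu = w @ lr
            out[i, j] = out[j, i] = w @ (lr - mu) ** 2
    return VariationMatrix(matrix=out)


def aitchison_distance(x, y) -> float:
    """Aitchison distance: Euclidean distance between clr (or ilr) images."""
    lx, ly = np.log(np.asarray(x, float)), np.log(np.asarray(y, float))
    dx = (lx - lx.mean()) - (ly - ly.mean())
    return float(np.linalg.norm(dx))
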