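"""Outline morphometrics: tracing, interpolation, Procrustes, EFA, PCA.

A comb silhouette becomes a closed planar outline, the outline a set of
elliptic Fourier coefficients (a_n, b_n, c_n, d_n per harmonic), and a
population of coefficient vectors a set of principal-component shape
scores.  Harmonic power P_n = (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2 guides
how many harmonics suffice to describe a shape.

The Fourier integrals use the piecewise-linear outline with equal
parameter increments per sampled point.  Outlines entering the pipeline
are first resampled to equal arc-length spacing, where this coincides
with the chord-length parameterization of the classical formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure


# ---------------------------------------------------------------------------
# Outline container


@dataclass
class Outline:
    """Closed planar outline as an ordered point sequence.

    Consecutive duplicate points are removed on construction; orientation
    (signed area) is computed and stored.
    """

    points: np.ndarray
    closed: bool = True
    orientation: str = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        # drop consecutive duplicates (incl. wrap-around pair)
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
        pts = pts[keep]
        if len(pts) > 1 and np.all(pts[0] == pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValueError("an outline needs at least 3 distinct points")
        self.points = pts
        self.orientation = "ccw" if self.signed_area() >= 0 else "cw"

    def __len__(self) -> int:
        return len(self.points)

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def ensure_ccw(self) -> "Outline":
        if self.orientation == "ccw":
            return self
        return Outline(self.points[::-1])


# ---------------------------------------------------------------------------
# Tracing and interpolation


_MOORE = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)  # clockwise Moore neighborhood starting west, in (row, col)


def trace_outline(mask: np.ndarray) -> Outline:
    """Trace the closed boundary of the largest foreground component.

    Moore-neighbor boundary following with Jacob's stopping criterion on
    the largest connected component (8-connectivity).  Returns boundary
    pixel centers as (x, y) = (col, row) coordinates.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask contains no foreground pixels")
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    comp = labels == int(np.argmax(counts))
    rows, cols = np.nonzero(comp)
    if (rows.min() == 0 and rows.max() == mask.shape[0] - 1
            and cols.min() == 0 and cols.max() == mask.shape[1] - 1):
        warnings.warn("foreground touches all four image borders; the object may be cropped")

    padded = np.pad(comp, 1)
    # start: uppermost-leftmost foreground pixel, entered from the west
    r0 = rows.min() + 1
    c0 = cols[rows == rows.min()].min() + 1
    boundary = [(r0, c0)]
    if int(padded.sum()) == 1:
        raise ValueError("largest component has a single pixel; no closed boundary")
    # backtrack direction: pointing at the background pixel we came from
    prev = (r0, c0 - 1)
    cur = (r0, c0)
    start, start_prev = cur, prev
    while True:
        dr, dc = prev[0] - cur[0], prev[1] - cur[1]
        k0 = int(np.nonzero((_MOORE[:, 0] == dr) & (_MOORE[:, 1] == dc))[0][0])
        nxt = None
        for step in range(1, 9):
            k = (k0 + step) % 8
            cand = (cur[0] + _MOORE[k, 0], cur[1] + _MOORE[k, 1])
            if padded[cand]:
                nxt = cand
                prev = (cur[0] + _MOORE[(k - 1) % 8, 0], cur[1] + _MOORE[(k - 1) % 8, 1])
                break
        if nxt is None:  # isolated pixel, handled above
            break
        cur = nxt
        if cur == start and prev == start_prev:
            break
        boundary.append(cur)
        if len(boundary) > 4 * padded.size:  # safety; cannot occur on valid input
            raise RuntimeError("boundary tracing failed to terminate")
    pts = np.array([(c - 1, r - 1) for r, c in boundary], dtype=float)
    return Outline(pts)


def interpolate_outline(outline: Outline, k: int = 16570) -> Outline:
    """Resample to ``k`` points equally spaced by arc length.

    The first output point is the outline's original first point.  The
    default of 16,570 coordinates matches the resolution used for the
    comb outline data set.
    """
    if k < 3:
        raise ValueError("k must be at least 3")
    pts = outline.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("outline has zero perimeter")
    s = np.linspace(0.0, total, k, endpoint=False)
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    return Outline(np.column_stack([x, y]))


def smooth_outline(outline: Outline, iterations: int = 20) -> Outline:
    """Closed-curve (1/4, 1/2, 1/4) neighbor smoothing.

    Removes the pixel staircase of traced boundaries, whose inflated arc
    length otherwise distorts the Fourier parameterization; wavelengths
    much longer than a few samples are essentially untouched.
    """
    if iterations < 0:
        raise ValueError("iterations must be non-negative")
    p = outline.points.copy()
    for _ in range(iterations):
        p = 0.25 * np.roll(p, 1, axis=0) + 0.5 * p + 0.25 * np.roll(p, -1, axis=0)
    return Outline(p)


# ---------------------------------------------------------------------------
# Generalized Procrustes alignment


@dataclass
class AlignedOutlineSet:
    """Population of Procrustes-aligned outlines.

    Each outline is centered at the origin, scaled to unit centroid size,
    and rotated to the iteratively re-estimated mean shape.
    """

    outlines: list
    centroid_sizes: np.ndarray
    rotations: np.ndarray
    iterations: int
    mean_shape: np.ndarray

    def coordinate_matrix(self) -> np.ndarray:
        """(n_individuals, 2k) matrix of flattened aligned coordinates."""
        return np.stack([o.points.ravel() for o in self.outlines])


def _centroid_size(pts: np.ndarray) -> float:
    c = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(c**2)))


def _optimal_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """2D rotation (no reflection) minimizing ||src R - dst||."""
    h = src.T @ dst
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def align_outlines(outlines, tol: float = 1e-8, max_iter: int = 100) -> AlignedOutlineSet:
    """Generalized Procrustes alignment of same-length outlines."""
    if len(outlines) < 2:
        raise ValueError("alignment needs at least 2 outlines")
    counts = {len(o) for o in outlines}
    if len(counts) != 1:
        raise ValueError(f"outlines have unequal point counts {sorted(counts)}; interpolate first")
    shapes, sizes = [], []
    for o in outlines:
        pts = o.points - o.points.mean(axis=0)
        size = _centroid_size(pts)
        if size <= 0:
            raise ValueError("degenerate outline with zero centroid size")
        shapes.append(pts / size)
        sizes.append(size)
    shapes = np.array(shapes)
    angles = np.zeros(len(shapes))
    mean = shapes[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i, s in enumerate(shapes):
            r = _optimal_rotation(s, mean)
            shapes[i] = s @ r
            angles[i] += np.arctan2(r[0, 1], r[0, 0])
        new_mean = shapes.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        norm = _centroid_size(new_mean)
        if norm > 0:
            new_mean /= norm
        delta = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if delta < tol:
            break
    return AlignedOutlineSet(
        outlines=[Outline(s) for s in shapes],
        centroid_sizes=np.array(sizes),
        rotations=angles,
        iterations=n_iter,
        mean_shape=mean,
    )


# ---------------------------------------------------------------------------
# Elliptic Fourier analysis


@dataclass
class EFACoefficients:
    """Elliptic Fourier descriptors for harmonics 1..H.

    ``a``, ``b`` describe x(t); ``c``, ``d`` describe y(t); ``A0``, ``C0``
    are the centroid offsets and ``T`` the perimeter parameter.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    A0: float = 0.0
    C0: float = 0.0
    T: float = 1.0

    def __post_init__(self) -> None:
        self.a, self.b = np.atleast_1d(np.asarray(self.a, float)), np.atleast_1d(np.asarray(self.b, float))
        self.c, self.d = np.atleast_1d(np.asarray(self.c, float)), np.atleast_1d(np.asarray(self.d, float))
        lens = {len(self.a), len(self.b), len(self.c), len(self.d)}
        if len(lens) != 1:
            raise ValueError("coefficient arrays must share one length")

    @property
    def n_harmonics(self) -> int:
        return len(self.a)

    def power(self) -> np.ndarray:
        """Per-harmonic power P_n = (a_n^2+b_n^2+c_n^2+d_n^2)/2."""
        return (self.a**2 + self.b**2 + self.c**2 + self.d**2) / 2.0

    def flatten(self, include_offsets: bool = False) -> np.ndarray:
        vec = np.concatenate([self.a, self.b, self.c, self.d])
        if include_offsets:
            vec = np.concatenate([vec, [self.A0, self.C0]])
        return vec

    @classmethod
    def from_flat(cls, vec: np.ndarray, A0: float = 0.0, C0: float = 0.0, T: float = 1.0) -> "EFACoefficients":
        vec = np.asarray(vec, float)
        if len(vec) % 4:
            raise ValueError("flat coefficient vector length must be a multiple of 4")
        h = len(vec) // 4
        return cls(vec[:h], vec[h:2 * h], vec[2 * h:3 * h], vec[3 * h:], A0=A0, C0=C0, T=T)


def efa_decompose(outline: Outline, n_harmonics: int = 26) -> EFACoefficients:
    """Elliptic Fourier decomposition of a closed outline.

    The default of 26 harmonics captures >99% of harmonic power on comb
    outlines.  The input is normalized to counterclockwise orientation so
    coefficients are deterministic.
    """
    if n_harmonics < 1:
        raise ValueError("need at least 1 harmonic")
    outline = outline.ensure_ccw()
    pts = outline.points
    n = len(pts)
    closed = np.vstack([pts, pts[:1]])
    dxy = np.diff(closed, axis=0)
    T = float(np.hypot(dxy[:, 0], dxy[:, 1]).sum())
    # equal parameter increments: point i at phase 2*pi*i/n
    phi = 2.0 * np.pi * np.arange(n + 1) / n
    h = np.arange(1, n_harmonics + 1)[:, None]
    dcos = np.cos(h * phi[1:]) - np.cos(h * phi[:-1])
    dsin = np.sin(h * phi[1:]) - np.sin(h * phi[:-1])
    const = n / (2.0 * (h[:, 0] ** 2) * np.pi**2)
    a = const * (dcos @ dxy[:, 0])
    b = const * (dsin @ dxy[:, 0])
    c = const * (dcos @ dxy[:, 1])
    d = const * (dsin @ dxy[:, 1])
    # piecewise-linear x(t), y(t) with equal dt: the mean is the segment
    # midpoint average, which equals the vertex mean on a closed polygon
    A0, C0 = pts.mean(axis=0)
    return EFACoefficients(a, b, c, d, A0=float(A0), C0=float(C0), T=T)


def efa_reconstruct(coeffs: EFACoefficients, k: int = 500) -> Outline:
    """Evaluate the Fourier series at ``k`` equally spaced parameters."""
    if k < 3:
        raise ValueError("k must be at least 3")
    if coeffs.n_harmonics < 1 or not np.any(coeffs.power() > 0):
        raise ValueError("cannot reconstruct from empty/zero coefficients")
    t = 2.0 * np.pi * np.arange(k) / k
    h = np.arange(1, coeffs.n_harmonics + 1)[:, None]
    cos_t, sin_t = np.cos(h * t), np.sin(h * t)
    x = coeffs.A0 + coeffs.a @ cos_t + coeffs.b @ sin_t
    y = coeffs.C0 + coeffs.c @ cos_t + coeffs.d @ sin_t
    return Outline(np.column_stack([x, y]))


def harmonic_power(coeffs, threshold: float = 0.99):
    """Per-harmonic power, cumulative fraction and harmonics required.

    ``coeffs`` is one :class:`EFACoefficients` or a sequence of them (the
    cumulative fraction is then averaged over the set before locating the
    threshold).  Returns ``(power, cumulative_fraction, n_required)``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if isinstance(coeffs, EFACoefficients):
        coeffs = [coeffs]
    powers = np.stack([c.power() for c in coeffs])
    totals = powers.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("outline with zero total harmonic power")
    cum = np.cumsum(powers / totals, axis=1).mean(axis=0)
    n_required = int(np.argmax(cum >= threshold - 1e-12) + 1)
    return powers.mean(axis=0), cum, n_required


# ---------------------------------------------------------------------------
# Shape PCA


@dataclass
class ShapePCA:
    """Principal components of a coefficient (or coordinate) matrix."""

    scores: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    mean: np.ndarray


def shape_pca(matrix: np.ndarray, n_components: int | None = None) -> ShapePCA:
    """PCA of individuals x coefficient-space, centered but not rescaled.

    Coefficients share units, so columns are mean-centered only.  Scores
    times loadings reconstruct the centered data at full rank.
    """
    from sklearn.decomposition import PCA

    x = np.asarray(matrix, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 individuals")
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values")
    if np.allclose(x, x[0], atol=0, rtol=0):
        raise ValueError("constant matrix has zero variance; PCA undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    return ShapePCA(
        scores=scores,
        loadings=pca.components_,
        variance_fraction=pca.explained_variance_ratio_,
        mean=pca.mean_,
    )
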