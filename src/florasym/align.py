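"""Generalized Procrustes analysis with bending-energy sliding semilandmarks.

The superimposition is a full-Procrustes GPA: every configuration is centred,
scaled to unit centroid size and rotated onto the evolving consensus, with
reflections *never* allowed — reflected symmetry copies of each corolla enter
the analysis as explicit data points, so permitting reflections in the fit
would collapse the asymmetric shape subspaces.

Outline points are semilandmarks: their along-curve position carries no
homology, so after each superimposition pass they are allowed to slide along
the outline tangent (the chord between their two outline neighbours) to the
position minimising the thin-plate-spline bending energy of the deformation
from the consensus to the configuration.  The two basal corner points of each
petal are fixed anatomical landmarks and never slide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .tps_io import Configuration, Dataset

__all__ = [
    "SliderSpec",
    "AlignmentResult",
    "centroid_size",
    "partial_procrustes_fit",
    "gpa",
    "slide_semilandmarks",
    "bending_energy_matrix",
    "bending_energy",
    "default_slider_spec",
]


class DegenerateConfigurationError(ValueError):
    """Raised for configurations with zero centroid size."""


# ---------------------------------------------------------------------------
# Slider specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SliderSpec:
    """Which points slide, and between which outline neighbours.

    ``fixed``: indices of fixed landmarks (never move).
    ``triplets``: ``(m, 3)`` int array of ``(before, slider, after)`` rows;
    the slider's tangent is the chord from *before* to *after*.  Neighbours
    are within-petal only, so sliding never crosses a petal boundary.
    """

    fixed: np.ndarray
    triplets: np.ndarray

    @property
    def sliders(self) -> np.ndarray:
        return self.triplets[:, 1]


def default_slider_spec(n_petals: int = 4, points_per_petal: int = 50) -> SliderSpec:
    """Slider layout for a corolla of outline-digitised petals.

    The first and last point of each petal block (the basal corners) are
    fixed; the interior points are sliders with their immediate within-petal
    neighbours.  For the study layout this is 8 fixed landmarks and 192
    sliding semilandmarks.
    """
    fixed = []
    triplets = []
    for p in range(n_petals):
        base = p * points_per_petal
        fixed.extend([base, base + points_per_petal - 1])
        for j in range(1, points_per_petal - 1):
            triplets.append((base + j - 1, base + j, base + j + 1))
    return SliderSpec(fixed=np.asarray(fixed, dtype=int),
                      triplets=np.asarray(triplets, dtype=int))


# ---------------------------------------------------------------------------
# Size and pairwise fits
# ---------------------------------------------------------------------------

def centroid_size(config: Configuration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances from the centroid."""
    pts = config.points if isinstance(config, Configuration) else np.asarray(config, float)
    centred = pts - pts.mean(axis=0)
    cs = float(np.sqrt(np.sum(centred ** 2)))
    if cs == 0.0:
        warnings.warn("degenerate configuration: all points coincident (CS = 0)")
    return cs


def _center_scale(pts: np.ndarray) -> np.ndarray:
    centred = pts - pts.mean(axis=0)
    cs = np.sqrt(np.sum(centred ** 2))
    if cs == 0.0:
        raise DegenerateConfigurationError("zero centroid size")
    return centred / cs


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix R (det +1) minimising ||source @ R - target||_F."""
    m = source.T @ target
    a = m[0, 0] + m[1, 1]
    b = m[1, 0] - m[0, 1]
    h = np.hypot(a, b)
    if h == 0.0:
        return np.eye(2)
    c, s = a / h, b / h
    return np.array([[c, -s], [s, c]])


def partial_procrustes_fit(
    source: Configuration | np.ndarray, target: Configuration | np.ndarray
) -> tuple[np.ndarray, float]:
    """Superimpose *source* on *target*; return (aligned source, distance).

    Both configurations are centred and scaled to unit centroid size; the
    source is then rotated (rotation only — no reflection) to minimise the
    summed squared distance to the target.  The returned distance is the root
    of that minimised sum.
    """
    src = source.points if isinstance(source, Configuration) else np.asarray(source, float)
    tgt = target.points if isinstance(target, Configuration) else np.asarray(target, float)
    if src.shape != tgt.shape:
        raise ValueError(f"landmark count mismatch: {src.shape} vs {tgt.shape}")
    a = _center_scale(src)
    b = _center_scale(tgt)
    rot = _optimal_rotation(a, b)
    aligned = a @ rot
    return aligned, float(np.linalg.norm(aligned - b))


def _rotate_all(coords: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Rotate each centred unit-CS configuration onto the consensus (batched)."""
    m = np.einsum("nki,kj->nij", coords, consensus)  # (n, 2, 2) cross-products
    a = m[:, 0, 0] + m[:, 1, 1]
    b = m[:, 1, 0] - m[:, 0, 1]
    h = np.hypot(a, b)
    h[h == 0.0] = 1.0
    c, s = a / h, b / h
    rot = np.empty((coords.shape[0], 2, 2))
    rot[:, 0, 0] = c
    rot[:, 0, 1] = -s
    rot[:, 1, 0] = s
    rot[:, 1, 1] = c
    return np.einsum("nki,nij->nkj", coords, rot)


# ---------------------------------------------------------------------------
# Thin-plate-spline bending energy
# ---------------------------------------------------------------------------

def bending_energy_matrix(reference: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Bending-energy matrix of the 2D thin-plate spline anchored at *reference*.

    Kernel ``U(r) = r^2 log r``.  The returned ``(k, k)`` matrix ``B`` gives
    the bending energy of a deformation with landmark displacements
    ``(dx, dy)`` as ``dx' B dx + dy' B dy``; affine deformations lie in its
    null space.
    """
    ref = np.asarray(reference, float)
    k = ref.shape[0]
    d = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kern = np.where(d > 0.0, d * d * np.log(d), 0.0)
    q = np.column_stack([np.ones(k), ref])
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = kern
    lmat[:k, k:] = q
    lmat[k:, :k] = q.T
    if ridge:
        lmat[:k, :k] += ridge * np.eye(k)
    try:
        linv = scipy.linalg.inv(lmat)
    except scipy.linalg.LinAlgError:
        warnings.warn("singular TPS system; applying ridge regularisation")
        return bending_energy_matrix(ref, ridge=(ridge or 1e-8) * 10)
    be = linv[:k, :k]
    return (be + be.T) / 2.0


def bending_energy(be_matrix: np.ndarray, displacement: np.ndarray) -> float:
    """Bending energy of a displacement field ``(k, 2)`` under ``be_matrix``."""
    d = np.asarray(displacement, float)
    return float(d[:, 0] @ be_matrix @ d[:, 0] + d[:, 1] @ be_matrix @ d[:, 1])


def slide_semilandmarks(
    aligned: np.ndarray,
    consensus: np.ndarray,
    sliders: SliderSpec,
    be_matrix: np.ndarray | None = None,
    chunk: int = 128,
) -> np.ndarray:
    """Slide semilandmarks of superimposed configurations along their tangents.

    For each configuration, every slider moves along its unit tangent (the
    chord between its two outline neighbours) by the amount minimising the
    thin-plate-spline bending energy of the deformation from *consensus* to
    the configuration.  Fixed landmarks never move; since zero displacement is
    always admissible, the bending energy cannot increase.

    *aligned* may be a single ``(k, 2)`` configuration or an ``(n, k, 2)``
    stack; the updated coordinates are returned (input untouched).
    """
    coords = np.asarray(aligned, float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    coords = coords.copy()
    n, k, _ = coords.shape

    if be_matrix is None:
        be_matrix = bending_energy_matrix(consensus)
    sl = sliders.sliders
    before, after = sliders.triplets[:, 0], sliders.triplets[:, 2]
    b_ss = be_matrix[np.ix_(sl, sl)]
    b_s = be_matrix[sl]  # (m, k)

    for lo in range(0, n, chunk):
        sub = coords[lo:lo + chunk]
        tang = sub[:, after] - sub[:, before]          # (c, m, 2)
        norm = np.linalg.norm(tang, axis=-1, keepdims=True)
        norm[norm == 0.0] = 1.0
        tang = tang / norm
        u, v = tang[..., 0], tang[..., 1]              # (c, m)

        diff = sub - consensus                          # (c, k, 2)
        gx = diff[..., 0] @ b_s.T                       # (c, m) = (B dx)[sliders]
        gy = diff[..., 1] @ b_s.T
        rhs = -(u * gx + v * gy)

        amat = (u[:, :, None] * u[:, None, :] +
                v[:, :, None] * v[:, None, :]) * b_ss   # (c, m, m)
        try:
            t = np.linalg.solve(amat, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            warnings.warn("singular sliding system; ridge-regularised solve")
            amat = amat + 1e-10 * np.trace(amat, axis1=1, axis2=2)[:, None, None] \
                * np.eye(amat.shape[-1])
            t = np.linalg.solve(amat, rhs[..., None])[..., 0]

        sub[:, sl, 0] += t * u
        sub[:, sl, 1] += t * v
        coords[lo:lo + chunk] = sub

    return coords[0] if single else coords


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    """GPA output: unit-centroid-size, consensus-rotated coordinates."""

    aligned: np.ndarray          # (n, k, 2)
    consensus: np.ndarray        # (k, 2), coordinate-wise mean of aligned
    centroid_sizes: np.ndarray   # (n,), from the raw digitised coordinates
    iterations: int
    slide_iterations: int
    deltas: list = field(default_factory=list)
    ss_history: list = field(default_factory=list)

    @property
    def flat(self) -> np.ndarray:
        """Aligned coordinates flattened to ``(n, 2k)`` (x1,y1,x2,y2,...)."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)


def _gpa_iterate(coords: np.ndarray, consensus: np.ndarray,
                 tol: float, max_iter: int
                 ) -> tuple[np.ndarray, np.ndarray, int, list, list]:
    deltas = []
    ss_history = []
    it = 0
    for it in range(1, max_iter + 1):
        coords = _rotate_all(coords, consensus)
        new_consensus = coords.mean(axis=0)
        delta = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        deltas.append(delta)
        ss_history.append(float(np.sum((coords - consensus) ** 2)))
        if delta < tol:
            break
    return coords, consensus, it, deltas, ss_history


def gpa(
    data: Dataset | np.ndarray,
    sliders: SliderSpec | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
    slide_iter: int = 5,
) -> AlignmentResult:
    """Generalized Procrustes analysis, optionally with sliding semilandmarks.

    Iterates superimposition on the current consensus and consensus updates
    until the consensus RMS change drops below *tol*.  With a
    :class:`SliderSpec`, each converged superimposition is followed by a
    bending-energy sliding pass against the grand consensus, then
    re-superimposition, for up to *slide_iter* outer rounds.  Deterministic
    for a fixed input order.
    """
    raw = data.coords() if isinstance(data, Dataset) else np.asarray(data, float)
    if raw.ndim != 3 or raw.shape[0] < 2:
        raise ValueError("gpa needs at least 2 configurations of shape (k, 2)")
    n = raw.shape[0]

    centred = raw - raw.mean(axis=1, keepdims=True)
    sizes = np.sqrt(np.sum(centred ** 2, axis=(1, 2)))
    if np.any(sizes == 0.0):
        raise DegenerateConfigurationError("zero-centroid-size configuration in input")
    coords = centred / sizes[:, None, None]

    consensus = _center_scale(coords[0])
    coords, consensus, iters, deltas, ss_history = _gpa_iterate(
        coords, consensus, tol, max_iter)
    total_iters = iters
    slide_rounds = 0

    if sliders is not None:
        for _ in range(slide_iter):
            be = bending_energy_matrix(consensus)
            coords = slide_semilandmarks(coords, consensus, sliders, be_matrix=be)
            # sliding perturbs centring/scale; restore and re-superimpose
            coords = coords - coords.mean(axis=1, keepdims=True)
            cs = np.sqrt(np.sum(coords ** 2, axis=(1, 2)))
            coords = coords / cs[:, None, None]
            prev = consensus
            coords, consensus, iters, d2, ss2 = _gpa_iterate(
                coords, consensus, tol, max_iter)
            total_iters += iters
            deltas.extend(d2)
            ss_history.extend(ss2)
            slide_rounds += 1
            if float(np.sqrt(np.mean((consensus - prev) ** 2))) < tol:
                break

    if deltas and deltas[-1] >= tol:
        warnings.warn(
            f"GPA did not converge to tol={tol:g}; final consensus delta "
            f"{deltas[-1]:.3g}"
        )
    consensus = coords.mean(axis=0)
    return AlignmentResult(
        aligned=coords,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations=total_iters,
        slide_iterations=slide_rounds,
        deltas=deltas,
        ss_history=ss_history,
    )
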