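"""PCA of the symmetry-expanded shape space and its subspace decomposition.

PCA of Procrustes-aligned coordinates of a complete symmetry group splits
shape space into orthogonal subspaces indexed by the characters of the Klein
four-group.  Writing ``T_V`` and ``T_H`` for the two relabelling reflections
acting as linear maps on shape space, every eigenvector ``v`` of the
covariance of a symmetry-closed sample satisfies (up to eigenvalue
degeneracy) ``T(v) = +/- v``; the sign pair ``(s_V, s_H) = (v.T_V(v),
v.T_H(v))`` classifies the component:

* ``(+, +)`` — fully symmetric: coordinated variation of all four petals,
  the four copies of one corolla share identical scores;
* ``(+, -)`` or ``(-, +)`` — lateral asymmetry: contrasts between adjacent
  petal pairs, copies sit in mirror positions;
* ``(-, -)`` — transversal asymmetry: contrasts between opposite petal pairs.

Characters are computed on eigenvectors (operator commutation) rather than by
inspecting copy scores, because with close or degenerate eigenvalues raw PCA
axes can mix characters; classification therefore re-solves the PCA within
each character subspace using the exact group-averaging projectors, which
yields pure components regardless of the spectrum.  The copy-score criterion
remains available as an independent cross-check
(:func:`classify_by_copy_scores`).

The reflections only act as exact linear maps if the consensus symmetry axes
coincide with the coordinate axes, so the aligned dataset is first rotated to
that canonical orientation (:func:`canonicalize_orientation`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignmentResult, _optimal_rotation
from .symmetry import TRANSFORMS, get_transform, landmark_permutation
from .tps_io import Dataset

__all__ = [
    "Decomposition",
    "AsymmetryScores",
    "canonicalize_orientation",
    "shape_pca",
    "classify_components",
    "classify_by_copy_scores",
    "variance_fractions",
    "asymmetry_scores",
    "transform_shape_vector",
]

SUBSPACES = ("symmetric", "lateral", "transversal")


@dataclass
class Decomposition:
    """Eigenstructure of the aligned, symmetry-expanded shape sample."""

    eigenvectors: np.ndarray          # (p, 2k) rows, orthonormal
    eigenvalues: np.ndarray           # (p,) descending
    scores: np.ndarray                # (n, p)
    mean: np.ndarray                  # (2k,) grand mean shape (flattened)
    consensus: np.ndarray             # (k, 2) canonical-frame consensus
    n_petals: int
    points_per_petal: int
    labels: list[str] | None = None   # per-PC subspace label
    characters: np.ndarray | None = None  # (p, 2) = (s_V, s_H)
    total_variance: float = 0.0

    def pcs_with_label(self, label: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("components not yet classified")
        return np.flatnonzero(np.asarray(self.labels) == label)

    def to_frame(self) -> pd.DataFrame:
        p = len(self.eigenvalues)
        frame = pd.DataFrame({
            "pc": np.arange(1, p + 1),
            "eigenvalue": self.eigenvalues,
            "variance_pct": 100.0 * self.eigenvalues /
                            max(self.total_variance, np.finfo(float).tiny),
        })
        if self.labels is not None:
            frame["label"] = self.labels
            frame["s_V"] = self.characters[:, 0]
            frame["s_H"] = self.characters[:, 1]
        return frame


@dataclass
class AsymmetryScores:
    """Per-unit asymmetry magnitudes (distances from the symmetric midpoint)."""

    table: pd.DataFrame        # unit ids + lateral_score, transversal_score
    mode: str                  # per_flower | per_configuration
    score_kind: str            # norm | abs_sum
    symmetric_scores: np.ndarray  # per-unit score vectors on symmetric PCs


# ---------------------------------------------------------------------------
# Shape-space action of the symmetry transforms
# ---------------------------------------------------------------------------

def transform_shape_vector(
    vec: np.ndarray, transform: str, n_petals: int, points_per_petal: int
) -> np.ndarray:
    """Apply a relabelling reflection to flattened shape vectors ``(..., 2k)``."""
    t = get_transform(transform)
    v = np.asarray(vec, float)
    pts = v.reshape(v.shape[:-1] + (-1, 2)).copy()
    if t.flip_x:
        pts[..., 0] *= -1.0
    if t.flip_y:
        pts[..., 1] *= -1.0
    perm = landmark_permutation(t, n_petals, points_per_petal)
    return pts[..., perm, :].reshape(v.shape)


def canonicalize_orientation(
    aligned: np.ndarray, consensus: np.ndarray, n_petals: int,
    points_per_petal: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate aligned data so the consensus symmetry axes are the coordinate axes.

    GPA fixes orientation only up to an arbitrary rotation.  If the consensus
    ``C`` is (near-)invariant under the relabelling reflection about an axis
    at angle ``phi``, then the relabelled x-reflection of ``C`` differs from
    ``C`` by a rotation of ``2*phi``; halving that fitted angle gives the
    frame in which ``reflectV``/``reflectH`` are exact coordinate negations.
    """
    c = consensus - consensus.mean(axis=0)
    reflected = transform_shape_vector(
        c.reshape(-1), "reflectV", n_petals, points_per_petal
    ).reshape(-1, 2)
    rot = _optimal_rotation(reflected, c)
    phi0 = 0.5 * np.arctan2(rot[1, 0], rot[0, 0])

    def residual(phi: float) -> tuple[float, np.ndarray]:
        cs, sn = np.cos(phi), np.sin(phi)
        r = np.array([[cs, -sn], [sn, cs]])
        c_rot = c @ r
        check = transform_shape_vector(
            c_rot.reshape(-1), "reflectV", n_petals, points_per_petal
        ).reshape(-1, 2)
        return (np.linalg.norm(check - c_rot)
                / max(np.linalg.norm(c_rot), 1e-300), r)

    # the half-angle fit is defined modulo 90 degrees and up to sign; the
    # wrong branch maps the relabelling of one axis onto the other, so pick
    # the candidate frame with the smallest symmetry residual
    (resid, r_half) = min(
        (residual(s * phi0 + b) for s in (1.0, -1.0)
         for b in (0.0, np.pi / 2.0)),
        key=lambda t: t[0])
    if resid > 0.05:
        warnings.warn(
            f"consensus deviates from biradial symmetry (relative residual "
            f"{resid:.3g}); check the landmark labelling convention"
        )
    return aligned @ r_half, consensus @ r_half


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def shape_pca(
    alignment: AlignmentResult,
    n_petals: int = 4,
    points_per_petal: int = 50,
    canonicalize: bool = True,
    eig_tol: float = 1e-12,
) -> Decomposition:
    """Covariance PCA (divisor n-1) of aligned shape coordinates.

    Components with eigenvalues below ``eig_tol`` times the leading eigenvalue
    (or absolutely zero variance) are dropped; the retained eigenvectors are
    orthonormal rows and the eigenvalue sum equals the total Procrustes
    variance of the retained space.
    """
    aligned = alignment.aligned
    if aligned.shape[0] < 2:
        raise ValueError("PCA needs at least 2 configurations")
    consensus = alignment.consensus
    if canonicalize:
        aligned, consensus = canonicalize_orientation(
            aligned, consensus, n_petals, points_per_petal)

    n = aligned.shape[0]
    flat = aligned.reshape(n, -1)
    mean = flat.mean(axis=0)
    centred = flat - mean
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    eigvals = svals ** 2 / (n - 1)
    if eigvals[0] > 0:
        keep = eigvals > eig_tol * eigvals[0]
    else:
        keep = np.zeros_like(eigvals, dtype=bool)
    total = float(np.sum(centred ** 2) / (n - 1))
    eigvals = eigvals[keep]
    vecs = vt[keep]
    scores = centred @ vecs.T
    return Decomposition(
        eigenvectors=vecs,
        eigenvalues=eigvals,
        scores=scores,
        mean=mean,
        consensus=consensus,
        n_petals=n_petals,
        points_per_petal=points_per_petal,
        total_variance=total,
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def character_project(
    vectors: np.ndarray, s_v: int, s_h: int, n_petals: int,
    points_per_petal: int
) -> np.ndarray:
    """Project shape vectors onto one character subspace of the Klein group.

    ``P = (I + s_V T_V + s_H T_H + s_V s_H T_HV) / 4`` — the group-averaging
    projector onto the subspace where the two relabelling reflections act as
    the signs ``(s_V, s_H)``.
    """
    out = np.array(vectors, float, copy=True)
    for sign, name in ((s_v, "reflectV"), (s_h, "reflectH"),
                       (s_v * s_h, "reflectHV")):
        out += sign * transform_shape_vector(vectors, name, n_petals,
                                             points_per_petal)
    return out / 4.0


_CHARACTER_LABELS = (
    ((1, 1), "symmetric"),
    ((1, -1), "lateral"),
    ((-1, 1), "lateral"),
    ((-1, -1), "transversal"),
)


def classify_components(
    dec: Decomposition,
    tol_threshold: float = 0.9,
    eig_tol: float = 1e-12,
) -> Decomposition:
    """Resolve the PCA into pure-character components and label them.

    The covariance of a symmetry-closed sample commutes with the group action,
    so shape space splits into four orthogonal character subspaces that the
    covariance leaves invariant.  Raw PCA axes mix characters wherever
    eigenvalues are close, so the centred data are projected onto each
    character subspace with the exact group-averaging projectors and the PCA
    is re-solved within each; the re-sorted components are pure by
    construction.  Labels: ``(+,+)`` symmetric, ``(-,-)`` transversal, mixed
    signs lateral (the two lateral characters are merged, as the two nominal
    axes cannot be told apart).  The characters ``s_T = v . T(v)`` are
    recomputed on the final eigenvectors as a verification; a component whose
    character magnitude falls below *tol_threshold* is flagged ambiguous.
    """
    n = dec.scores.shape[0]
    centred = dec.scores @ dec.eigenvectors  # reconstruct centred data
    vec_list, val_list, label_list = [], [], []
    for (s_v, s_h), label in _CHARACTER_LABELS:
        sub = character_project(centred, s_v, s_h, dec.n_petals,
                                dec.points_per_petal)
        _, svals, vt = np.linalg.svd(sub, full_matrices=False)
        eigvals = svals ** 2 / (n - 1)
        keep = eigvals > eig_tol * max(dec.eigenvalues[0], np.finfo(float).tiny)
        vec_list.append(vt[keep])
        val_list.append(eigvals[keep])
        label_list.extend([label] * int(keep.sum()))

    vecs = np.vstack(vec_list) if vec_list else np.empty((0, centred.shape[1]))
    vals = np.concatenate(val_list)
    labels = np.asarray(label_list, dtype=object)
    order = np.argsort(vals)[::-1]
    vecs, vals, labels = vecs[order], vals[order], list(labels[order])

    # verification characters on the final eigenvectors; no tangent projection
    # is needed (the aligned data are centred and rotation-fitted, and the
    # unit-size sphere's radial direction is itself symmetric-character)
    s_v_arr = np.empty(len(vals))
    s_h_arr = np.empty(len(vals))
    for i, v in enumerate(vecs):
        s_v_arr[i] = float(v @ transform_shape_vector(
            v, "reflectV", dec.n_petals, dec.points_per_petal))
        s_h_arr[i] = float(v @ transform_shape_vector(
            v, "reflectH", dec.n_petals, dec.points_per_petal))
        if min(abs(s_v_arr[i]), abs(s_h_arr[i])) < tol_threshold:
            labels[i] = "ambiguous"
    if "ambiguous" in labels:
        warnings.warn(
            f"{labels.count('ambiguous')} principal component(s) could not be "
            "assigned to a symmetry subspace"
        )

    dec.eigenvectors = vecs
    dec.eigenvalues = vals
    dec.scores = centred @ vecs.T
    dec.labels = labels
    dec.characters = np.column_stack([s_v_arr, s_h_arr])
    return dec


def classify_by_copy_scores(
    dec: Decomposition, expanded: Dataset, tol: float = 0.9
) -> list[str]:
    """Independent classification from the score geometry of symmetry copies.

    On a symmetric PC the four copies of one object share one score; on an
    asymmetric PC the copies form mirror pairs whose pattern over
    (identity, V, H, HV) is ``(1, s_V, s_H, s_V*s_H)``.  Regressing each
    copy's scores on the identity copy's recovers the character signs without
    touching the eigenvectors.
    """
    meta = expanded.meta()
    keys = meta.apply(
        lambda r: (r["flower"], r["imaging"], r["digitisation"], r["object_id"]),
        axis=1)
    order = {t.id: j for j, t in enumerate(TRANSFORMS)}
    by_object: dict = {}
    for i, (key, tr) in enumerate(zip(keys, meta["transform"])):
        by_object.setdefault(key, [None] * 4)[order[tr]] = i
    idx = np.array([v for v in by_object.values() if None not in v])
    base = dec.scores[idx[:, 0]]            # identity copies, (n_obj, p)
    denom = np.sum(base ** 2, axis=0)
    denom[denom == 0.0] = np.finfo(float).tiny
    s_v = np.sum(dec.scores[idx[:, 1]] * base, axis=0) / denom
    s_h = np.sum(dec.scores[idx[:, 2]] * base, axis=0) / denom
    labels = []
    for a, b in zip(s_v, s_h):
        if a > tol and b > tol:
            labels.append("symmetric")
        elif a < -tol and b < -tol:
            labels.append("transversal")
        elif abs(a) > tol and abs(b) > tol:
            labels.append("lateral")
        else:
            labels.append("ambiguous")
    return labels


def variance_fractions(dec: Decomposition) -> dict[str, float]:
    """Percent of total shape variance per symmetry subspace."""
    if dec.labels is None:
        raise ValueError("components not yet classified")
    labels = np.asarray(dec.labels)
    total = dec.eigenvalues.sum()
    if total <= 0:
        return {s: 0.0 for s in SUBSPACES}
    out = {s: float(100.0 * dec.eigenvalues[labels == s].sum() / total)
           for s in SUBSPACES}
    unassigned = float(100.0 * dec.eigenvalues[labels == "ambiguous"].sum() / total)
    if unassigned > 0:
        warnings.warn(
            f"{unassigned:.2f}% of variance on ambiguous components reported "
            "as 'unassigned'"
        )
        out["unassigned"] = unassigned
    return out


# ---------------------------------------------------------------------------
# Asymmetry magnitudes
# ---------------------------------------------------------------------------

def asymmetry_scores(
    dec: Decomposition,
    expanded: Dataset,
    mode: str = "per_flower",
    score_kind: str = "norm",
) -> AsymmetryScores:
    """Distance of each unit from the symmetric midpoint in each asymmetric subspace.

    ``score_kind='norm'`` (default) is the Euclidean distance in the subspace
    spanned by that label's PCs; ``'abs_sum'`` sums the absolute per-PC scores
    instead.  ``mode='per_flower'`` averages over symmetry copies and the
    imaging/digitisation replicates (the copies of one configuration share the
    same subspace norm by mirror symmetry); ``'per_configuration'`` keeps one
    row per expanded configuration.
    """
    if dec.labels is None:
        raise ValueError("components not yet classified")
    if score_kind not in ("norm", "abs_sum"):
        raise ValueError(f"unknown score_kind {score_kind!r}")
    if mode not in ("per_flower", "per_configuration"):
        raise ValueError(f"unknown mode {mode!r}")

    def magnitude(sub_scores: np.ndarray) -> np.ndarray:
        if sub_scores.shape[1] == 0:
            return np.zeros(sub_scores.shape[0])
        if score_kind == "norm":
            return np.sqrt(np.sum(sub_scores ** 2, axis=1))
        return np.sum(np.abs(sub_scores), axis=1)

    lat = magnitude(dec.scores[:, dec.pcs_with_label("lateral")])
    trans = magnitude(dec.scores[:, dec.pcs_with_label("transversal")])
    sym_scores = dec.scores[:, dec.pcs_with_label("symmetric")]

    meta = expanded.meta()
    table = meta.copy()
    table["lateral_score"] = lat
    table["transversal_score"] = trans

    if mode == "per_configuration":
        return AsymmetryScores(table=table, mode=mode, score_kind=score_kind,
                               symmetric_scores=sym_scores)

    grouped = table.groupby("flower", sort=True)
    out = grouped.agg(
        tree=("tree", "first"),
        sex=("sex", "first"),
        lateral_score=("lateral_score", "mean"),
        transversal_score=("transversal_score", "mean"),
    ).reset_index()
    sym_mean = np.stack([
        sym_scores[grouped.indices[f]].mean(axis=0) for f in out["flower"]
    ]) if sym_scores.shape[1] else np.zeros((len(out), 0))
    return AsymmetryScores(table=out, mode=mode, score_kind=score_kind,
                           symmetric_scores=sym_mean)
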