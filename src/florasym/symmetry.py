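"""Biradial symmetry transformations with landmark re-labelling.

A tetrameric corolla in planar view has two perpendicular (nominal) symmetry
axes, so its symmetry group is the Klein four-group: identity, reflection
across the vertical axis, reflection across the horizontal axis, and the
composition of both (a half-turn).  Applying a reflection to a landmark
configuration must be accompanied by re-labelling: the reflected petals fall
on other petals' positions and the within-petal traversal direction flips, so
the point labels are permuted to restore homology.

Canonical layout assumed (see :mod:`florasym.synthetic`): petals P1..P4
counterclockwise starting in the (+x, +y) quadrant, points within each petal
counterclockwise.  Then

* ``reflectV`` (negate x): P1<->P2, P3<->P4, within-petal order reversed;
* ``reflectH`` (negate y): P1<->P4, P2<->P3, within-petal order reversed;
* ``reflectHV`` (negate both; a rotation): P1<->P3, P2<->P4, order preserved.

Reflections operate in each configuration's own centred coordinates; no
symmetry-axis estimation is performed, because the subsequent GPA aligns all
copies anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import partial_procrustes_fit
from .tps_io import Configuration, Dataset

__all__ = [
    "SymmetryTransform",
    "TRANSFORMS",
    "get_transform",
    "apply_transform",
    "landmark_permutation",
    "expand_symmetry_group",
    "symmetrise",
    "validate_labeling",
    "compose",
]


@dataclass(frozen=True)
class SymmetryTransform:
    """One element of the corolla's Klein four-group.

    ``flip_x`` / ``flip_y`` describe the coordinate map (in centred
    coordinates); ``petal_perm[p]`` is the source petal whose (possibly
    reversed) points land in destination block ``p``; ``reverse_within`` flags
    the within-petal order flip that accompanies a single reflection.
    """

    id: str
    flip_x: bool
    flip_y: bool
    petal_perm: tuple[int, ...]
    reverse_within: bool


_TRANSFORMS = {
    "identity": SymmetryTransform("identity", False, False, (0, 1, 2, 3), False),
    "reflectV": SymmetryTransform("reflectV", True, False, (1, 0, 3, 2), True),
    "reflectH": SymmetryTransform("reflectH", False, True, (3, 2, 1, 0), True),
    "reflectHV": SymmetryTransform("reflectHV", True, True, (2, 3, 0, 1), False),
}

TRANSFORMS = tuple(_TRANSFORMS.values())


def get_transform(name: str) -> SymmetryTransform:
    try:
        return _TRANSFORMS[name]
    except KeyError:
        raise ValueError(
            f"unknown symmetry transform {name!r}; expected one of "
            f"{list(_TRANSFORMS)}"
        ) from None


def compose(a: SymmetryTransform, b: SymmetryTransform) -> SymmetryTransform:
    """Group composition ``a . b`` (apply *b* first, then *a*)."""
    flip_x = a.flip_x ^ b.flip_x
    flip_y = a.flip_y ^ b.flip_y
    perm = tuple(b.petal_perm[a.petal_perm[p]] for p in range(len(a.petal_perm)))
    reverse = a.reverse_within ^ b.reverse_within
    for t in TRANSFORMS:
        if (t.flip_x, t.flip_y, t.petal_perm, t.reverse_within) == \
                (flip_x, flip_y, perm, reverse):
            return t
    raise RuntimeError("composition left the group (should be impossible)")


def landmark_permutation(
    t: SymmetryTransform, n_petals: int = 4, points_per_petal: int = 50
) -> np.ndarray:
    """Flat index array ``perm`` with ``new_points = old_points[perm]``."""
    if len(t.petal_perm) != n_petals:
        raise ValueError(
            f"transform {t.id} describes {len(t.petal_perm)} petals, "
            f"dataset has {n_petals}"
        )
    perm = np.empty(n_petals * points_per_petal, dtype=int)
    for dest in range(n_petals):
        src = t.petal_perm[dest]
        idx = np.arange(points_per_petal) + src * points_per_petal
        if t.reverse_within:
            idx = idx[::-1]
        perm[dest * points_per_petal:(dest + 1) * points_per_petal] = idx
    return perm


def apply_transform(
    config: Configuration,
    t: SymmetryTransform | str,
    n_petals: int = 4,
    points_per_petal: int = 50,
) -> Configuration:
    """Reflect a configuration and re-label its points to restore homology."""
    if isinstance(t, str):
        t = get_transform(t)
    pts = config.points - config.points.mean(axis=0)
    if t.flip_x:
        pts = pts * np.array([-1.0, 1.0])
    if t.flip_y:
        pts = pts * np.array([1.0, -1.0])
    perm = landmark_permutation(t, n_petals, points_per_petal)
    out = config.copy()
    out.points = pts[perm]
    out.transform_id = compose(t, get_transform(config.transform_id)).id
    return out


def expand_symmetry_group(data: Dataset) -> Dataset:
    """Quadruple a dataset with the reflected, re-labelled symmetry copies.

    Every raw configuration is joined by its three transformed copies, which
    share all metadata except ``transform_id``.  The copies of one object stay
    adjacent (identity first), so downstream grouping by object is positional
    as well as label-based.
    """
    bad = [c.object_id for c in data if c.transform_id != "identity"]
    if bad:
        raise ValueError(
            f"dataset already contains non-identity symmetry copies "
            f"(e.g. {bad[0]!r}); expand_symmetry_group expects raw data"
        )
    configs = []
    for cfg in data:
        configs.append(cfg.copy())
        for t in TRANSFORMS[1:]:
            configs.append(
                apply_transform(cfg, t, data.n_petals, data.points_per_petal)
            )
    return Dataset(configs, n_petals=data.n_petals,
                   points_per_petal=data.points_per_petal)


def symmetrise(expanded: Dataset, aligned: np.ndarray) -> tuple[Dataset, np.ndarray]:
    """Average the four aligned symmetry copies of each object.

    Because the copies are re-labelled, their aligned coordinates are
    homologous and the coordinate-wise mean over the group is the object's
    fully symmetric shape component — the "symmetrised" configuration used
    for the measurement-error ANOVA and the sex regression.

    Returns a Dataset of one configuration per original object (metadata
    preserved, ``transform_id='symmetrised'``) plus the ``(n_obj, k, 2)``
    averaged coordinates.
    """
    aligned = np.asarray(aligned, float)
    if aligned.shape[0] != len(expanded):
        raise ValueError("aligned coordinates do not match the expanded dataset")

    groups: dict[tuple, dict[str, int]] = {}
    order: list[tuple] = []
    for i, cfg in enumerate(expanded):
        key = (cfg.flower_id, cfg.imaging_rep, cfg.digitisation_rep, cfg.object_id)
        if key not in groups:
            groups[key] = {}
            order.append(key)
        groups[key][cfg.transform_id] = i

    needed = {t.id for t in TRANSFORMS}
    incomplete = [key for key in order if set(groups[key]) != needed]
    if incomplete:
        msgs = []
        for key in incomplete[:5]:
            missing = sorted(needed - set(groups[key]))
            msgs.append(f"object {key[3]!r} missing {missing}")
        raise ValueError("incomplete symmetry groups: " + "; ".join(msgs))

    coords = np.empty((len(order), aligned.shape[1], 2))
    configs = []
    for j, key in enumerate(order):
        idx = [groups[key][t.id] for t in TRANSFORMS]
        coords[j] = aligned[idx].mean(axis=0)
        template = expanded[groups[key]["identity"]]
        sym = template.copy()
        sym.points = coords[j]
        sym.transform_id = "symmetrised"
        configs.append(sym)
    return Dataset(configs, n_petals=expanded.n_petals,
                   points_per_petal=expanded.points_per_petal), coords


# ---------------------------------------------------------------------------
# Labeling validation
# ---------------------------------------------------------------------------

def _remap_indices(n_petals: int, ppp: int, offset: int, reverse_petals: bool,
                   reverse_within: bool) -> np.ndarray:
    """Index array realising one candidate relabeling of the raw file order."""
    petals = np.arange(n_petals)
    if reverse_petals:
        petals = petals[::-1]
    petals = np.roll(petals, -offset)
    idx = []
    for p in petals:
        block = np.arange(ppp) + p * ppp
        if reverse_within:
            block = block[::-1]
        idx.append(block)
    return np.concatenate(idx)


def _copy_distance_score(subset, idx, n_petals: int, ppp: int) -> float:
    dists = []
    for cfg in subset:
        remapped = cfg.copy()
        remapped.points = cfg.points[idx]
        for t in TRANSFORMS[1:]:
            copy = apply_transform(remapped, t, n_petals, ppp)
            _, d = partial_procrustes_fit(copy, remapped)
            dists.append(d)
    return float(np.mean(dists))


def validate_labeling(
    data: Dataset, max_configs: int = 20, check_start_shift: bool = True
) -> tuple[dict, dict[tuple, float]]:
    """Diagnose whether a file's point ordering matches the canonical layout.

    Scores every candidate block remap (petal offset x petal direction x
    within-petal reversal, 16 in all) by the mean Procrustes distance between
    each configuration and its three reflected, re-labelled symmetry copies.

    All 16 block remaps *normalise* the Klein four-group of relabelling
    reflections, so this score — and every downstream result (expansion, GPA,
    PCA subspaces) — is mathematically invariant under them: they are
    equivalent labelings of the same biradial structure, mirroring the
    ambiguity of the two symmetry axes themselves.  The recommendation
    therefore tie-breaks to the identity representative; a non-identity
    recommendation only ever signals numerically meaningful asymmetry between
    score-equivalent candidates (i.e. data that are not a consistent block
    relabeling of the canonical layout).

    What *is* detectable is a within-petal cyclic start-point shift (an
    outline digitised from the wrong corner), which breaks the fixed-landmark
    homology: with ``check_start_shift`` the score is also minimised over
    cyclic shifts and the best shift reported as ``start_shift``.

    Returns ``(recommendation, scores)``; *recommendation* has keys
    ``petal_offset``, ``reverse_petals``, ``reverse_within``, ``start_shift``
    and ``score``; *scores* maps each candidate triple to its mean distance.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    subset = data.configurations[:max_configs]
    ppp = data.points_per_petal
    scores: dict[tuple, float] = {}
    for offset in range(data.n_petals):
        for reverse_petals in (False, True):
            for reverse_within in (False, True):
                idx = _remap_indices(data.n_petals, ppp, offset,
                                     reverse_petals, reverse_within)
                scores[(offset, reverse_petals, reverse_within)] = \
                    _copy_distance_score(subset, idx, data.n_petals, ppp)

    # deterministic tie-break: identity first, then by offset / flags
    ordered = sorted(scores)
    best_score = min(scores.values())
    best = next(k for k in ordered if scores[k] <= best_score * (1 + 1e-9) + 1e-12)

    start_shift = 0
    shift_score = scores[best]
    if check_start_shift and ppp > 2:
        base = np.arange(data.n_petals * ppp).reshape(data.n_petals, ppp)
        for shift in range(1, ppp):
            idx = np.concatenate([np.roll(row, -shift) for row in base])
            s = _copy_distance_score(subset, idx, data.n_petals, ppp)
            if s < shift_score * (1 - 1e-9):
                shift_score, start_shift = s, shift

    recommendation = {
        "petal_offset": best[0],
        "reverse_petals": best[1],
        "reverse_within": best[2],
        "start_shift": start_shift,
        "score": scores[best] if start_shift == 0 else shift_score,
    }
    return recommendation, scores
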