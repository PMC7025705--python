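"""Synthetic tetrameric corolla outlines with controlled (a)symmetry.

Emulates the study design of a gynodioecious tree sampled for corolla shape:
two sexual groups (female, hermaphrodite), several trees per sex, several
flowers per tree, each flower photographed twice and each photograph digitised
twice.  A flower is four petal outlines of 50 points each, petals placed at
the bisector angles 45/135/225/315 degrees so that the (nominal) symmetry axes
are the coordinate axes before the random whole-flower rotation.

Shape variation is injected through petal-template perturbations organised by
symmetry character:

* *symmetric* — the same perturbation on all four petals (coordinated
  inter-flower variation; invariant under both reflections);
* *lateral* — the two adjacent-pair contrast patterns ``(+,+,-,-)`` and
  ``(+,-,-,+)`` (each anti-invariant under exactly one reflection);
* *transversal* — the opposite-pair contrast ``(+,-,+,-)`` (anti-invariant
  under both reflections);
* per-petal independent noise (spans all characters).

Contrast perturbations touch only mirror-symmetric template parameters
(length, width, tip shape); the chiral ``skew`` parameter changes character
under reflection and is only driven by the unstructured per-petal noise.

Measurement error enters at two nested levels: a per-photograph rigid motion
plus isotropic point jitter shared by both digitisations of that photograph,
and a per-digitisation tangential point jitter (digitising error moves points
mostly *along* the traced outline — exactly the error the sliding
semilandmarks are designed to absorb).

Female flowers are scaled by ``female_size_factor`` (default 0.845, i.e. a
corolla about 15.5% smaller than the hermaphrodite mean) and their lateral and
transversal perturbation SDs are multiplied by ``female_asym_factor``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import centroid_size
from .tps_io import Configuration, Dataset, resample_outline, write_metadata, write_tps

__all__ = [
    "PetalTemplate",
    "GeneratorParams",
    "render_petal",
    "generate_corolla",
    "generate_population",
    "write_population",
    "DEFAULT_FLOWERS_PER_TREE",
]

#: per-tree flower counts of the study design (8 female trees, then 8
#: hermaphrodite trees; 169 flowers in total)
DEFAULT_FLOWERS_PER_TREE = (13, 12, 11, 11, 9, 13, 10, 10,
                            11, 9, 10, 10, 10, 10, 10, 10)

#: adjacent-pair contrast patterns spanning the two lateral characters, and
#: the opposite-pair contrast spanning the transversal character
LATERAL_PATTERNS = (np.array([1.0, 1.0, -1.0, -1.0]),
                    np.array([1.0, -1.0, -1.0, 1.0]))
TRANSVERSAL_PATTERN = np.array([1.0, -1.0, 1.0, -1.0])


@dataclass(frozen=True)
class PetalTemplate:
    """Parametric petal outline (dimensionless lengths in digitiser units).

    The outline runs from basal corner A to basal corner B around the tip.
    ``tip_shape`` interpolates from broadly obtuse (0) to sharply pointed (1);
    ``base_width`` is the basal width as a fraction of the maximal width;
    ``skew`` shifts the tip sideways (0 = bilaterally symmetric petal);
    ``attach_radius`` is the distance of the petal base midpoint from the
    corolla centre.
    """

    length: float = 300.0
    width: float = 200.0
    tip_shape: float = 0.5
    base_width: float = 0.4
    skew: float = 0.0
    attach_radius: float = 60.0

    def validate(self) -> None:
        if not (self.length > 0 and self.width > 0):
            raise ValueError(
                f"degenerate petal template: length={self.length}, "
                f"width={self.width} (both must be > 0)"
            )
        if not (0 < self.base_width <= 1):
            raise ValueError(f"base_width must be in (0, 1], got {self.base_width}")

    def perturbed(self, d_length: float = 0.0, d_width: float = 0.0,
                  d_tip: float = 0.0, d_skew: float = 0.0) -> "PetalTemplate":
        """Offset template, clipped to stay geometrically valid."""
        return dataclasses.replace(
            self,
            length=max(self.length + d_length, 1e-3 * self.length),
            width=max(self.width + d_width, 1e-3 * self.width),
            tip_shape=float(np.clip(self.tip_shape + d_tip, 0.0, 1.0)),
            skew=self.skew + d_skew,
        )


def _bezier(p0, p1, p2, p3, t):
    t = t[:, None]
    u = 1.0 - t
    return (u ** 3 * p0 + 3 * u ** 2 * t * p1 + 3 * u * t ** 2 * p2 + t ** 3 * p3)


def render_petal(template: PetalTemplate, n_points: int,
                 dense: int = 400) -> np.ndarray:
    """Render a petal outline as *n_points* arc-length-equidistant points.

    Local frame: petal base on the x axis, tip towards +y.  The curve is two
    cubic Bezier arcs (corner A -> tip -> corner B) densely evaluated and then
    resampled to equal arc-length spacing; corner A sits at positive x, so the
    points run counterclockwise.  First and last point lie on the petal base.
    """
    template.validate()
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    L, W = template.length, template.width
    half_base = template.base_width * W / 2.0
    tip = np.array([template.skew * W / 2.0, L])
    a = np.array([half_base, 0.0])
    b = np.array([-half_base, 0.0])
    # bulge control at maximal width, tip control pulled in for pointed tips
    tip_pull = (1.0 - template.tip_shape) * W / 4.0
    right = _bezier(a, np.array([W / 2.0, 0.35 * L]),
                    tip + np.array([tip_pull, -0.1 * L]), tip,
                    np.linspace(0.0, 1.0, dense))
    left = _bezier(tip, tip + np.array([-tip_pull, -0.1 * L]),
                   np.array([-W / 2.0, 0.35 * L]), b,
                   np.linspace(0.0, 1.0, dense))
    curve = np.vstack([right, left[1:]])
    return resample_outline(curve, n_points)


def generate_corolla(
    base: PetalTemplate,
    perturbations=None,
    rotation: float = 0.0,
    translation=(0.0, 0.0),
    n_points: int = 50,
    object_id: str = "synthetic",
    **meta,
) -> Configuration:
    """Assemble four perturbed petals into one 200-point configuration.

    *perturbations* is a sequence of 4 dicts of :meth:`PetalTemplate.perturbed`
    keyword offsets (or ``None`` for an unperturbed corolla).  Petal P1 sits in
    the (+x, +y) quadrant (bisector at 45 degrees) with P2..P4 counterclockwise;
    the symmetry axes are the coordinate axes before *rotation* is applied.
    """
    if perturbations is None:
        perturbations = [{}] * 4
    if len(perturbations) != 4:
        raise ValueError(f"expected 4 petal perturbations, got {len(perturbations)}")
    blocks = []
    for p, offsets in enumerate(perturbations):
        theta = np.deg2rad(45.0 + 90.0 * p) + rotation
        tpl = base.perturbed(**offsets)
        local = render_petal(tpl, n_points)
        # local +y (petal axis) -> radial direction theta
        c, s = np.cos(theta - np.pi / 2.0), np.sin(theta - np.pi / 2.0)
        rot = np.array([[c, -s], [s, c]])
        attach = tpl.attach_radius * np.array([np.cos(theta), np.sin(theta)])
        blocks.append(local @ rot.T + attach + np.asarray(translation, float))
    return Configuration(points=np.vstack(blocks), object_id=object_id, **meta)


@dataclass(frozen=True)
class GeneratorParams:
    """Population-level generator settings (SDs are relative to the template).

    The perturbation SDs (``sigma_sym``, ``sigma_lat``, ``sigma_trans``,
    ``sigma_petal``, ``tree_effect_sd``) are relative: a draw with SD ``s``
    offsets petal length by ``s * length`` standard deviations, width by
    ``s * width``, and tip shape by ``0.3 * s``.  ``sigma_imaging`` and
    ``sigma_digit`` are absolute point jitters in digitiser units.
    """

    n_trees_per_sex: int = 8
    flowers_per_tree: int | tuple = DEFAULT_FLOWERS_PER_TREE
    n_imaging: int = 2
    n_digitisation: int = 2
    sigma_sym: float = 0.153
    sigma_lat: float = 0.063
    sigma_trans: float = 0.0382
    sigma_petal: float = 0.004
    sigma_imaging: float = 0.8
    sigma_digit: float = 0.8
    female_size_factor: float = 0.845
    female_asym_factor: float = 1.27
    tree_effect_sd: float = 0.088
    seed: int = 0
    base_template: PetalTemplate = field(default_factory=PetalTemplate)
    n_points: int = 50

    def validate(self) -> None:
        for name in ("sigma_sym", "sigma_lat", "sigma_trans", "sigma_petal",
                     "sigma_imaging", "sigma_digit", "tree_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_trees_per_sex < 1 or self.n_imaging < 1 or self.n_digitisation < 1:
            raise ValueError("counts must be >= 1")
        if self.female_size_factor <= 0:
            raise ValueError("female_size_factor must be > 0")

    def flowers_for(self, tree_index: int) -> int:
        """Flower count for global tree index (females first)."""
        if isinstance(self.flowers_per_tree, int):
            return self.flowers_per_tree
        counts = tuple(self.flowers_per_tree)
        if len(counts) != 2 * self.n_trees_per_sex:
            raise ValueError(
                f"flowers_per_tree lists {len(counts)} trees, design has "
                f"{2 * self.n_trees_per_sex}"
            )
        return counts[tree_index]


def _draw_shape_offsets(rng: np.random.Generator, sigma: float,
                        template: PetalTemplate) -> np.ndarray:
    """Size-neutral coordinated draw on (length, width, tip).

    Elongation (length up, width down, and vice versa) plus an independent
    tip-shape component: the corolla's centroid size is unchanged to first
    order, so inter-flower and inter-tree shape variation does not contaminate
    the size dimorphism imposed by ``female_size_factor``.
    """
    z_elong, z_tip = rng.standard_normal(2)
    return sigma * np.array([template.length * z_elong,
                             -template.width * z_elong,
                             0.3 * z_tip])


def _draw_contrast_offsets(rng: np.random.Generator, sigma: float,
                           template: PetalTemplate,
                           with_skew: bool = False) -> np.ndarray:
    """Independent draw on (length, width, tip[, skew]) at relative SD sigma.

    Used for the petal-contrast patterns (whose alternating signs cancel any
    first-order size change across the corolla) and for per-petal noise.
    """
    dim = 4 if with_skew else 3
    scale = np.array([template.length, template.width, 0.3, 0.3])[:dim]
    return sigma * scale * rng.standard_normal(dim)


def _offsets_to_kwargs(vec: np.ndarray) -> dict:
    keys = ("d_length", "d_width", "d_tip", "d_skew")
    return {k: float(v) for k, v in zip(keys, vec)}


def generate_population(params: GeneratorParams) -> tuple[Dataset, dict]:
    """Simulate a full nested sample of corolla configurations.

    Returns the dataset (``n_trees_per_sex * 2`` trees' flowers, each flower
    as ``n_imaging * n_digitisation`` configurations, object ids ``0001``...)
    and a ground-truth record of every latent draw for parameter-recovery
    tests.  Identical params (including seed) give identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    tpl = params.base_template
    base_cs = centroid_size(generate_corolla(tpl, n_points=params.n_points).points)
    configs: list[Configuration] = []
    truth: dict = {"params": {k: (v if not isinstance(v, PetalTemplate)
                                  else dataclasses.asdict(v))
                              for k, v in dataclasses.asdict(params).items()},
                   "trees": {}}

    obj_counter = 0
    tree_index = 0
    for sex in ("female", "hermaphrodite"):
        asym = params.female_asym_factor if sex == "female" else 1.0
        size = params.female_size_factor if sex == "female" else 1.0
        for t in range(params.n_trees_per_sex):
            tree_id = f"{sex}{t + 1}"
            tree_offset = _draw_shape_offsets(rng, params.tree_effect_sd, tpl)
            tree_truth = {"offset": tree_offset.tolist(), "flowers": {}}
            for f in range(params.flowers_for(tree_index)):
                flower_id = f"{tree_id}_f{f + 1:02d}"
                sym = _draw_shape_offsets(rng, params.sigma_sym, tpl)
                lat = [_draw_contrast_offsets(rng, asym * params.sigma_lat, tpl)
                       for _ in LATERAL_PATTERNS]
                trans = _draw_contrast_offsets(rng, asym * params.sigma_trans, tpl)
                petal_noise = [
                    _draw_contrast_offsets(rng, params.sigma_petal, tpl,
                                           with_skew=True)
                    for _ in range(4)
                ]
                per_petal = []
                for p in range(4):
                    vec = np.zeros(4)
                    vec[:3] += tree_offset + sym
                    for pat, draw in zip(LATERAL_PATTERNS, lat):
                        vec[:3] += pat[p] * draw
                    vec[:3] += TRANSVERSAL_PATTERN[p] * trans
                    vec += petal_noise[p]
                    per_petal.append(vec)
                tree_truth["flowers"][flower_id] = {
                    "symmetric": sym.tolist(),
                    "lateral": [d.tolist() for d in lat],
                    "transversal": trans.tolist(),
                    "petal_noise": [d.tolist() for d in petal_noise],
                }

                clean = generate_corolla(
                    tpl,
                    [_offsets_to_kwargs(v) for v in per_petal],
                    n_points=params.n_points,
                )
                # normalise the noise-free corolla to the template's centroid
                # size, so female_size_factor is the only systematic size
                # signal (shape perturbations are size-neutral by design)
                clean_pts = clean.points * (
                    size * base_cs / centroid_size(clean.points))

                for im in range(1, params.n_imaging + 1):
                    angle = rng.uniform(0.0, 2.0 * np.pi)
                    shift = rng.normal(0.0, 0.1 * tpl.length, size=2)
                    photo_jitter = rng.normal(0.0, params.sigma_imaging,
                                              size=clean_pts.shape)
                    c, s = np.cos(angle), np.sin(angle)
                    rot = np.array([[c, -s], [s, c]])
                    photo_pts = (clean_pts + photo_jitter) @ rot.T + shift
                    for dig in range(1, params.n_digitisation + 1):
                        pts = photo_pts.copy()
                        if params.sigma_digit > 0:
                            # tangential jitter, petal blocks treated separately
                            # so tangents never bridge petals
                            npp = params.n_points
                            for p in range(4):
                                blk = photo_pts[p * npp:(p + 1) * npp]
                                tang = np.gradient(blk, axis=0)
                                norm = np.linalg.norm(tang, axis=1, keepdims=True)
                                norm[norm == 0.0] = 1.0
                                amt = rng.normal(0.0, params.sigma_digit, size=npp)
                                pts[p * npp:(p + 1) * npp] = \
                                    blk + amt[:, None] * tang / norm
                        obj_counter += 1
                        configs.append(Configuration(
                            points=pts,
                            object_id=f"{obj_counter:04d}",
                            flower_id=flower_id,
                            tree_id=tree_id,
                            sex=sex,
                            imaging_rep=im,
                            digitisation_rep=dig,
                        ))
            truth["trees"][tree_id] = tree_truth
            tree_index += 1

    return Dataset(configs, n_petals=4, points_per_petal=params.n_points), truth


def write_population(dataset: Dataset, truth: dict, out_dir: str | Path) -> dict:
    """Write TPS landmarks, sidecar metadata CSV and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tps": out / "landmarks.tps",
        "metadata": out / "metadata.csv",
        "truth": out / "ground_truth.json",
    }
    write_tps(dataset, paths["tps"])
    write_metadata(dataset, paths["metadata"])
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return {k: str(v) for k, v in paths.items()}
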