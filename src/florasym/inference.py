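"""Permutation inference for size and shape in a fully nested design.

Four tools around the morphometric pipeline:

* :func:`nested_anova` — type-I (sequential) ANOVA for a scalar (centroid
  size) or multivariate (Procrustes shape coordinate) response under a fully
  nested design, e.g. sex / tree(sex) / flower(tree) / imaging / digitisation.
  Sums of squares at each level are the summed squared deviations of that
  level's group means from their parent-level means (summed over coordinates
  for shape); each F ratio uses the mean square of the immediately nested
  effect as denominator, and p-values come from restricted permutations of the
  exchangeable units of that nested level.
* :func:`goodall_regression` — multivariate regression of shape on a binary
  factor, tested with Goodall's F (between- over within-group Procrustes
  variance with df 1 and n-2) under label permutation.
* :func:`dispersion_test` — homogeneity of multivariate dispersions, the
  multivariate analogue of Levene's test: each point's Euclidean distance to
  its group centroid is computed in a score subspace, a one-way ANOVA F on
  those distances is the statistic, and group assignments of an exchangeable
  unit (flower or configuration) are permuted.
* :func:`nmds` — two-dimensional non-metric multidimensional scaling with
  Kruskal stress-1, used to visualise per-group dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats
from sklearn.manifold import smacof

__all__ = [
    "AnovaTable",
    "RegressionResult",
    "DispersionResult",
    "NmdsResult",
    "nested_anova",
    "goodall_regression",
    "dispersion_test",
    "nmds",
    "dispersion_rejection_rate",
]


# ---------------------------------------------------------------------------
# Nested permutation ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Sequential nested ANOVA: one row per effect plus the residual and total."""

    table: pd.DataFrame  # columns: effect, df, SS, MS, eta2, F, p

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string(index=False)

    def row(self, effect: str) -> pd.Series:
        hit = self.table[self.table["effect"] == effect]
        if hit.empty:
            raise KeyError(f"no effect {effect!r} in table")
        return hit.iloc[0]


def _group_codes(labels: pd.Series | np.ndarray) -> np.ndarray:
    return pd.factorize(np.asarray(labels))[0]


def _level_ss(resp: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Sum over groups of ||group sum||^2 / group size (the 'uncorrected' SS)."""
    d = resp.shape[1]
    sums = np.zeros((n_groups, d))
    np.add.at(sums, codes, resp)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    return float(np.sum(np.sum(sums ** 2, axis=1) / counts))


def _sequential_ss(resp: np.ndarray, level_codes: list[np.ndarray]) -> np.ndarray:
    """SS explained at each nesting level plus the residual.

    ``level_codes`` is ordered coarse to fine (e.g. sex, tree, flower, photo);
    returns ``len(level_codes) + 1`` values summing exactly to the total SS.
    """
    n = resp.shape[0]
    uncorrected = [np.sum(resp.sum(axis=0) ** 2) / n]  # grand-mean level
    for codes in level_codes:
        uncorrected.append(_level_ss(resp, codes, codes.max() + 1))
    uncorrected.append(float(np.sum(resp ** 2)))       # per-row level
    return np.diff(uncorrected)


def _nest_codes(meta: pd.DataFrame, factors: list[str]) -> list[np.ndarray]:
    """Cumulative group codes: level i groups rows by factors[:i+1]."""
    codes = []
    key = None
    for f in factors:
        col = meta[f].astype(str)
        key = col if key is None else key + "/" + col
        codes.append(_group_codes(key))
    return codes


def nested_anova(
    response: np.ndarray,
    design: pd.DataFrame,
    factors: list[str] | None = None,
    effect_names: list[str] | None = None,
    residual_name: str = "digitising error",
    n_perm: int = 999,
    seed: int | np.random.Generator | None = 0,
    scheme: str = "nested",
) -> AnovaTable:
    """Sequential nested permutation ANOVA.

    ``response`` is ``(n,)`` for size or ``(n, d)`` / ``(n, k, 2)`` for shape;
    ``design`` holds one column per factor; ``factors`` are ordered coarse to
    fine (default ``["sex", "tree", "flower", "imaging"]``, residual =
    digitisation).  The F for each effect uses the next effect's MS (the
    residual MS for the last factor); the residual row has no F.

    ``scheme='nested'`` permutes, for each effect, the exchangeable units of
    the immediately nested level within the enclosing stratum (trees across
    sexes; flowers across trees within their sex; photographs across flowers
    within their tree; digitisation rows across photographs within their
    flower).  ``scheme='rows'`` permutes raw rows freely for every effect.
    """
    if factors is None:
        factors = ["sex", "tree", "flower", "imaging"]
    if effect_names is None:
        effect_names = {
            ("sex", "tree", "flower", "imaging"):
                ["Sex", "Tree (sex)", "Flower (tree)", "Imaging error"],
        }.get(tuple(factors), list(factors))
    if scheme not in ("nested", "rows"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    resp = np.asarray(response, float)
    if resp.ndim == 1:
        resp = resp[:, None]
    elif resp.ndim == 3:
        resp = resp.reshape(resp.shape[0], -1)
    n = resp.shape[0]
    if len(design) != n:
        raise ValueError("design table does not match response length")
    resp = resp - resp.mean(axis=0)  # SS relative to the grand mean

    codes = _nest_codes(design, factors)
    n_levels = [c.max() + 1 for c in codes]
    ss = _sequential_ss(resp, codes)
    df = np.diff([1] + n_levels + [n]).astype(float)
    ss_total = float(np.sum(resp ** 2))

    with np.errstate(invalid="ignore", divide="ignore"):
        ms = np.where(df > 0, ss / df, np.nan)
    n_eff = len(factors)
    f_stats = np.full(n_eff, np.nan)
    for i in range(n_eff):
        if df[i] > 0 and df[i + 1] > 0 and ms[i + 1] > 0:
            f_stats[i] = ms[i] / ms[i + 1]

    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    p_values = np.full(n_eff, np.nan)
    if n_perm > 0 and ss_total > 0:
        for i in range(n_eff):
            if not np.isfinite(f_stats[i]):
                continue
            f_perm = _permute_effect(resp, codes, i, n, n_perm, rng, scheme)
            p_values[i] = (1.0 + np.sum(f_perm >= f_stats[i] - 1e-12)) \
                / (n_perm + 1.0)

    rows = []
    for i in range(n_eff):
        rows.append((effect_names[i], int(df[i]), ss[i], ms[i],
                     ss[i] / ss_total if ss_total > 0 else np.nan,
                     f_stats[i], p_values[i]))
    rows.append((residual_name, int(df[-1]), ss[-1], ms[-1],
                 ss[-1] / ss_total if ss_total > 0 else np.nan,
                 np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, np.nan, np.nan, np.nan, np.nan))
    return AnovaTable(pd.DataFrame(
        rows, columns=["effect", "df", "SS", "MS", "eta2", "F", "p"]))


def _permute_effect(resp, codes, i, n, n_perm, rng, scheme) -> np.ndarray:
    """Permutation F distribution for effect *i* (0-based, coarse to fine)."""
    fine = codes[i + 1] if i + 1 < len(codes) else np.arange(n)  # units permuted
    coarse = codes[i]                                            # groups they move between
    stratum = codes[i - 1] if i > 0 else np.zeros(n, dtype=int)  # enclosing level
    above = codes[i - 1] if i > 0 else None

    n_units = fine.max() + 1
    d = resp.shape[1]
    unit_sums = np.zeros((n_units, d))
    np.add.at(unit_sums, fine, resp)
    unit_counts = np.bincount(fine, minlength=n_units).astype(float)
    # per-unit fixed labels (units are nested, so these are well defined)
    first = np.full(n_units, -1, dtype=int)
    first[fine[::-1]] = np.arange(n)[::-1]
    unit_coarse = coarse[first]
    unit_stratum = stratum[first]

    n_coarse = coarse.max() + 1
    n_above = int(stratum.max()) + 1

    # SS pieces that do not move under this permutation
    ss_above = np.sum(resp.sum(axis=0) ** 2) / n if above is None \
        else _level_ss(resp, above, above.max() + 1)
    ss_fine_level = _level_ss(resp, fine, n_units) if i + 1 < len(codes) \
        else float(np.sum(resp ** 2))
    df_coarse = n_coarse - (1 if above is None else above.max() + 1)
    df_fine = n_units - n_coarse if i + 1 < len(codes) else n - n_coarse

    strata_units = [np.flatnonzero(unit_stratum == s) for s in range(n_above)]

    f_out = np.empty(n_perm)
    for b in range(n_perm):
        if scheme == "rows":
            ss_perm = _sequential_ss(resp[rng.permutation(n)], codes)
            num = ss_perm[i]
            den = ss_perm[i + 1]
            df_num = df_coarse
            df_den = df_fine
        else:
            perm_coarse = unit_coarse.copy()
            for units in strata_units:
                perm_coarse[units] = unit_coarse[units[rng.permutation(len(units))]]
            gsums = np.zeros((n_coarse, d))
            np.add.at(gsums, perm_coarse, unit_sums)
            gcounts = np.bincount(perm_coarse, weights=unit_counts,
                                  minlength=n_coarse)
            ss_coarse_lvl = float(np.sum(np.sum(gsums ** 2, axis=1) / gcounts))
            num = ss_coarse_lvl - ss_above
            den = ss_fine_level - ss_coarse_lvl
            df_num = df_coarse
            df_den = df_fine
        with np.errstate(invalid="ignore", divide="ignore"):
            f_out[b] = (num / df_num) / (den / df_den) if den > 0 else np.inf
    return f_out


# ---------------------------------------------------------------------------
# Goodall's F regression on a binary factor
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    f_statistic: float
    p_value: float
    percent_variance: float
    group_means: dict[str, np.ndarray]
    n_perm: int


def goodall_regression(
    shapes: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = 0,
) -> RegressionResult:
    """Multivariate regression of shape on a binary factor via Goodall's F.

    ``F = (SS_between / 1) / (SS_within / (n - 2))`` on Procrustes
    coordinates; the p-value is the fraction of label permutations (observed
    statistic included) with F at least as large.
    """
    resp = np.asarray(shapes, float)
    if resp.ndim == 3:
        resp = resp.reshape(resp.shape[0], -1)
    elif resp.ndim == 1:
        resp = resp[:, None]
    groups = np.asarray(groups)
    levels, codes = np.unique(groups, return_inverse=True)
    if len(levels) != 2:
        raise ValueError(f"binary factor required, got levels {levels.tolist()}")
    counts = np.bincount(codes)
    if counts.min() == 0:
        raise ValueError("one group is empty")
    n = resp.shape[0]

    centred = resp - resp.mean(axis=0)
    ss_total = float(np.sum(centred ** 2))

    def f_of(code_vec: np.ndarray) -> tuple[float, float]:
        sums = np.zeros((2, centred.shape[1]))
        np.add.at(sums, code_vec, centred)
        cnts = np.bincount(code_vec, minlength=2).astype(float)
        ss_b = float(np.sum(np.sum(sums ** 2, axis=1) / cnts))
        ss_w = ss_total - ss_b
        return (ss_b / 1.0) / (ss_w / (n - 2)) if ss_w > 0 else np.inf, ss_b

    f_obs, ss_between = f_of(codes)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    exceed = 1  # the observed permutation
    for _ in range(n_perm):
        f_b, _ = f_of(rng.permutation(codes))
        if f_b >= f_obs - 1e-12:
            exceed += 1
    p = exceed / (n_perm + 1.0)

    means = {str(lv): resp[codes == j].mean(axis=0) for j, lv in enumerate(levels)}
    return RegressionResult(
        f_statistic=float(f_obs),
        p_value=float(p),
        percent_variance=float(100.0 * ss_between / ss_total) if ss_total > 0 else 0.0,
        group_means=means,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Homogeneity of multivariate dispersions (Levene analogue)
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    group_means: dict[str, float]   # mean distance to group centroid
    difference: float               # first group minus second (sorted labels)
    ci_lower: float
    ci_upper: float
    f_statistic: float
    p_value: float
    n_perm: int
    permute_unit: str
    distances: np.ndarray
    groups: np.ndarray


def _anova_f_1d(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = values.shape[0]
    sums = np.bincount(codes, weights=values, minlength=n_groups)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    grand = values.sum()
    ss_b = float(np.sum(sums ** 2 / counts) - grand ** 2 / n)
    ss_t = float(np.sum(values ** 2) - grand ** 2 / n)
    ss_w = ss_t - ss_b
    df_b, df_w = n_groups - 1, n - n_groups
    if ss_w <= 0 or df_w <= 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / df_b) / (ss_w / df_w)


def dispersion_test(
    scores: np.ndarray,
    groups,
    permute_unit: str = "flower",
    flower_ids=None,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = 0,
) -> DispersionResult:
    """Levene-analogue test for homogeneity of multivariate dispersions.

    Each point's Euclidean distance to its own group centroid (in the score
    subspace) is the dispersion measure; the statistic is the one-way ANOVA F
    on those distances.  The p-value permutes group assignments of the chosen
    exchangeable unit: ``'flower'`` keeps all rows of one flower (symmetry
    copies and replicate digitisations) together, ``'configuration'`` permutes
    rows freely.  The 95% CI of the difference in mean distances is the
    pooled two-sample t interval.
    """
    x = np.asarray(scores, float)
    if x.ndim == 1:
        x = x[:, None]
    groups = np.asarray(groups)
    levels, codes = np.unique(groups, return_inverse=True)
    n_groups = len(levels)
    if n_groups < 2 or np.bincount(codes).min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    if permute_unit not in ("flower", "configuration"):
        raise ValueError(f"unknown permute_unit {permute_unit!r}")
    if permute_unit == "flower" and flower_ids is None:
        raise ValueError("permute_unit='flower' requires flower_ids")

    centroids = np.stack([x[codes == g].mean(axis=0) for g in range(n_groups)])
    dist = np.linalg.norm(x - centroids[codes], axis=1)

    f_obs = _anova_f_1d(dist, codes, n_groups)

    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if permute_unit == "flower":
        flower_ids = np.asarray(flower_ids)
        units, unit_of_row = np.unique(flower_ids, return_inverse=True)
        # group label of each unit (flowers never straddle groups)
        unit_code = np.full(len(units), -1, dtype=int)
        unit_code[unit_of_row] = codes
        exceed = 1
        for _ in range(n_perm):
            perm = rng.permutation(unit_code)
            if _anova_f_1d(dist, perm[unit_of_row], n_groups) >= f_obs - 1e-12:
                exceed += 1
    else:
        exceed = 1
        for _ in range(n_perm):
            if _anova_f_1d(dist, rng.permutation(codes), n_groups) >= f_obs - 1e-12:
                exceed += 1
    p = exceed / (n_perm + 1.0)

    means = {str(lv): float(dist[codes == g].mean())
             for g, lv in enumerate(levels)}
    d0, d1 = dist[codes == 0], dist[codes == 1]
    diff = float(d0.mean() - d1.mean())
    n0, n1 = len(d0), len(d1)
    sp2 = ((n0 - 1) * d0.var(ddof=1) + (n1 - 1) * d1.var(ddof=1)) / (n0 + n1 - 2)
    se = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    tcrit = scipy.stats.t.ppf(0.975, n0 + n1 - 2)
    return DispersionResult(
        group_means=means,
        difference=diff,
        ci_lower=float(diff - tcrit * se),
        ci_upper=float(diff + tcrit * se),
        f_statistic=float(f_obs),
        p_value=float(p),
        n_perm=n_perm,
        permute_unit=permute_unit,
        distances=dist,
        groups=groups,
    )


def dispersion_rejection_rate(
    n_datasets: int,
    n_per_group: int = 20,
    dim: int = 4,
    scale_second_group: float = 1.0,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Monte-Carlo rejection rate of the dispersion test (calibration/power).

    Each simulated dataset holds two isotropic Gaussian groups of
    ``n_per_group`` points in ``dim`` dimensions; the second group's scores
    are multiplied by ``scale_second_group`` (1 = the null).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    groups = np.repeat(["a", "b"], n_per_group)
    rejections = 0
    for _ in range(n_datasets):
        x = rng.standard_normal((2 * n_per_group, dim))
        x[n_per_group:] *= scale_second_group
        res = dispersion_test(x, groups, permute_unit="configuration",
                              n_perm=n_perm, seed=rng)
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_datasets


# ---------------------------------------------------------------------------
# Non-metric multidimensional scaling
# ---------------------------------------------------------------------------

@dataclass
class NmdsResult:
    coordinates: np.ndarray
    stress: float               # Kruskal stress-1
    stress_history: list[float]
    iterations: int
    seed: int | None


def _classical_mds(dist: np.ndarray, dims: int) -> np.ndarray:
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def nmds(
    scores: np.ndarray,
    dims: int = 2,
    seed: int | None = 0,
    n_random_starts: int = 3,
    max_iter: int = 300,
    chunk: int = 25,
) -> NmdsResult:
    """Two-dimensional NMDS of score vectors, minimising Kruskal stress-1.

    Runs SMACOF in non-metric mode from a classical (metric) scaling start
    plus ``n_random_starts`` random starts and keeps the best solution.  The
    optimisation is chunked so a stress trajectory can be recorded; stress is
    non-increasing along it.  Deterministic for a fixed seed.
    """
    x = np.asarray(scores, float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 3:
        raise ValueError("NMDS needs at least 3 points")
    dist = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(x))

    rng = np.random.default_rng(seed)
    inits = [_classical_mds(dist, dims)]
    scale = max(dist.max(), 1e-12)
    for _ in range(n_random_starts):
        inits.append(rng.normal(0.0, scale / 4.0, size=(x.shape[0], dims)))

    best = None
    for init in inits:
        coords = init
        history = []
        total_iter = 0
        stress = np.inf
        for _ in range(int(np.ceil(max_iter / chunk))):
            new_coords, new_stress, n_it = smacof(
                dist, metric=False, n_components=dims, init=coords,
                n_init=1, max_iter=chunk, eps=1e-9,
                normalized_stress=True, return_n_iter=True,
            )
            if new_stress > stress:   # converged; keep the better embedding
                break
            coords, stress = new_coords, float(new_stress)
            history.append(stress)
            total_iter += n_it
            if len(history) > 1 and history[-2] - history[-1] < 1e-9:
                break
        if best is None or stress < best[1]:
            best = (coords, float(stress), history, total_iter)

    coords, stress, history, iters = best
    return NmdsResult(coordinates=coords, stress=stress,
                      stress_history=history, iterations=iters, seed=seed)
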