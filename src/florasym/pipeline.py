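"""One-command orchestration of the corolla symmetry workflow.

``run_study_pipeline`` executes the full analysis: read (or simulate)
landmark data, optionally check the petal labelling, expand every
configuration by its symmetry group, run GPA with sliding semilandmarks,
symmetrise, run the nested size and shape ANOVAs, the sex regression, the
symmetry decomposition with variance fractions and asymmetry scores, the
dispersion tests per subspace, and NMDS ordinations — writing every table to
the output directory together with the config that produced it.

A single global seed is split into independent per-stage seeds with
``numpy``'s SeedSequence spawning, so individual stages can be re-run in
isolation and still reproduce.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align, decomposition, inference, symmetry, synthetic, tps_io

__all__ = ["RunConfig", "run_study_pipeline", "load_config"]

log = logging.getLogger("florasym")

STAGES = ("simulate", "anova", "regression", "dispersion", "nmds")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialised verbatim into the output."""

    # input: either a TPS file + metadata CSV, or generator parameters
    tps_path: str | None = None
    metadata_path: str | None = None
    generator: synthetic.GeneratorParams | None = None

    out_dir: str = "florasym_out"
    seed: int = 0

    use_sliders: bool = True
    gpa_tol: float = 1e-6
    gpa_max_iter: int = 50
    slide_iter: int = 5

    n_perm_anova: int = 999
    n_perm_regression: int = 999
    n_perm_dispersion: int = 9999
    permute_unit: str = "flower"        # dispersion exchangeable unit
    score_mode: str = "norm"            # asymmetry score kind
    dispersion_mode: str = "per_configuration"  # points entering dispersion/NMDS
    run_nmds: bool = True
    nmds_max_points: int = 350          # subsample cap for the ordination
    validate_labeling: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            g = dataclasses.asdict(self.generator)
            g["base_template"] = dataclasses.asdict(self.generator.base_template)
            d["generator"] = g
        return d


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML or JSON."""
    raw = yaml.safe_load(Path(path).read_text())
    gen = raw.pop("generator", None)
    cfg = RunConfig(**raw)
    if gen is not None:
        tpl = gen.pop("base_template", None)
        if tpl is not None:
            gen["base_template"] = synthetic.PetalTemplate(**tpl)
        if "flowers_per_tree" in gen and isinstance(gen["flowers_per_tree"], list):
            gen["flowers_per_tree"] = tuple(gen["flowers_per_tree"])
        cfg.generator = synthetic.GeneratorParams(**gen)
    return cfg


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(STAGES, children)}


def _load_input(config: RunConfig, seeds: dict[str, int]) -> tps_io.Dataset:
    if config.tps_path is not None:
        log.info("reading landmarks from %s", config.tps_path)
        return tps_io.read_tps(config.tps_path, metadata=config.metadata_path)
    if config.generator is not None:
        params = dataclasses.replace(config.generator, seed=seeds["simulate"])
        log.info("simulating population (seed %d)", params.seed)
        data, _ = synthetic.generate_population(params)
        return data
    raise ValueError("config must provide either tps_path or generator params")


def run_study_pipeline(config: RunConfig) -> dict:
    """Run the complete workflow; returns the summary report dictionary."""
    out = Path(config.out_dir)
    seeds = _stage_seeds(config.seed)
    report: dict = {"seeds": seeds, "settings": {
        "permute_unit": config.permute_unit,
        "score_mode": config.score_mode,
        "dispersion_mode": config.dispersion_mode,
        "use_sliders": config.use_sliders,
    }}

    stage = "input"
    try:
        data = _load_input(config, seeds)
        if len(data) == 0:
            raise ValueError("empty input dataset")
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(),
                                                        sort_keys=True))
        report["n_configurations_raw"] = len(data)
        report["design"] = data.design_summary()

        if config.validate_labeling:
            stage = "validate-labeling"
            rec, _ = symmetry.validate_labeling(data)
            report["labeling"] = rec
            if rec["petal_offset"] != 0 or rec["reverse_petals"] \
                    or rec["reverse_within"]:
                log.warning("labeling check recommends remap %s", rec)

        stage = "symmetry expansion"
        expanded = symmetry.expand_symmetry_group(data)
        report["n_configurations_expanded"] = len(expanded)
        log.info("expanded %d -> %d configurations", len(data), len(expanded))

        stage = "GPA"
        sliders = align.default_slider_spec(data.n_petals, data.points_per_petal) \
            if config.use_sliders else None
        alignment = align.gpa(expanded, sliders=sliders, tol=config.gpa_tol,
                              max_iter=config.gpa_max_iter,
                              slide_iter=config.slide_iter)
        report["gpa_iterations"] = alignment.iterations
        report["gpa_slide_rounds"] = alignment.slide_iterations

        stage = "symmetrisation"
        sym_data, sym_coords = symmetry.symmetrise(expanded, alignment.aligned)
        sym_meta = sym_data.meta()

        stage = "size ANOVA"
        raw_cs = alignment.centroid_sizes[::4]  # one per raw object (identity first)
        anova_size = inference.nested_anova(
            raw_cs, sym_meta, n_perm=config.n_perm_anova,
            seed=seeds["anova"])
        anova_size.table.to_csv(out / "anova_size.csv", index=False)
        report["anova_size_df"] = anova_size.table["df"].tolist()

        by_sex = pd.Series(raw_cs).groupby(sym_meta["sex"].values).mean()
        if {"female", "hermaphrodite"} <= set(by_sex.index):
            report["female_cs_reduction_pct"] = float(
                100.0 * (1.0 - by_sex["female"] / by_sex["hermaphrodite"]))

        stage = "shape ANOVA"
        anova_shape = inference.nested_anova(
            sym_coords, sym_meta, n_perm=config.n_perm_anova,
            seed=seeds["anova"] + 1)
        anova_shape.table.to_csv(out / "anova_shape.csv", index=False)

        stage = "sex regression"
        # one symmetrised mean shape per flower: replicate photographs and
        # digitisations are not independent units for the sex contrast
        flower_codes, flower_idx = pd.factorize(sym_meta["flower"])
        flower_shapes = np.zeros((len(flower_idx),) + sym_coords.shape[1:])
        np.add.at(flower_shapes, flower_codes, sym_coords)
        flower_shapes /= np.bincount(flower_codes)[:, None, None]
        flower_sex = sym_meta.groupby("flower", sort=False)["sex"].first() \
            .reindex(flower_idx).values
        regression = inference.goodall_regression(
            flower_shapes, flower_sex,
            n_perm=config.n_perm_regression, seed=seeds["regression"])
        (out / "regression.json").write_text(json.dumps({
            "goodall_F": regression.f_statistic,
            "p_value": regression.p_value,
            "percent_variance": regression.percent_variance,
            "n_perm": regression.n_perm,
        }, indent=1))
        report["goodall_F"] = regression.f_statistic
        report["regression_percent_variance"] = regression.percent_variance

        stage = "symmetry decomposition"
        dec = decomposition.shape_pca(alignment, data.n_petals,
                                      data.points_per_petal)
        dec = decomposition.classify_components(dec)
        dec.to_frame().to_csv(out / "decomposition.csv", index=False)
        fractions = decomposition.variance_fractions(dec)
        report["variance_fractions"] = fractions

        scores = decomposition.asymmetry_scores(
            dec, expanded, mode="per_flower", score_kind=config.score_mode)
        scores.table.to_csv(out / "asymmetry_scores.csv", index=False)

        stage = "dispersion tests"
        exp_meta = expanded.meta()
        if config.dispersion_mode == "per_configuration":
            disp_meta = exp_meta
            pc_scores = dec.scores
        elif config.dispersion_mode == "identity_only":
            # one row per raw digitised configuration (mirror copies dropped;
            # averaging them would cancel the asymmetric scores)
            mask = (exp_meta["transform"] == "identity").values
            disp_meta = exp_meta[mask].reset_index(drop=True)
            pc_scores = dec.scores[mask]
        else:
            raise ValueError(
                f"unknown dispersion_mode {config.dispersion_mode!r}")
        dispersion = {}
        for j, label in enumerate(decomposition.SUBSPACES):
            cols = dec.pcs_with_label(label)
            if len(cols) == 0:
                continue
            res = inference.dispersion_test(
                pc_scores[:, cols], disp_meta["sex"].values,
                permute_unit=config.permute_unit,
                flower_ids=disp_meta["flower"].values,
                n_perm=config.n_perm_dispersion,
                seed=seeds["dispersion"] + j)
            dispersion[label] = res
            (out / f"dispersion_{label}.json").write_text(json.dumps({
                "group_mean_distance": res.group_means,
                "difference": res.difference,
                "ci_95": [res.ci_lower, res.ci_upper],
                "F": res.f_statistic,
                "p_value": res.p_value,
                "n_perm": res.n_perm,
                "permute_unit": res.permute_unit,
            }, indent=1))
        report["dispersion"] = {
            label: {"group_means": res.group_means,
                    "difference": res.difference,
                    "p_value": res.p_value}
            for label, res in dispersion.items()
        }

        if config.run_nmds:
            stage = "NMDS"
            report["nmds_stress"] = {}
            rng = np.random.default_rng(seeds["nmds"])
            for label in decomposition.SUBSPACES:
                cols = dec.pcs_with_label(label)
                if len(cols) == 0:
                    continue
                pts = dec.scores[:, cols]
                idx = np.arange(pts.shape[0])
                if pts.shape[0] > config.nmds_max_points:
                    idx = np.sort(rng.choice(pts.shape[0],
                                             config.nmds_max_points,
                                             replace=False))
                res = inference.nmds(pts[idx], dims=2,
                                     seed=seeds["nmds"] + len(report["nmds_stress"]))
                coords = pd.DataFrame(res.coordinates, columns=["nmds1", "nmds2"])
                coords.insert(0, "object_id", exp_meta["object_id"].values[idx])
                coords["sex"] = exp_meta["sex"].values[idx]
                coords.to_csv(out / f"nmds_{label}.csv", index=False)
                report["nmds_stress"][label] = res.stress
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    log.info("pipeline complete; outputs in %s", out)
    return report
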