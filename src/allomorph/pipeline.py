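"""End-to-end per-sex allometry analysis.

Runs, for each requested sex: superimposition, size ANOVA, shape PCA,
PC selection, MANOVA, CVA, evolutionary / pooled-within / per-population
allometric regressions, the angle test between the evolutionary and
pooled-within vectors, the Monte-Carlo mean-angle test among
per-population vectors, and CVA of the non-allometric shape component.
All result tables are written as plain delimited text with a manifest,
so runs are diff-able; identical inputs and config give identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import allometry as allo
from . import group_tests, ordination, vector_stats
from .gpa import AlignedSample, gpa_align, shape_space_dim
from .io import ShapeDataset, read_landmark_table, read_tps, subset, write_landmark_table

__all__ = ["AnalysisConfig", "SexResult", "run_full_analysis", "load_dataset"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of a full analysis run.

    ``dim_p`` is the shape-space dimension used by the angle nulls;
    ``None`` means 2k - 4.  ``joint_alignment`` superimposes all sexes
    together before splitting (default: each sex aligned separately,
    since all reported results are per-sex).
    """

    input_path: str | None = None
    input_format: str = "table"  # "table" | "tps"
    sexes: tuple[str, ...] = ("female", "male")
    adults_only: bool = True
    pc_threshold: float = 0.90
    dim_p: int | None = None
    n_reps: int = 10_000
    seed: int = 0
    n_perm: int = 999
    output_dir: str | None = None
    flip_y: bool = False
    joint_alignment: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.pc_threshold <= 1:
            raise ValueError(f"pc_threshold must be in (0, 1], got {self.pc_threshold}")
        if self.n_reps < 1000:
            raise ValueError(f"n_reps must be >= 1000, got {self.n_reps}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sexes" in raw:
            raw["sexes"] = tuple(raw["sexes"])
        return cls(**raw)


@dataclass
class SexResult:
    """All computed results for one sex."""

    sex: str
    aligned: AlignedSample
    anova: group_tests.AnovaResult
    pca: ordination.PcaResult
    selected_pcs: np.ndarray
    manova: group_tests.ManovaResult
    cva: ordination.CvaResult
    evolutionary: allo.AllometricModel
    pooled_within: allo.AllometricModel
    per_population: dict[str, allo.AllometricModel]
    evo_within_angle: vector_stats.AngleTestResult
    mean_within_angle: vector_stats.AngleTestResult
    residual_cva: ordination.CvaResult
    summary: dict[str, Any] = field(default_factory=dict)


def load_dataset(config: AnalysisConfig) -> ShapeDataset:
    if config.input_path is None:
        raise ValueError("config has no input_path")
    if config.input_format == "tps":
        dataset = read_tps(config.input_path)
    elif config.input_format == "table":
        dataset = read_landmark_table(config.input_path)
    else:
        raise ValueError(f"unknown input format {config.input_format!r}")
    if config.flip_y:
        dataset = dataset.flip_y()
    return dataset


def _analyse_sex(
    sex: str, aligned: AlignedSample, config: AnalysisConfig
) -> SexResult:
    groups = aligned.populations()
    dim_p = config.dim_p if config.dim_p is not None else shape_space_dim(aligned.k)

    anova = group_tests.one_way_anova(aligned.ln_cs, groups)
    pca_result = ordination.shape_pca(aligned)
    selected = ordination.select_pcs_by_variance(pca_result, config.pc_threshold)
    manova = group_tests.manova_wilks(pca_result.scores[:, selected], groups)
    cva_result = ordination.cva(aligned.shapes, groups)

    evolutionary = allo.evolutionary_allometry(aligned, groups)
    pooled = allo.pooled_within_allometry(aligned, groups)
    per_pop = allo.per_group_allometries(aligned, groups)

    evo_within = vector_stats.pairwise_angle_test(
        evolutionary.slope, pooled.slope, p=dim_p
    )
    mean_within = vector_stats.mean_pairwise_angle_test(
        [m.slope for m in per_pop.values()],
        p=dim_p,
        n_reps=config.n_reps,
        seed=config.seed,
    )
    residuals = allo.nonallometric_component(aligned, pooled, groups)
    residual_cva = ordination.cva(residuals, groups)

    summary = {
        "sex": sex,
        "n": int(aligned.n),
        "n_populations": int(len(per_pop)),
        "gpa_iterations": int(aligned.n_iterations),
        "anova_F": anova.F,
        "anova_p": anova.p_value,
        "n_pcs_selected": int(len(selected)),
        "wilks_lambda": manova.wilks_lambda,
        "manova_F": manova.F,
        "manova_p": manova.p_value,
        "cv1_percent_among": float(cva_result.percent_among[0]),
        "evolutionary_percent": evolutionary.percent_explained,
        "within_percent": pooled.percent_explained,
        "evo_within_angle_deg": evo_within.angle_deg,
        "evo_within_angle_p": evo_within.p_value,
        "mean_within_angle_deg": mean_within.angle_deg,
        "mean_within_angle_p": mean_within.p_value,
        "dim_p": int(dim_p),
    }
    return SexResult(
        sex=sex,
        aligned=aligned,
        anova=anova,
        pca=pca_result,
        selected_pcs=selected,
        manova=manova,
        cva=cva_result,
        evolutionary=evolutionary,
        pooled_within=pooled,
        per_population=per_pop,
        evo_within_angle=evo_within,
        mean_within_angle=mean_within,
        residual_cva=residual_cva,
        summary=summary,
    )


def run_full_analysis(
    config: AnalysisConfig, dataset: ShapeDataset | None = None
) -> dict[str, SexResult]:
    """Run the whole analysis for every configured sex.

    Returns a mapping sex -> SexResult; if ``config.output_dir`` is set,
    also writes all result tables, aligned coordinates, model vectors,
    predicted wireframe shapes, a manifest and a run log there.
    """
    if dataset is None:
        dataset = load_dataset(config)
    if config.adults_only:
        dataset = subset(dataset, lambda m: m.age_class == "adult")

    joint: AlignedSample | None = None
    if config.joint_alignment:
        joint = gpa_align(dataset)

    results: dict[str, SexResult] = {}
    for sex in config.sexes:
        sex_data = subset(dataset, lambda m, s=sex: m.sex == s)
        if len(sex_data) == 0:
            logger.info("no specimens for sex %r; skipped", sex)
            continue
        try:
            if joint is not None:
                mask = np.array([m.sex == sex for m in joint.meta])
                aligned = AlignedSample(
                    shapes=joint.shapes[mask],
                    centroid_sizes=joint.centroid_sizes[mask],
                    ln_cs=joint.ln_cs[mask],
                    consensus=joint.consensus,
                    meta=tuple(m for m in joint.meta if m.sex == sex),
                    n_iterations=joint.n_iterations,
                )
            else:
                aligned = gpa_align(sex_data)
            results[sex] = _analyse_sex(sex, aligned, config)
        except Exception as exc:
            raise RuntimeError(f"analysis failed for sex {sex!r}: {exc}") from exc

    if config.output_dir is not None:
        _write_bundle(results, config, Path(config.output_dir))
    return results


# ---------------------------------------------------------------- output

_FLOAT_FMT = "%.12g"


def _write_bundle(
    results: dict[str, SexResult], config: AnalysisConfig, outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        manifest.append(name)

    summaries = []
    for sex, res in results.items():
        tag = sex or "all"
        aligned_ds = res.aligned.to_dataset()
        aligned_path = outdir / f"{tag}_aligned.csv"
        write_landmark_table(aligned_ds, aligned_path)
        # append size columns for downstream use
        df = pd.read_csv(aligned_path)
        df["centroid_size"] = res.aligned.centroid_sizes
        df["ln_cs"] = res.aligned.ln_cs
        df.to_csv(aligned_path, index=False, float_format=_FLOAT_FMT)
        manifest.append(f"{tag}_aligned.csv")

        save(
            pd.DataFrame(
                {
                    "component": np.arange(1, res.pca.n_components + 1),
                    "eigenvalue": res.pca.eigenvalues,
                    "cum_variance": res.pca.cum_variance,
                }
            ),
            f"{tag}_pca_eigenvalues.csv",
        )
        save(
            pd.DataFrame(
                res.pca.scores,
                columns=[f"PC{i + 1}" for i in range(res.pca.scores.shape[1])],
            ),
            f"{tag}_pca_scores.csv",
        )
        cva_df = pd.DataFrame(
            res.cva.scores,
            columns=[f"CV{i + 1}" for i in range(res.cva.scores.shape[1])],
        )
        cva_df.insert(0, "population", res.aligned.populations())
        save(cva_df, f"{tag}_cva_scores.csv")
        save(
            pd.DataFrame(
                res.residual_cva.scores,
                columns=[f"CV{i + 1}" for i in range(res.residual_cva.scores.shape[1])],
            ),
            f"{tag}_nonallometric_cva_scores.csv",
        )

        models = {"evolutionary": res.evolutionary, "pooled_within": res.pooled_within}
        models.update({f"pop_{g}": m for g, m in res.per_population.items()})
        rows = []
        for name, m in models.items():
            for ci, (b0, b1) in enumerate(zip(m.intercept, m.slope)):
                rows.append([name, m.level, ci, b0, b1])
        save(
            pd.DataFrame(
                rows, columns=["model", "level", "coordinate", "intercept", "slope"]
            ),
            f"{tag}_allometric_models.csv",
        )
        save(
            pd.DataFrame(
                [
                    [name, m.level, m.n_units, m.percent_explained]
                    for name, m in models.items()
                ],
                columns=["model", "level", "n_units", "percent_explained"],
            ),
            f"{tag}_allometric_summary.csv",
        )

        # predicted wireframe shapes at the observed size extremes
        lo, hi = float(res.aligned.ln_cs.min()), float(res.aligned.ln_cs.max())
        wf_rows = []
        for name, m in models.items():
            sizes = (
                [res.evolutionary.mean_size, lo, hi]
                if m.level == "evolutionary"
                else [m.mean_size, lo, hi]
            )
            for s in sizes:
                wf_rows.append([name, s, *allo.predict_shape(m, s)])
        k = res.aligned.k
        coord_cols = [f"{a}{i}" for i in range(1, k + 1) for a in ("x", "y")]
        save(
            pd.DataFrame(wf_rows, columns=["model", "ln_cs", *coord_cols]),
            f"{tag}_wireframes.csv",
        )

        tests = pd.DataFrame(
            [
                ["anova_ln_cs", res.anova.F, res.anova.df_between, res.anova.df_within, res.anova.p_value, "", ""],
                ["manova_wilks", res.manova.wilks_lambda, res.manova.df1, res.manova.df2, res.manova.p_value, "", ""],
                [
                    "evo_vs_within_angle",
                    res.evo_within_angle.angle_deg,
                    res.evo_within_angle.dim,
                    "",
                    res.evo_within_angle.p_value,
                    res.evo_within_angle.null_kind,
                    "",
                ],
                [
                    "mean_within_angle",
                    res.mean_within_angle.angle_deg,
                    res.mean_within_angle.dim,
                    "",
                    res.mean_within_angle.p_value,
                    res.mean_within_angle.null_kind,
                    res.mean_within_angle.n_reps,
                ],
            ],
            columns=["test", "statistic", "df1_or_dim", "df2", "p_value", "null_kind", "n_reps"],
        )
        save(tests, f"{tag}_tests.csv")
        summaries.append(res.summary)

    pd.DataFrame(summaries).to_csv(
        outdir / "summary.csv", index=False, float_format=_FLOAT_FMT
    )
    manifest.append("summary.csv")

    log = {
        "config": dataclasses.asdict(config),
        "sexes_analysed": list(results),
        "gpa_iterations": {s: r.aligned.n_iterations for s, r in results.items()},
        "seed": config.seed,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")
    manifest.append("run_log.json")
    (outdir / "MANIFEST.txt").write_text("\n".join(sorted(manifest)) + "\n")
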