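"""End-to-end orchestration: simulate/load -> radiomics -> reduce -> screen
-> model search -> fusion -> leaderboards and a human-readable report.

A run directory is fully determined by its configuration (and the seed in
it): re-running with the same config reproduces every artifact byte for
byte.  Each stage writes its table so every number in the report can be
traced to an artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import CohortLabels, FeatureTable
from .model_search import (
    ModelResult,
    SearchConfig,
    clinical_baseline,
    fuse_multimodal,
    search_models,
)
from .radiomics import DiscretizationConfig, extract_feature_vector
from .selection import reduce_redundancy, wilcoxon_screen
from .synthetic import CohortSpec, MatchedCohort, gen_matched_cohort


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters of one discovery run.

    With ``cohort_dir`` unset, a synthetic matched cohort is generated from
    the ``cohort`` spec; otherwise NIfTI/CSV inputs are read from the
    directory layout produced by :func:`mmdiscover.synthetic.write_cohort`.
    """

    out_dir: str = "run"
    cohort_dir: str | None = None
    cohort: CohortSpec = dataclasses.field(default_factory=CohortSpec)
    contrast: str = "3+3 vs >=3+4"
    r2_threshold: float = 0.99
    alpha: float = 0.05
    train_fraction: float = 0.8
    n_repeats: int = 200
    max_subset_size: int = 1
    prescreen_top: int | None = 25
    k_top: int = 2
    n_levels: int = 32
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        spec = CohortSpec(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("cohort", {}).items()
        })
        return cls(cohort=spec, **raw)

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            max_subset_size=self.max_subset_size,
            train_fraction=self.train_fraction,
            n_repeats=self.n_repeats,
            ridge_penalty=1e-4,
            seed=self.seed,
            prescreen_top=self.prescreen_top,
        )


def _load_cohort(cohort_dir: Path, spec: CohortSpec) -> MatchedCohort:
    from .containers import RoiMask, VolumetricImage
    from .synthetic import GroundTruth

    mirna = FeatureTable.from_csv(cohort_dir / "mirna.csv", "miRNA")
    clinical = FeatureTable.from_csv(cohort_dir / "clinical.csv", "clinical")
    lab = pd.read_csv(cohort_dir / "labels.csv", index_col="sample_id")["gleason"]
    lab.index = lab.index.astype(str)
    vols = {}
    for mod in ("T2W", "ADC"):
        d = cohort_dir / mod
        vols[mod] = {
            p.name.removesuffix("_img.nii.gz"): (
                VolumetricImage.from_nifti(p),
                RoiMask.from_nifti(d / p.name.replace("_img", "_mask")),
            )
            for p in sorted(d.glob("*_img.nii.gz"))
        }
    truth = GroundTruth([], [], {})
    return MatchedCohort(mirna, vols["T2W"], vols["ADC"], clinical, CohortLabels(lab), truth)


def radiomics_table(
    volumes: dict, modality: str, cfg: DiscretizationConfig
) -> FeatureTable:
    """Per-sample radiomic feature rows for one imaging modality."""
    rows = {sid: extract_feature_vector(img, mask, cfg) for sid, (img, mask) in volumes.items()}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return FeatureTable(df, modality)


def _leaderboard_frame(results: list[ModelResult]) -> pd.DataFrame:
    rows = []
    for rank, m in enumerate(results, start=1):
        d = m.to_dict()
        d["rank"] = rank
        d["features"] = "; ".join(m.feature_ids)
        d["Sensitivity/Specificity"] = f"{m.sensitivity:.3g}/{m.specificity:.3g}"
        d["PPV/NPV"] = f"{m.ppv:.3g}/{m.npv:.3g}"
        d["AUC [CI], SD"] = (
            f"{m.auc_mean:.3g} [{m.auc_ci[0]:.3g}-{m.auc_ci[1]:.3g}], {m.auc_sd:.3g}"
        )
        del d["feature_ids"]
        rows.append(d)
    cols = [
        "rank", "features", "Sensitivity/Specificity", "PPV/NPV", "AUC [CI], SD",
        "sensitivity", "specificity", "ppv", "npv",
        "auc_mean", "auc_ci_low", "auc_ci_high", "auc_sd", "youden_j", "n_repeats",
    ]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the populated run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate/load"
    try:
        if config.cohort_dir is None:
            cohort = gen_matched_cohort(config.cohort)
        else:
            cohort = _load_cohort(Path(config.cohort_dir), config.cohort)
        labels = CohortLabels(cohort.labels.gleason, config.contrast)
        disc = DiscretizationConfig(n_levels=config.n_levels)

        stage = "radiomics"
        tables = {
            "miRNA": cohort.mirna,
            "T2W": radiomics_table(cohort.t2w_volumes, "T2W", disc),
            "ADC": radiomics_table(cohort.adc_volumes, "ADC", disc),
        }
        for name, t in tables.items():
            t.to_csv(out / f"features_{name}.csv")

        stage = "redundancy reduction"
        reduced: dict[str, FeatureTable] = {}
        redundancy: dict[str, dict] = {}
        for name, t in tables.items():
            red, rep = reduce_redundancy(t, config.r2_threshold)
            reduced[name] = red
            redundancy[name] = rep.to_dict()
            red.to_csv(out / f"reduced_{name}.csv")
        (out / "redundancy.json").write_text(
            json.dumps(redundancy, indent=2, sort_keys=True)
        )

        stage = "wilcoxon screen"
        screens = {}
        for name, t in reduced.items():
            res = wilcoxon_screen(t, labels, config.alpha)
            df = pd.DataFrame(
                [(r.feature_id, r.p_value, r.significant) for r in res],
                columns=["feature_id", "p_value", "significant"],
            )
            df.to_csv(out / f"screen_{name}.csv", index=False)
            screens[name] = df

        stage = "model search"
        scfg = config.search_config()
        leaderboards: dict[str, list[ModelResult]] = {}
        for name, t in reduced.items():
            results: list[ModelResult] = []
            for k in range(1, scfg.max_subset_size + 1):
                results.extend(search_models(t, labels, k, scfg))
            from .model_search import rank_models

            leaderboards[name] = rank_models(results)
            _leaderboard_frame(leaderboards[name]).to_csv(
                out / f"leaderboard_{name}.csv", index=False
            )

        stage = "clinical baseline"
        clin = clinical_baseline(cohort.clinical, labels, scfg)
        _leaderboard_frame(clin).to_csv(out / "leaderboard_clinical.csv", index=False)

        stage = "multimodal fusion"
        fused: dict[str, list[ModelResult]] = {}
        for img_mod in ("T2W", "ADC"):
            pair = {"miRNA": reduced["miRNA"], img_mod: reduced[img_mod]}
            tops = {m: leaderboards[m] for m in pair}
            fused[f"miRNA+{img_mod}"] = fuse_multimodal(
                pair, labels, tops, config.k_top, scfg
            )
            _leaderboard_frame(fused[f"miRNA+{img_mod}"]).to_csv(
                out / f"leaderboard_fused_miRNA_{img_mod}.csv", index=False
            )

        stage = "manifest"
        cfg_json = json.dumps(config.to_dict(), sort_keys=True)
        manifest = {
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.seed,
            "package_version": __version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

        stage = "report"
        write_report(out)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err
    return out


def write_report(run_dir: str | Path) -> Path:
    """Render report.md + report.json from a completed run directory.

    Percentages are rounded half-even to one decimal.
    """
    run = Path(run_dir)
    redundancy = json.loads((run / "redundancy.json").read_text())
    report: dict = {"redundancy": {}, "screen": {}, "top_models": {}}
    lines = ["# Multimodal biomarker discovery report", ""]
    lines.append("## Redundancy reduction (R^2-linked groups)")
    lines.append("")
    lines.append("| modality | features before | after | % removed |")
    lines.append("|---|---|---|---|")
    for mod, rep in sorted(redundancy.items()):
        before = len(rep["kept"]) + len(rep["removed"])
        pct = round(rep["percent_removed"], 1)
        report["redundancy"][mod] = {
            "before": before,
            "after": len(rep["kept"]),
            "percent_removed": pct,
        }
        lines.append(f"| {mod} | {before} | {len(rep['kept'])} | {pct} |")
    lines.append("")
    lines.append("## Univariate screen hits (Wilcoxon)")
    lines.append("")
    for p in sorted(run.glob("screen_*.csv")):
        mod = p.stem.removeprefix("screen_")
        df = pd.read_csv(p)
        hits = df.loc[df["significant"].astype(bool)] if len(df) else df
        report["screen"][mod] = {
            "n_significant": int(len(hits)),
            "features": hits["feature_id"].tolist(),
        }
        lines.append(f"- **{mod}**: {len(hits)} significant feature(s)")
    lines.append("")
    lines.append("## Top models per leaderboard")
    lines.append("")
    for p in sorted(run.glob("leaderboard_*.csv")):
        name = p.stem.removeprefix("leaderboard_")
        df = pd.read_csv(p)
        report["top_models"][name] = df.head(5).to_dict(orient="records")
        lines.append(f"### {name}")
        lines.append("")
        if len(df):
            cols = ["rank", "features", "Sensitivity/Specificity", "PPV/NPV", "AUC [CI], SD"]
            lines.append("| " + " | ".join(cols) + " |")
            lines.append("|" + "---|" * len(cols))
            for _, row in df.head(5)[cols].iterrows():
                lines.append("| " + " | ".join(str(v) for v in row) + " |")
        else:
            lines.append("(no models)")
        lines.append("")
    (run / "report.md").write_text("\n".join(lines))
    (run / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return run / "report.md"
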