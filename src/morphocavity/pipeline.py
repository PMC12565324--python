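"""Config-driven end-to-end orchestration.

Stage order: load/generate -> mirror left -> exclusions -> semi-landmark
transfer + sliding -> bilateral Procrustes ANOVA (sides combined only when
non-significant) -> sensitivity re-run without unpaired specimens -> GPA ->
PCA + elbow + resampling stability -> Ward/HCPC with index vote ->
MANOVA / ANOVA / Tukey characterization -> demographics and patient pair
summary.  Every stage logs its parameters and writes CSV/JSON artifacts;
the same config and seed produce a byte-identical report.
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
import yaml
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from . import cohort as cohort_mod
from . import shape_stats as stats_mod
from .geometry_io import (
    CohortTable,
    LandmarkConfiguration,
    SpecimenRecord,
    mirror_mesh,
    read_cohort,
    read_landmarks,
    read_mesh,
)
from .procrustes import gpa, procrustes_anova
from .sliding import SlidingOptions, slide_semilandmarks, transfer_semilandmarks
from .synthetic import PopulationSpec, generate_population, generate_template
from .tps import bending_energy_matrix

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_pipeline", "write_report", "load_config"]

log = logging.getLogger("morphocavity")


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 1 territory)."""


class StageError(RuntimeError):
    """A pipeline stage failed after validation (exit code 2 territory)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class DataConfig:
    kind: str = "synthetic"  # "synthetic" | "files"
    # synthetic
    n_patients: int = 45
    cluster_proportions: tuple[float, ...] = (0.25, 0.5, 0.25)
    sigma_dig: float = 0.3
    side_effect: float = 0.0
    rho_pair: float = 0.75
    mesh_resolution: int = 20
    # files
    manifest: str | None = None  # CSV: specimen_id,patient_id,side,mesh,landmarks
    cohort: str | None = None
    template_mesh: str | None = None
    template_landmarks: str | None = None


@dataclass
class SlideConfig:
    tol: float = 1e-6
    max_iter: int = 10
    reference: str = "template"  # "template" | "mean"


@dataclass
class GpaConfig:
    tol: float = 1e-10
    max_iter: int = 100


@dataclass
class AnovaConfig:
    n_perm: int = 999


@dataclass
class HcpcConfig:
    kmin: int = 2
    kmax: int = 10
    consolidate: bool = False


@dataclass
class StatsConfig:
    alpha: float = 0.05
    p_adjust: str = "none"  # "none" | "BH"


@dataclass
class PcaConfig:
    retain_m: int | None = None  # None -> elbow selection
    stability_sizes: tuple[int, ...] | None = None
    stability_reps: int = 100
    stability_m: int = 5


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "morphocavity_out"
    data: DataConfig = field(default_factory=DataConfig)
    template_resolution: int = 40
    slide: SlideConfig = field(default_factory=SlideConfig)
    gpa: GpaConfig = field(default_factory=GpaConfig)
    anova: AnovaConfig = field(default_factory=AnovaConfig)
    hcpc: HcpcConfig = field(default_factory=HcpcConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    pca: PcaConfig = field(default_factory=PcaConfig)
    exclusions: tuple[dict, ...] = ()

    def validate(self) -> None:
        if self.hcpc.kmax < self.hcpc.kmin:
            raise ConfigError(f"hcpc.kmax ({self.hcpc.kmax}) < hcpc.kmin ({self.hcpc.kmin})")
        if self.hcpc.kmin < 2:
            raise ConfigError("hcpc.kmin must be >= 2")
        if not 0 < self.stats.alpha < 1:
            raise ConfigError("stats.alpha must lie in (0, 1)")
        if self.stats.p_adjust not in ("none", "BH"):
            raise ConfigError(f"unknown stats.p_adjust {self.stats.p_adjust!r}")
        if self.slide.reference not in ("template", "mean"):
            raise ConfigError(f"unknown slide.reference {self.slide.reference!r}")
        if self.data.kind not in ("synthetic", "files"):
            raise ConfigError(f"unknown data.kind {self.data.kind!r}")
        if self.data.kind == "files":
            for key in ("manifest", "cohort", "template_mesh", "template_landmarks"):
                if getattr(self.data, key) is None:
                    raise ConfigError(f"data.{key} required when data.kind = files")
        if self.anova.n_perm < 1:
            raise ConfigError("anova.n_perm must be positive")


def _build_dataclass(cls, payload: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(payload) - set(names)
    if unknown:
        raise ConfigError(f"unknown config keys at {path}: {sorted(unknown)}")
    kwargs = {}
    for key, value in payload.items():
        f = names[key]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "data", "slide", "gpa", "anova", "hcpc", "stats", "pca",
        ):
            sub_cls = {
                "data": DataConfig, "slide": SlideConfig, "gpa": GpaConfig,
                "anova": AnovaConfig, "hcpc": HcpcConfig, "stats": StatsConfig,
                "pca": PcaConfig,
            }[f.name]
            if not isinstance(value, dict):
                raise ConfigError(f"config section {path}.{key} must be a mapping")
            kwargs[key] = _build_dataclass(sub_cls, value, f"{path}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(source: str | Path | dict) -> PipelineConfig:
    """Build and schema-validate a pipeline config from YAML or a dict."""
    if isinstance(source, (str, Path)):
        payload = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    else:
        payload = source
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ConfigError("pipeline config must be a mapping")
    cfg = _build_dataclass(PipelineConfig, payload, "config")
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# data loading
# ---------------------------------------------------------------------------


@dataclass
class _Dataset:
    template: Any
    specimens: list[dict]  # record, mesh, fixed (10,3), true_cluster|None
    cohort: CohortTable
    true_labels: dict[str, int] | None


def _load_synthetic(cfg: PipelineConfig) -> _Dataset:
    spec = PopulationSpec(
        n_patients=cfg.data.n_patients,
        cluster_proportions=cfg.data.cluster_proportions,
        sigma_dig=cfg.data.sigma_dig,
        side_effect=cfg.data.side_effect,
        rho_pair=cfg.data.rho_pair,
        seed=cfg.seed,
        mesh_resolution=cfg.data.mesh_resolution,
    )
    pop = generate_population(spec)
    template = generate_template(cfg.template_resolution)
    specimens = [
        {
            "record": s.record,
            "mesh": s.mesh,
            "fixed": s.landmarks.fixed,
            "true_cluster": s.true_cluster,
        }
        for s in pop.specimens
    ]
    return _Dataset(template, specimens, pop.cohort, pop.true_labels())


def _load_files(cfg: PipelineConfig) -> _Dataset:
    from .geometry_io import TemplateDefinition

    manifest = pd.read_csv(cfg.data.manifest, dtype=str)
    needed = {"specimen_id", "patient_id", "side", "mesh", "landmarks"}
    if not needed.issubset(manifest.columns):
        raise ConfigError(f"manifest must have columns {sorted(needed)}")
    tmesh = read_mesh(cfg.data.template_mesh)
    tconf = read_landmarks(cfg.data.template_landmarks, dialect="csv")
    if tconf.n_fixed != 10 or tconf.n_landmarks != 210:
        raise ConfigError("template landmarks must be 10 fixed + 200 semi-landmarks")
    template = TemplateDefinition(
        tmesh,
        tconf.fixed,
        tuple(f"fixed_{i}" for i in range(10)),
        tconf.semilandmarks,
        tconf.patch_ids[tconf.patch_ids != 0],
    )
    base = Path(cfg.data.manifest).parent
    specimens = []
    for row in manifest.itertuples(index=False):
        mesh = read_mesh(base / row.mesh)
        conf = read_landmarks(base / row.landmarks, dialect="csv")
        specimens.append(
            {
                "record": SpecimenRecord(row.specimen_id, row.patient_id, row.side),
                "mesh": mesh,
                "fixed": conf.fixed,
                "true_cluster": None,
            }
        )
    cohort = read_cohort(cfg.data.cohort)
    return _Dataset(template, specimens, cohort, None)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Execute the full workflow; returns the report dict (also written to disk)."""
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)
    report: dict[str, Any] = {"seed": cfg.seed, "stages": []}

    def artifact(name: str, df: pd.DataFrame) -> None:
        df.to_csv(out / "tables" / f"{name}.csv", index=False)

    def done(stage: str, **params: Any) -> None:
        log.info("stage %s: done %s", stage, params)
        report["stages"].append({"stage": stage, **params})

    # --- load / generate ---------------------------------------------------
    try:
        ds = _load_synthetic(cfg) if cfg.data.kind == "synthetic" else _load_files(cfg)
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError("load", str(exc)) from exc
    done("load", kind=cfg.data.kind, n_specimens=len(ds.specimens))

    # --- mirror left sides to the right-side convention --------------------
    for s in ds.specimens:
        if s["record"].side == "left":
            s["mesh"] = mirror_mesh(s["mesh"])
            fixed = s["fixed"].copy()
            fixed[:, 0] = -fixed[:, 0]
            s["fixed"] = fixed
    done("mirror", n_left=sum(s["record"].side == "left" for s in ds.specimens))

    # --- exclusions --------------------------------------------------------
    records = [s["record"] for s in ds.specimens]
    rules = [
        cohort_mod.ExclusionRule(
            rule.get("reason", "excluded by config"),
            (lambda r, pid=rule.get("patient_id"), side=rule.get("side"): (
                (pid is None or r.patient_id == pid)
                and (side is None or r.side == side)
            )),
        )
        for rule in cfg.exclusions
    ]
    kept_records, audit = cohort_mod.exclude_specimens(records, rules)
    kept_ids = {r.specimen_id for r in kept_records}
    ds.specimens = [s for s in ds.specimens if s["record"].specimen_id in kept_ids]
    artifact("exclusions", audit)
    done("exclusions", n_excluded=len(audit), n_kept=len(ds.specimens))

    # --- transfer + slide --------------------------------------------------
    # digitization noise and any injected side offset keep fixed landmarks
    # off the exact surface; widen the on-surface gate accordingly
    surface_tol = max(0.5, 5.0 * cfg.data.sigma_dig + cfg.data.side_effect)
    opts = SlidingOptions(tol=cfg.slide.tol, max_iter=cfg.slide.max_iter)
    bending = bending_energy_matrix(ds.template.all_points())
    configs: list[LandmarkConfiguration] = []
    energy_rows = []
    try:
        for s in ds.specimens:
            initial = transfer_semilandmarks(
                ds.template,
                s["mesh"],
                s["fixed"],
                specimen_id=s["record"].specimen_id,
                surface_tol=surface_tol,
            )
            result = slide_semilandmarks(ds.template, initial, s["mesh"], opts, bending)
            configs.append(result.configuration)
            energy_rows.append(
                {
                    "specimen_id": s["record"].specimen_id,
                    "initial_energy": result.energy_trace[0],
                    "final_energy": result.energy_trace[-1],
                    "iterations": result.iterations,
                    "converged": result.converged,
                }
            )
    except Exception as exc:
        raise StageError("slide", str(exc)) from exc
    artifact("sliding_energy", pd.DataFrame(energy_rows))
    done("slide", tol=cfg.slide.tol, max_iter=cfg.slide.max_iter)

    coords = np.stack([c.coordinates for c in configs])
    records = [s["record"] for s in ds.specimens]
    sides = np.array([r.side for r in records])

    # --- bilateral dimorphism test -----------------------------------------
    try:
        aligned_all = gpa(coords, tol=cfg.gpa.tol, max_iter=cfg.gpa.max_iter)
        side_test = procrustes_anova(aligned_all, sides, cfg.anova.n_perm, cfg.seed)
        # sensitivity: drop specimens of patients lacking the other side
        by_patient: dict[str, int] = {}
        for r in records:
            by_patient[r.patient_id] = by_patient.get(r.patient_id, 0) + 1
        paired_mask = np.array([by_patient[r.patient_id] == 2 for r in records])
        if paired_mask.sum() >= 4 and len(set(sides[paired_mask])) == 2:
            aligned_paired = gpa(coords[paired_mask], tol=cfg.gpa.tol, max_iter=cfg.gpa.max_iter)
            side_test_paired = procrustes_anova(
                aligned_paired, sides[paired_mask], cfg.anova.n_perm, cfg.seed
            )
            sensitivity_p = side_test_paired.p
        else:
            sensitivity_p = None
    except Exception as exc:
        raise StageError("side_test", str(exc)) from exc
    combine_sides = side_test.p > cfg.stats.alpha
    if not combine_sides:
        log.warning(
            "bilateral dimorphism significant (p=%.4f <= %.2f): sides are "
            "analyzed separately", side_test.p, cfg.stats.alpha,
        )
    done(
        "side_test",
        p=side_test.p,
        F=side_test.F,
        sensitivity_p=sensitivity_p,
        combined=bool(combine_sides),
    )

    # --- GPA + PCA on the analysis set -------------------------------------
    strata = (
        {"combined": np.ones(len(records), bool)}
        if combine_sides
        else {side: sides == side for side in ("right", "left")}
    )
    stratum_reports = {}
    for stratum, mask in strata.items():
        stratum_reports[stratum] = _analyze_stratum(
            cfg,
            coords[mask],
            [r for r, m in zip(records, mask) if m],
            ds,
            artifact,
            done,
            prefix="" if combine_sides else f"{stratum}_",
        )
    report.update(stratum_reports["combined"] if combine_sides else {"strata": stratum_reports})
    report["side_test"] = {
        "p": side_test.p,
        "F": side_test.F,
        "sensitivity_p": sensitivity_p,
        "combined": bool(combine_sides),
    }
    report["config"] = _config_dict(cfg)
    write_report(report, out)
    return report


def _analyze_stratum(cfg, coords, records, ds, artifact, done, prefix=""):
    sub: dict[str, Any] = {}
    try:
        aligned = gpa(coords, tol=cfg.gpa.tol, max_iter=cfg.gpa.max_iter)
    except Exception as exc:
        raise StageError("gpa", str(exc)) from exc
    done(prefix + "gpa", n=aligned.n_specimens, iterations=aligned.iterations)

    try:
        pca = stats_mod.shape_pca(aligned)
        m = cfg.pca.retain_m or stats_mod.select_components_elbow(pca.explained_ratio)
        sizes = cfg.pca.stability_sizes
        if sizes is None:
            lo = min(20, aligned.n_specimens)
            sizes = tuple(range(lo, aligned.n_specimens + 1, 10)) or (aligned.n_specimens,)
        sizes = tuple(s for s in sizes if s <= aligned.n_specimens)
        stability = stats_mod.pca_stability_resampling(
            aligned, sizes, reps=cfg.pca.stability_reps, m=cfg.pca.stability_m, seed=cfg.seed
        )
    except Exception as exc:
        raise StageError("pca", str(exc)) from exc
    artifact(prefix + "pca_spectrum", pd.DataFrame({
        "component": np.arange(1, pca.n_components + 1),
        "explained_ratio": pca.explained_ratio,
    }))
    artifact(prefix + "pca_stability", stability)
    sub["pca"] = {
        "n_components": int(pca.n_components),
        "retained": int(m),
        "explained_retained": float(pca.explained_ratio[:m].sum()),
    }
    done(prefix + "pca", retained=int(m))

    try:
        tree = stats_mod.ward_tree(pca.scores[:, :m])
        kmax = min(cfg.hcpc.kmax, aligned.n_specimens - 1)
        k, ratios, low_conf = stats_mod.select_cluster_count(
            tree, cfg.hcpc.kmin, kmax, return_details=True
        )
        votes, majority = stats_mod.cluster_count_vote(pca.scores[:, :m], cfg.hcpc.kmin, kmax)
        labels = tree.cut(k)
        if cfg.hcpc.consolidate:
            centers = np.stack(
                [pca.scores[labels == g, :m].mean(axis=0) for g in range(1, k + 1)]
            )
            km = KMeans(n_clusters=k, init=centers, n_init=1, random_state=cfg.seed)
            labels = km.fit_predict(pca.scores[:, :m]) + 1
    except Exception as exc:
        raise StageError("hcpc", str(exc)) from exc
    label_map = {r.specimen_id: int(l) for r, l in zip(records, labels)}
    artifact(prefix + "cluster_labels", pd.DataFrame({
        "specimen_id": [r.specimen_id for r in records],
        "cluster": labels,
    }))
    sub["hcpc"] = {
        "k": int(k),
        "low_confidence": bool(low_conf),
        "index_votes": {name: int(v) for name, v in votes.items()},
        "majority_k": int(majority),
        "cluster_sizes": {str(int(g)): int((labels == g).sum()) for g in np.unique(labels)},
    }
    if ds.true_labels is not None:
        truth = [ds.true_labels[r.specimen_id] for r in records]
        sub["hcpc"]["ari_vs_truth"] = float(adjusted_rand_score(truth, labels))
    done(prefix + "hcpc", k=int(k))

    alpha = cfg.stats.alpha
    try:
        try:
            manova = stats_mod.manova_per_landmark(aligned, labels)
        except ValueError as exc:
            # tiny clusters: MANOVA undefined, characterized by ANOVA/Tukey only
            manova = None
            sub["characterization"] = {"manova_skipped": str(exc)}
        try:
            anova = stats_mod.anova_per_axis(aligned, labels)
            tukey = stats_mod.tukey_pairwise(aligned, labels)
        except ValueError as exc:
            # singleton clusters: per-axis comparisons undefined
            anova = tukey = None
            sub.setdefault("characterization", {})["anova_skipped"] = str(exc)
        if cfg.stats.p_adjust == "BH":
            if anova is not None:
                anova["p_adj"] = stats_mod.benjamini_hochberg(anova["p"].to_numpy())
            if manova is not None:
                manova["p_adj"] = stats_mod.benjamini_hochberg(
                    manova["p"].fillna(1.0).to_numpy()
                )
    except Exception as exc:
        raise StageError("characterization", str(exc)) from exc
    if anova is not None:
        artifact(prefix + "anova", anova)
        artifact(prefix + "tukey", tukey)
    if manova is not None:
        artifact(prefix + "manova", manova)
        sub.setdefault("characterization", {}).update(
            {
                "n_landmarks_significant_manova": int((manova["p"] < alpha).sum()),
                "n_landmarks_nonsignificant_manova": int((manova["p"] >= alpha).sum()),
            }
        )
    done(prefix + "characterization")

    try:
        pair_summary = cohort_mod.pair_clusters_by_patient(label_map, records)
        demo, demo_info = cohort_mod.demographics_table(label_map, records, ds.cohort)
    except Exception as exc:
        raise StageError("cohort_summary", str(exc)) from exc
    artifact(prefix + "pair_summary", pair_summary.to_frame())
    artifact(prefix + "demographics", demo)
    sub["pairs"] = {
        "total_patients": pair_summary.total_patients,
        "excluded_patients": len(pair_summary.excluded_patients),
        "counts": {f"{a}-{b}": n for (a, b), n in sorted(pair_summary.pair_counts.items())},
        "at_least_one": {
            str(int(c)): cohort_mod.at_least_one_membership(pair_summary, int(c))
            for c in sorted({x for pair in pair_summary.pair_counts for x in pair})
        } if pair_summary.total_patients else {},
    }
    sub["demographics"] = {
        k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
        for k, v in demo_info.items()
    }
    done(prefix + "cohort_summary", patients=pair_summary.total_patients)
    return sub


def _config_dict(cfg: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [convert(x) for x in obj]
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        return obj

    return convert(cfg)


def write_report(results: dict, out_dir: str | Path) -> Path:
    """Serialize the report deterministically (sorted keys, plain floats)."""
    if not results:
        raise ValueError("refusing to write an empty report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"

    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"unserializable report entry of type {type(obj)}")

    path.write_text(
        json.dumps(results, indent=2, sort_keys=True, default=default) + "\n",
        encoding="utf-8",
    )
    return path
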