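"""Configuration-driven end-to-end runs.

``run_pipeline`` executes the whole analysis in dependency order —
generate phantom cohort -> preprocess -> cross-validated CNN training ->
saliency stacks -> voxel-wise GLMs (SUVR and saliency) with permutation FWE
and cluster-extent thresholding -> occlusion / strength-of-association —
with a single master seed fanned out into named per-stage sub-seeds, and
returns a :class:`RunReport` whose tables mirror the analysis outputs
(per-fold metrics, cluster table, post-occlusion R^2 table with an
all-clusters row, curve summaries).
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm as glm_mod
from . import occlusion as occ_mod
from . import saliency as sal_mod
from .metrics import make_folds
from .model import CentiloidCNN, CrossValidatedCNN
from .nn import CNNConfig
from .preprocess import compute_suvr
from .synthetic import SyntheticConfig, generate_dataset, write_dataset
from .volume import Volume

STAGES = ("generate", "train", "saliency", "glm", "occlusion")


@dataclass
class PipelineConfig:
    """Nested stage configs, master seed, output directory, stage toggles."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    k_folds: int = 10
    train_folds: tuple[int, ...] | None = None  # None -> all folds
    alpha: float = 0.05
    n_perm: int = 1000
    extent_at_1mm: int = 200
    connectivity: int = 26
    tail: str = "positive"
    saliency_fwhm_mm: float = 2.0
    signed_saliency: bool = False
    occlusion_fill: float = 0.0
    loess_span: float = 0.5
    cl_threshold: float = 25.0  # descriptive Abeta+/- labelling only
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid: {STAGES}")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")

    def stage_seed(self, stage: str) -> int:
        """Named sub-seed (< 2**31) so stages are individually rerunnable."""
        return int((int(self.seed) * 2654435761
                    + zlib.crc32(stage.encode())) % (2**31 - 1))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d:
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        if "cnn" in d:
            d["cnn"] = CNNConfig(**d["cnn"])
        for key in ("stages", "train_folds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_dict(self) -> dict:
        """JSON/YAML-safe plain dict (tuples normalised to lists)."""
        return json.loads(json.dumps(asdict(self)))


@dataclass
class RunReport:
    """Per-stage status and the headline result tables of one run."""

    config: PipelineConfig
    stage_status: dict = field(default_factory=dict)   # stage -> "ok"/"skipped"/error
    stage_seconds: dict = field(default_factory=dict)
    manifests: dict = field(default_factory=dict)      # stage -> file manifest
    tables: dict = field(default_factory=dict)         # name -> DataFrame
    scalars: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)      # in-memory objects

    def completed(self) -> list[str]:
        return [s for s, st in self.stage_status.items() if st == "ok"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, progress: bool = False) -> RunReport:
    """Execute the enabled stages in dependency order.

    Later stages require earlier ones: disabling a dependency makes the
    dependent stage fail with a :class:`PipelineError` naming it.  Rerunning
    with the same config reproduces all outputs (training runs in
    deterministic mode by construction).
    """
    report = RunReport(config=config)
    art = report.artifacts
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def log(msg):
        if progress:
            print(f"[taucl] {msg}", flush=True)

    def run_stage(name, fn):
        if name not in config.stages:
            report.stage_status[name] = "skipped"
            return
        t0 = time.time()
        log(f"stage {name} ...")
        fn()
        report.stage_status[name] = "ok"
        report.stage_seconds[name] = round(time.time() - t0, 2)

    # ----------------------------------------------------------- generate
    def do_generate():
        syn = SyntheticConfig(**{**asdict(config.synthetic),
                                 "seed": config.stage_seed("generate")})
        cohort, atlas, volumes = generate_dataset(syn)
        art.update(synthetic=syn, cohort=cohort, atlas=atlas, volumes=volumes)
        report.scalars["n_subjects"] = len(cohort)
        report.scalars["abeta_pos_fraction"] = float(
            (cohort["cl"] >= config.cl_threshold).mean()) if len(cohort) else 0.0
        if out:
            report.manifests["generate"] = write_dataset(
                cohort, volumes, atlas, out / "dataset", config=syn)

    # -------------------------------------------------------------- train
    def do_train():
        for dep in ("cohort",):
            if dep not in art:
                raise PipelineError("train", "missing generated dataset "
                                    "(enable the 'generate' stage)")
        cohort, atlas, volumes = art["cohort"], art["atlas"], art["volumes"]
        cnn_cfg = CNNConfig(**{**asdict(config.cnn),
                               "seed": config.stage_seed("train")})
        model = CentiloidCNN.from_dataset(cohort, volumes, atlas, cnn_cfg)
        plan = make_folds(cohort, K=config.k_folds,
                          seed=config.stage_seed("folds"))
        cv = CrossValidatedCNN(model, plan).fit(
            folds=config.train_folds, progress=progress)
        art.update(model=model, plan=plan, cv=cv, best=cv.best())
        report.tables["fold_metrics"] = cv.metrics_table().reset_index()
        report.scalars["best_fold"] = int(cv.best().fold)

    # ----------------------------------------------------------- saliency
    def do_saliency():
        if "cv" not in art:
            raise PipelineError("saliency", "no trained instances "
                                "(enable the 'train' stage)")
        model, atlas, cohort = art["model"], art["atlas"], art["cohort"]
        scaled = {sid: Volume(model.X[i], atlas.affine, "scaled",
                              meta={"subject_id": sid})
                  for i, sid in enumerate(model.ids)}
        stacks = sal_mod.saliency_stack(
            cohort, scaled, art["cv"].instances, mask=atlas,
            fwhm_mm=config.saliency_fwhm_mm, signed=config.signed_saliency)
        art.update(scaled=scaled, stacks=stacks)
        if out:
            report.manifests["saliency"] = sal_mod.save_stack(
                stacks, out / "saliency")

    # ---------------------------------------------------------------- glm
    def do_glm():
        if "stacks" not in art:
            raise PipelineError("glm", "no saliency stacks "
                                "(enable the 'saliency' stage)")
        cohort, atlas = art["cohort"], art["atlas"]
        design = glm_mod.design_from_cohort(cohort)
        mask = atlas.brain_mask
        extent = glm_mod.scale_extent(config.extent_at_1mm, atlas.voxel_size_mm)
        seed = config.stage_seed("glm")

        def analyse(volumes, kind):
            Y = glm_mod.stack_to_matrix(volumes, mask)
            thr = glm_mod.fwe_threshold(Y, design, alpha=config.alpha,
                                        n_perm=config.n_perm, seed=seed,
                                        tail=config.tail)
            tmap, fit = glm_mod.glm_tmap(volumes, design, mask,
                                         affine=atlas.affine)
            cs = glm_mod.threshold_and_cluster(
                tmap, thr, min_extent=extent, connectivity=config.connectivity,
                tail=config.tail, atlas=atlas,
                provenance={"dependent": kind, "alpha": config.alpha,
                            "n_perm": config.n_perm})
            return tmap, thr, cs

        # linear comparison arm: voxel-wise SUVR ~ CL + age + sex
        suvr = [compute_suvr(v, atlas) for v in art["volumes"]]
        t_suvr, thr_suvr, cs_suvr = analyse(suvr, "suvr")
        # CNN arm: saliency (best instance) ~ CL + age + sex
        best_fold = art["best"].fold
        t_sal, thr_sal, cs_sal = analyse(art["stacks"][best_fold], "saliency")

        art.update(design=design, suvr=suvr, clusters_suvr=cs_suvr,
                   clusters=cs_sal, tmap_suvr=t_suvr, tmap_saliency=t_sal)
        report.scalars.update(fwe_threshold_suvr=thr_suvr,
                              fwe_threshold_saliency=thr_sal,
                              extent_voxels=extent,
                              n_clusters_suvr=len(cs_suvr),
                              n_clusters_saliency=len(cs_sal))
        report.tables["clusters_suvr"] = cs_suvr.to_table()
        report.tables["clusters_saliency"] = cs_sal.to_table()

        if len(art["cv"].instances) >= 2:
            sets = []
            for inst in art["cv"].instances:
                tm, _, cs = analyse(art["stacks"][inst.fold], "saliency")
                sets.append(cs)
            D, consensus = glm_mod.cluster_consistency(sets)
            art["consensus"] = consensus
            off = D[np.triu_indices_from(D, k=1)]
            report.scalars["cross_instance_dice_mean"] = float(off.mean())
        if out:
            t_sal.save(out / "tmap_saliency.nii.gz")
            t_suvr.save(out / "tmap_suvr.nii.gz")
            report.manifests["glm"] = ["tmap_saliency.nii.gz", "tmap_suvr.nii.gz"]

    # ---------------------------------------------------------- occlusion
    def do_occlusion():
        if "clusters" not in art:
            raise PipelineError("occlusion", "no saliency-GLM clusters "
                                "(enable the 'glm' stage)")
        model, best, cs = art["model"], art["best"], art["clusters"]
        splits = {s: model.indices_of(best.split_ids[s])
                  for s in ("train", "validation", "test")
                  if best.split_ids.get(s)}
        shape = model.X.shape[1:]
        rows = []
        all_mask = cs.mask()
        for c in list(cs) + [None]:
            mask = all_mask if c is None else c.mask(shape)
            res = occ_mod.occlusion_r2(
                best, model.X, model.y, splits, mask,
                cluster_id="all clusters" if c is None else c.id,
                fill=config.occlusion_fill)
            row = {"cluster": res.cluster_id,
                   "n_voxels": res.n_occluded_voxels}
            for s in splits:
                row[f"r2_{s}_baseline"] = res.r2_baseline[s]
                row[f"r2_{s}_post"] = res.r2_post[s]
            rows.append(row)
        # the all-clusters row last, mirroring an occlusion summary table
        report.tables["occlusion"] = pd.DataFrame(
            [rows[-1]] + rows[:-1]) if rows else pd.DataFrame()

        curves = {}
        for c in cs:
            curves[c.id] = occ_mod.strength_of_association(
                art["cv"].instances, model.X, model.y, c.mask(shape),
                span=config.loess_span, fill=config.occlusion_fill,
                label=f"cluster {c.id}")
        art["curves"] = curves
        if curves:
            report.tables["curves"] = pd.concat([
                pd.DataFrame({"cluster": cid, "cl": cur.grid,
                              "mean": cur.mean, "sem": cur.sem})
                for cid, cur in curves.items()], ignore_index=True)

    try:
        run_stage("generate", do_generate)
        run_stage("train", do_train)
        run_stage("saliency", do_saliency)
        run_stage("glm", do_glm)
        run_stage("occlusion", do_occlusion)
    except PipelineError as err:
        report.stage_status[err.stage] = f"error: {err}"
        raise
    finally:
        if out:
            summary_path = out / "report.md"
            summary_path.write_text(render_report(report))
            (out / "report.json").write_text(json.dumps(
                {"stage_status": report.stage_status,
                 "stage_seconds": report.stage_seconds,
                 "scalars": report.scalars,
                 "config": config.to_dict()}, indent=2, default=str))
    return report


def render_report(report: RunReport) -> str:
    """Human-readable markdown summary of a (possibly partial) run."""
    lines = ["# taucl pipeline report", ""]
    done = report.completed()
    if not done:
        lines.append("No stages executed.")
        return "\n".join(lines) + "\n"
    lines.append("| stage | status | seconds |")
    lines.append("|---|---|---|")
    for s in STAGES:
        st = report.stage_status.get(s, "skipped")
        lines.append(f"| {s} | {st} | {report.stage_seconds.get(s, '')} |")
    lines.append("")
    if report.scalars:
        lines.append("## Key quantities")
        for k, v in report.scalars.items():
            lines.append(f"- {k}: {v:.4g}" if isinstance(v, float) else f"- {k}: {v}")
        lines.append("")
    for name, table in report.tables.items():
        if name == "curves":
            cur = report.tables["curves"]
            lines.append("## Strength-of-association curves")
            lines.append(f"{cur['cluster'].nunique()} cluster curve(s) over "
                         f"CL [{cur['cl'].min():.1f}, {cur['cl'].max():.1f}]")
            lines.append("")
            continue
        lines.append(f"## {name.replace('_', ' ')}")
        lines.append(table.round(3).to_markdown(index=False))
        lines.append("")
    if report.manifests:
        lines.append("## Files")
        for stage, manifest in report.manifests.items():
            if isinstance(manifest, dict):
                n = len(manifest.get("images", manifest))
            else:
                n = len(manifest)
            lines.append(f"- {stage}: {n} file(s)")
        lines.append("")
    return "\n".join(lines) + "\n"
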