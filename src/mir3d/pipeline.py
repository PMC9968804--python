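"""Structured configuration, staged pipeline runner and run manifest.

Stages run in canonical order: simulate -> reconstruct -> profile -> select
-> evaluate.  Each stage reads its inputs from and writes its outputs to
the run directory, so any contiguous subset can be rerun; identical config
and seed reproduce byte-identical outputs.  A manifest (config snapshot,
package version, per-file sha256, warnings) is written at the end of every
run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, genome3d, io, select, synthetic
from .errors import InvalidConfigError, PipelineError
from .profiling import filter_ambiguous, filter_low_expression, normalize_by_controls
from .synthetic import CONTROL_IDS, SimConfig

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

STAGES = ("simulate", "reconstruct", "profile", "select", "evaluate")


@dataclass(frozen=True)
class EmbeddingConfig:
    alpha: float = 1.0
    cap_factor: float = 1.5
    n_restarts: int = 300
    max_iter: int = 500
    tol: float = 1e-12
    #: expected contact count at unit distance; None means "use the
    #: simulation's contact_scale" (synthetic runs) and 1.0 otherwise.
    contact_scale: float | None = None

    def validate(self) -> "EmbeddingConfig":
        if self.alpha <= 0 or self.cap_factor < 1 or self.n_restarts < 1:
            raise InvalidConfigError("invalid embedding block")
        return self


@dataclass(frozen=True)
class FilterConfig:
    min_score: float = 5.0
    min_samples: int | None = None  # None -> ~76% of the cohort


@dataclass(frozen=True)
class SelectionConfig:
    eps: float = 3.0
    min_pts: int = 2
    k_top: int = 400
    m_representatives: int = 100
    p_max: float = 0.05
    p_adjust: str | None = "bh"
    cluster_p_filter: bool = True
    selection_mode: str = "fixed_panel"

    def validate(self) -> "SelectionConfig":
        if self.eps <= 0 or self.min_pts < 2 or self.k_top < 1 or self.m_representatives < 1:
            raise InvalidConfigError("invalid selection block")
        if not 0 < self.p_max <= 1:
            raise InvalidConfigError("p_max must be in (0, 1]")
        if self.selection_mode not in ("fixed_panel", "nested"):
            raise InvalidConfigError("selection_mode must be fixed_panel or nested")
        return self


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model_families: tuple[str, ...] = evaluate.MODEL_FAMILIES
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        self.sim.validate()
        self.embedding.validate()
        self.selection.validate()
        for fam in self.model_families:
            if fam not in evaluate.MODEL_FAMILIES:
                raise InvalidConfigError(f"unknown model family {fam!r}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        if "sim" in data:
            kwargs["sim"] = SimConfig(**data.pop("sim"))
        if "embedding" in data:
            kwargs["embedding"] = EmbeddingConfig(**data.pop("embedding"))
        if "filter" in data:
            kwargs["filter"] = FilterConfig(**data.pop("filter"))
        if "selection" in data:
            kwargs["selection"] = SelectionConfig(**data.pop("selection"))
        if "model_families" in data:
            kwargs["model_families"] = tuple(data.pop("model_families"))
        if "seed" in data:
            kwargs["seed"] = int(data.pop("seed"))
        if data:
            raise InvalidConfigError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _stage_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([tag, int(seed)]).generate_state(1)[0] % 2**31)


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.records: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.records.append(record.getMessage())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(outdir: Path, stage: str, *names: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise PipelineError(
            f"stage {stage!r}: missing inputs {missing}; run earlier stages first"
        )


def run_pipeline(
    config: PipelineConfig, outdir, stages: tuple[str, ...] = STAGES
) -> dict:
    """Execute the requested stages in canonical order; return the manifest."""
    config.validate()
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise PipelineError(f"unknown stages: {bad}")
    stages = tuple(s for s in STAGES if s in stages)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logging.getLogger("mir3d").addHandler(collector)
    written: list[str] = []
    try:
        for stage in stages:
            logger.info("stage %s: start", stage)
            try:
                written.extend(_run_stage(stage, config, outdir))
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("mir3d").removeHandler(collector)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stages_run": list(stages),
        "outputs": {name: _sha256(outdir / name) for name in sorted(set(written))},
        "warnings": collector.records,
        "n_failures": 0,
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest


def _run_stage(stage: str, config: PipelineConfig, outdir: Path) -> list[str]:
    if stage == "simulate":
        sim_cfg = replace(config.sim, seed=_stage_seed(config.seed, 10))
        ds = synthetic.simulate_dataset(sim_cfg)
        io.write_bins_bed(ds.bins, outdir / "bins.bed")
        io.write_contacts(ds.contacts, outdir / "contacts.tsv")
        io.write_annotation_bed(ds.annotation, outdir / "annotation.bed")
        io.write_expression(
            ds.expression, outdir / "expression.tsv", outdir / "labels.tsv"
        )
        io.write_coords(ds.structure, outdir / "true_coords.tsv")
        io.write_json(
            {
                "informative_mirnas": sorted(ds.truth.informative_mirnas),
                "informative_clusters": list(ds.truth.informative_clusters),
                "effect_size": ds.truth.effect_size,
                "control_ids": list(ds.truth.control_ids),
            },
            outdir / "truth.json",
        )
        return [
            "bins.bed",
            "contacts.tsv",
            "annotation.bed",
            "expression.tsv",
            "labels.tsv",
            "true_coords.tsv",
            "truth.json",
        ]

    if stage == "reconstruct":
        _require(outdir, stage, "contacts.tsv", "bins.bed")
        bins = io.read_bins_bed(outdir / "bins.bed")
        contacts = io.read_contacts(outdir / "contacts.tsv", bins)
        scale = config.embedding.contact_scale
        if scale is None:
            scale = config.sim.contact_scale
        targets = genome3d.contacts_to_distances(
            contacts,
            alpha=config.embedding.alpha,
            cap_factor=config.embedding.cap_factor,
            scale=scale,
        )
        model = genome3d.embed(
            targets,
            n_restarts=config.embedding.n_restarts,
            max_iter=config.embedding.max_iter,
            tol=config.embedding.tol,
            seed=_stage_seed(config.seed, 20),
        )
        io.write_coords(model, outdir / "coords.tsv")
        io.write_json(
            {
                "stress": model.stress,
                "restart_stresses": [float(s) for s in model.restart_stresses],
                "chosen_stress": model.stress,
                "n_restarts": model.n_restarts_used,
                "converged": model.converged,
                "seed": _stage_seed(config.seed, 20),
            },
            outdir / "embedding_report.json",
        )
        return ["coords.tsv", "embedding_report.json"]

    if stage == "profile":
        _require(outdir, stage, "expression.tsv", "labels.tsv", "annotation.bed")
        raw = io.read_expression(outdir / "expression.tsv", outdir / "labels.tsv")
        ann = io.read_annotation_bed(outdir / "annotation.bed")
        m = normalize_by_controls(raw, CONTROL_IDS)
        m = filter_low_expression(
            m, min_score=config.filter.min_score, min_samples=config.filter.min_samples
        )
        m = filter_ambiguous(m, ann)
        io.write_expression(m, outdir / "filtered_expression.tsv")
        return ["filtered_expression.tsv"]

    if stage == "select":
        _require(
            outdir,
            stage,
            "filtered_expression.tsv",
            "labels.tsv",
            "annotation.bed",
            "bins.bed",
            "coords.tsv",
        )
        m = io.read_expression(outdir / "filtered_expression.tsv", outdir / "labels.tsv")
        ann = io.read_annotation_bed(outdir / "annotation.bed")
        bins = io.read_bins_bed(outdir / "bins.bed")
        model = io.read_coords(outdir / "coords.tsv")
        sel = config.selection
        scores = select.spearman_scores(m)
        scores.to_csv(outdir / "scores.tsv", sep="\t")
        table = genome3d.map_tss_to_coords(ann, bins, model)
        table = table[table["mirna_id"].isin(m.signal.index)].reset_index(drop=True)
        clustering = select.dbscan_cluster(table, eps=sel.eps, min_pts=sel.min_pts)
        io.write_clustering(clustering, outdir / "clustering.tsv")
        io.write_cluster_scatter(table, clustering, outdir / "cluster_scatter.tsv")
        panels = {
            "all": select.all_panel(m),
            "top_scc": select.top_k_by_score(scores, k=sel.k_top, p_max=sel.p_max),
            "overlap_3d": select.overlap_3d_panel(m, table),
            "cluster_3d": select.proportional_representatives(
                clustering,
                scores,
                m=sel.m_representatives,
                p_max=sel.p_max if sel.cluster_p_filter else None,
                p_adjust=sel.p_adjust,
            ),
        }
        for name, panel in panels.items():
            io.write_panel(panel.mirna_ids, outdir / f"panel_{name}.txt")
        return [
            "scores.tsv",
            "clustering.tsv",
            "cluster_scatter.tsv",
            *(f"panel_{name}.txt" for name in panels),
        ]

    if stage == "evaluate":
        panel_files = {
            name: f"panel_{name}.txt"
            for name in ("all", "top_scc", "overlap_3d", "cluster_3d")
        }
        _require(
            outdir,
            stage,
            "filtered_expression.tsv",
            "labels.tsv",
            *panel_files.values(),
        )
        m = io.read_expression(outdir / "filtered_expression.tsv", outdir / "labels.tsv")
        panels = []
        for name, fname in panel_files.items():
            ids = io.read_panel(outdir / fname)
            if not ids:
                logger.warning("panel %s is empty; skipping", name)
                continue
            panels.append(select.FeaturePanel(ids, name, {}))
        specs = [evaluate.ModelSpec(family=f) for f in config.model_families]
        metric_rows, score_rows, curve_rows = [], [], []
        for panel in panels:
            for spec in specs:
                pred = evaluate.loocv_predict(m, panel, spec)
                ms = evaluate.compute_metrics(pred)
                metric_rows.append(
                    {
                        "panel": panel.method,
                        "n_features": len(panel),
                        "model": spec.label(),
                        **ms.as_dict(),
                    }
                )
                for sid, sc, tr in zip(pred.sample_ids, pred.scores, pred.truth):
                    score_rows.append(
                        (panel.method, spec.label(), sid, float(sc), int(tr))
                    )
                cd = evaluate.curves(pred)
                for r in cd.roc.itertuples(index=False):
                    curve_rows.append(
                        (panel.method, spec.label(), "roc", r.threshold, r.fpr, r.tpr)
                    )
                for r in cd.pr.itertuples(index=False):
                    curve_rows.append(
                        (panel.method, spec.label(), "pr", r.threshold, r.recall, r.precision)
                    )
        metrics = pd.DataFrame(metric_rows)
        metrics.to_csv(outdir / "metrics.csv", index=False)
        io.write_json(metrics.to_dict(orient="records"), outdir / "metrics.json")
        pd.DataFrame(
            score_rows, columns=["panel", "model", "sample_id", "score", "truth"]
        ).to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        pd.DataFrame(
            curve_rows, columns=["panel", "model", "curve", "threshold", "x", "y"]
        ).to_csv(outdir / "curves.tsv", sep="\t", index=False)
        return ["metrics.csv", "metrics.json", "predictions.tsv", "curves.tsv"]

    raise PipelineError(f"unknown stage {stage!r}")


def planted_panel_experiment(
    base_seed: int = 0,
    n_seeds: int = 20,
    m_panel: int = 20,
    sim: SimConfig | None = None,
    n_restarts: int = 5,
    eps: float = 3.0,
    min_pts: int = 2,
    p_max: float = 0.05,
) -> "pd.DataFrame":
    """Planted-signal recovery study, run fully in memory.

    For each seed: simulate a dataset, reconstruct the 3D model from the
    noisy contacts, profile the expression matrix, build the cluster_3d
    panel of size ``m_panel`` and a size-matched random panel, and evaluate
    both with an SVC under LOOCV.  Returns one row per seed with the
    fraction of planted informative miRNAs recovered by each panel and the
    two AUCs.
    """
    rows = []
    for s in range(n_seeds):
        seed = _stage_seed(base_seed, 1000 + s)
        cfg = replace(sim or SimConfig(), seed=seed)
        ds = synthetic.simulate_dataset(cfg)
        targets = genome3d.contacts_to_distances(
            ds.contacts, alpha=1.0 / cfg.contact_decay_exponent, scale=cfg.contact_scale
        )
        model = genome3d.embed(
            targets, n_restarts=n_restarts, max_iter=300, seed=seed
        )
        m = normalize_by_controls(ds.expression, CONTROL_IDS)
        m = filter_low_expression(m)
        m = filter_ambiguous(m, ds.annotation)
        scores = select.spearman_scores(m)
        table = genome3d.map_tss_to_coords(ds.annotation, ds.bins, model)
        table = table[table["mirna_id"].isin(m.signal.index)].reset_index(drop=True)
        clustering = select.dbscan_cluster(table, eps=eps, min_pts=min_pts)
        cluster_panel = select.proportional_representatives(
            clustering, scores, m=m_panel, p_max=p_max, p_adjust="bh"
        )
        rand_panel = select.random_panel(m.signal.index, size=m_panel, seed=seed)
        info = ds.truth.informative_mirnas
        spec = evaluate.ModelSpec(family="svc")
        auc_cluster = evaluate.compute_metrics(
            evaluate.loocv_predict(m, cluster_panel, spec)
        ).auc
        auc_random = evaluate.compute_metrics(
            evaluate.loocv_predict(m, rand_panel, spec)
        ).auc
        rows.append(
            {
                "seed": seed,
                "n_informative": len(info),
                "recovered_cluster": len(set(cluster_panel.mirna_ids) & info) / len(info),
                "recovered_random": len(set(rand_panel.mirna_ids) & info) / len(info),
                "auc_cluster": auc_cluster,
                "auc_random": auc_random,
                "stress": model.stress,
                "n_clusters_multi": clustering.n_multi,
                "n_clusters_singleton": clustering.n_singletons,
            }
        )
    return pd.DataFrame(rows)
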