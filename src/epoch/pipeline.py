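"""End-to-end synthetic study orchestration.

One validated YAML config drives the full chain: simulate reporter-cell
image fields and quantify NCC per condition; simulate a grouped count
matrix and run DE, senescence-signature extraction and reversal
statistics per treatment; rank genes and run permutation GSEA; train an
age clock on a simulated cohort sharing the experiment's gene model and
report centered delta transcriptomic ages with group comparisons; and
compute the signature association matrix.  Every stage draws from a
named substream of the single global seed, writes TSV/JSON outputs into
its own subdirectory, and contributes key numbers to a machine-readable
run report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, assoc, clock, de, gsea, io, ncc, sim_counts, sim_images
from ._rng import stream_rng

__all__ = ["PipelineConfig", "load_pipeline_config", "make_demo_config", "run_pipeline"]

log = logging.getLogger("epoch.pipeline")


class _Stage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True


class ImagesStage(_Stage):
    """Simulate one field per condition and quantify colocalization."""

    conditions: dict[str, float] = Field(
        default={"quiescent": 0.05, "senescent": 0.8, "senescent+C1": 0.2}
    )
    n_cells: int = 30
    height: int = 256
    width: int = 256
    noise_sd: float = 2.0
    segmentation: str = "truth"  # 'truth' or 'otsu'
    pos_control: str | None = "senescent"
    neg_control: str | None = "quiescent"


class CountsStage(_Stage):
    """Simulate the grouped experiment and run DE / signature / reversal."""

    n_genes: int = 2000
    samples_per_group: int = 4
    groups: list[str] = Field(
        default=["quiescent", "senescent", "senescent+C1", "senescent+C2"]
    )
    n_senescence_genes_up: int = 100
    n_senescence_genes_down: int = 100
    # strong senescence program so reversal-fraction recovery is
    # power-saturated rather than detection-limited
    senescence_log2fc: float = 2.5
    reversal_fraction_up: float = 0.5
    reversal_fraction_down: float = 0.5
    n_age_genes: int = 300
    age_slope_sd: float = 0.02
    dispersion: float = 0.1
    group_ages: dict[str, float] | None = Field(
        default={
            "quiescent": 30.0,
            "senescent": 65.0,
            "senescent+C1": 45.0,
            "senescent+C2": 50.0,
        }
    )
    signature_p_adj: float = 0.01
    signature_fc: float = 2.0
    reversal_p_adj: float = 0.05


class GseaStage(_Stage):
    """Pre-ranked GSEA on the senescence contrast."""

    n_perm: int = 500
    gmt: str | None = None  # user GMT; default: truth sets + random sets
    n_random_sets: int = 5
    random_set_size: int = 30
    padj_cutoff: float = 0.1


class ClockStage(_Stage):
    """Train on a simulated aging cohort, apply to the experiment."""

    cohort_size: int = 120
    age_range: tuple[float, float] = (20.0, 90.0)
    holdout_fraction: float = 0.25
    control_group: str = "quiescent"
    reference_group: str = "senescent"
    l1_ratio: float = 0.5
    cv_folds: int = 5


class AssocStage(_Stage):
    """Spearman association between treatment and senescence signatures."""

    top_n: int = 300


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "epoch_run"
    images: ImagesStage = Field(default_factory=ImagesStage)
    counts: CountsStage = Field(default_factory=CountsStage)
    gsea: GseaStage = Field(default_factory=GseaStage)
    clock: ClockStage = Field(default_factory=ClockStage)
    assoc: AssocStage = Field(default_factory=AssocStage)

    def validate_dependencies(self) -> None:
        needs_counts = [
            name
            for name in ("gsea", "clock", "assoc")
            if getattr(self, name).enabled
        ]
        if needs_counts and not self.counts.enabled:
            raise ValueError(
                f"stages {needs_counts} require the counts stage to be enabled"
            )
        if self.clock.enabled and self.counts.n_age_genes == 0:
            raise ValueError(
                "clock stage requires counts.n_age_genes > 0 (no age signal)"
            )
        if self.clock.enabled:
            for g in (self.clock.control_group, self.clock.reference_group):
                if g not in self.counts.groups:
                    raise ValueError(f"clock group {g!r} not among counts.groups")


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    cfg = PipelineConfig.model_validate(doc)
    cfg.validate_dependencies()
    return cfg


def make_demo_config(outdir="epoch_run", seed: int = 0) -> PipelineConfig:
    """The default demo study: all stages enabled with default settings."""
    cfg = PipelineConfig(seed=seed, outdir=str(outdir))
    cfg.validate_dependencies()
    return cfg


def _count_config(c: CountsStage, seed: int) -> sim_counts.SimCountConfig:
    return sim_counts.SimCountConfig(
        n_genes=c.n_genes,
        samples_per_group=c.samples_per_group,
        groups=tuple(c.groups),
        n_senescence_genes_up=c.n_senescence_genes_up,
        n_senescence_genes_down=c.n_senescence_genes_down,
        senescence_log2fc=c.senescence_log2fc,
        reversal_fraction_up=c.reversal_fraction_up,
        reversal_fraction_down=c.reversal_fraction_down,
        n_age_genes=c.n_age_genes,
        age_slope_sd=c.age_slope_sd,
        dispersion=c.dispersion,
        seed=seed,
    )


def _run_images(cfg: PipelineConfig, outdir: Path) -> dict:
    c = cfg.images
    tables = []
    for i, (condition, fraction) in enumerate(sorted(c.conditions.items())):
        field_seed = int(stream_rng(cfg.seed, "images", condition).integers(2**31))
        im_cfg = sim_images.SimImageConfig(
            height=c.height,
            width=c.width,
            n_cells=c.n_cells,
            mislocalization_fraction=fraction,
            noise_sd=c.noise_sd,
            seed=field_seed,
        )
        field = sim_images.simulate_ncc_field(im_cfg)
        io.write_field(field, outdir / condition.replace("+", "_"))
        if c.segmentation == "truth":
            seg = field.truth_segmentation()
        else:
            seg = ncc.segment_field(field.mcherry, field.egfp)
        tables.append(
            ncc.pearson_colocalization(
                field.mcherry, field.egfp, seg, condition=condition
            )
        )
    cells = pd.concat(
        [t.cells.assign(condition=t.condition) for t in tables], ignore_index=True
    )
    cells.to_csv(outdir / "colocalization_cells.tsv", sep="\t", index=False)
    pos = c.pos_control if c.pos_control in c.conditions else None
    neg = c.neg_control if c.neg_control in c.conditions else None
    screen = ncc.compare_conditions(
        tables, method="anova_bonferroni", pos_control=pos, neg_control=neg
    )
    screen.summary.to_csv(outdir / "condition_summary.tsv", sep="\t", index=False)
    screen.pairwise.to_csv(outdir / "pairwise_tests.tsv", sep="\t", index=False)
    return {
        "mean_r": {
            row["condition"]: round(row["mean_r"], 4)
            for _, row in screen.summary.iterrows()
        },
        "anova_p": screen.anova_p,
        "z_factor": None if screen.z_factor is None else round(screen.z_factor, 4),
    }


def _run_counts(cfg: PipelineConfig, outdir: Path) -> tuple[dict, dict]:
    c = cfg.counts
    sim_seed = int(stream_rng(cfg.seed, "counts-stage").integers(2**31))
    sc = _count_config(c, sim_seed)
    matrix = sim_counts.simulate_counts(sc, group_ages=c.group_ages)
    io.write_counts_tsv(matrix, outdir)
    matrix.truth["genes"].to_csv(outdir / "gene_truth.tsv", sep="\t")

    sen_de = de.de_test(matrix, "quiescent", "senescent")
    sen_de.table.to_csv(outdir / "de_senescent_vs_quiescent.tsv", sep="\t")
    signature = de.extract_signature(sen_de, c.signature_p_adj, c.signature_fc)
    pd.concat(
        [signature.up.assign(direction="up"), signature.down.assign(direction="down")]
    ).to_csv(outdir / "senescence_signature.tsv", sep="\t")

    treatments = [g for g in c.groups if "senescent" in g and g != "senescent"]
    treatment_de = {}
    reversal = {}
    for g in treatments:
        tde = de.de_test(matrix, "senescent", g)
        tde.table.to_csv(outdir / f"de_{g.replace('+', '_')}_vs_senescent.tsv", sep="\t")
        treatment_de[g] = tde
        summ = de.classify_reversal(signature, tde, c.reversal_p_adj)
        summ.table.to_csv(outdir / f"reversal_{g.replace('+', '_')}.tsv", sep="\t")
        reversal[g] = {
            d: {
                "reversed_pct": summ.reversed_pct(d),
                "reversed": int(summ.table.loc[d, "reversed"]),
                "total": int(summ.table.loc[d, "total"]),
            }
            for d in ("up", "down")
        }
    key = {
        "n_signature_up": len(signature.up_genes),
        "n_signature_down": len(signature.down_genes),
        "reversal": reversal,
    }
    state = {
        "matrix": matrix,
        "sen_de": sen_de,
        "treatment_de": treatment_de,
        "signature": signature,
        "sim_config": sc,
    }
    return key, state


def _run_gsea(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    c = cfg.gsea
    ranked = gsea.rank_metric(state["sen_de"])
    ranked.to_frame().to_csv(outdir / "ranks.tsv", sep="\t", index=False)
    if c.gmt is not None:
        sets = io.read_gmt(c.gmt)
    else:
        truth = state["matrix"].truth["genes"]
        sets = {
            "senescence_up": list(truth.index[truth["sen_direction"] == "up"]),
            "senescence_down": list(truth.index[truth["sen_direction"] == "down"]),
        }
        rng = stream_rng(cfg.seed, "gsea-random-sets")
        genes = np.asarray(truth.index)
        for i in range(c.n_random_sets):
            sets[f"random_{i + 1}"] = list(
                rng.choice(genes, size=c.random_set_size, replace=False)
            )
        io.write_gmt(sets, outdir / "gene_sets.gmt")
    perm_seed = int(stream_rng(cfg.seed, "gsea-perm").integers(2**31))
    table = gsea.gsea_preranked(
        ranked, sets, n_perm=c.n_perm, seed=perm_seed, padj_cutoff=c.padj_cutoff
    )
    table.table.to_csv(outdir / "enrichment.tsv", sep="\t")
    sig = table.table[table.table["significant"]]
    return {
        "n_sets": int(len(table.table)),
        "significant_sets": {
            name: round(float(row["nes"]), 3) for name, row in sig.iterrows()
        },
    }


def _run_clock(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    c = cfg.clock
    counts_cfg = state["sim_config"]
    cohort_seed = int(stream_rng(cfg.seed, "clock-cohort").integers(2**31))
    cohort_cfg = sim_counts.SimCountConfig(
        n_genes=counts_cfg.n_genes,
        samples_per_group=c.cohort_size,
        groups=("cohort",),
        n_senescence_genes_up=counts_cfg.n_senescence_genes_up,
        n_senescence_genes_down=counts_cfg.n_senescence_genes_down,
        senescence_log2fc=counts_cfg.senescence_log2fc,
        n_age_genes=counts_cfg.n_age_genes,
        age_slope_sd=counts_cfg.age_slope_sd,
        dispersion=counts_cfg.dispersion,
        age_range=c.age_range,
        seed=cohort_seed,
    )
    cohort = sim_counts.simulate_clock_cohort(
        cohort_cfg, gene_truth=state["matrix"].truth["genes"]
    )

    samples = list(cohort.counts.columns)
    rng = stream_rng(cfg.seed, "clock-split")
    order = rng.permutation(len(samples))
    n_hold = max(2, int(round(c.holdout_fraction * len(samples))))
    hold = [samples[i] for i in order[:n_hold]]
    train = [samples[i] for i in order[n_hold:]]

    def subset(ids):
        return sim_counts.CountMatrix(
            counts=cohort.counts[ids], sample_metadata=cohort.sample_metadata.loc[ids]
        )

    train_cm, hold_cm = subset(train), subset(hold)
    scaled = clock.preprocess_expression(train_cm)
    model = clock.train_clock(
        scaled,
        train_cm.sample_metadata["age"],
        l1_ratio=c.l1_ratio,
        cv_folds=c.cv_folds,
        seed=int(stream_rng(cfg.seed, "clock-train").integers(2**31)),
    )
    model.to_json(outdir / "clock_model.json")

    hold_scaled = clock.impute_missing(
        clock.preprocess_expression(hold_cm, model), model
    )
    hold_pred = clock.predict_tage(model, hold_scaled)
    holdout_r = float(
        np.corrcoef(hold_pred, hold_cm.sample_metadata["age"])[0, 1]
    )

    experiment = state["matrix"]
    exp_scaled = clock.impute_missing(
        clock.preprocess_expression(experiment, model), model
    )
    tages = clock.predict_tage(model, exp_scaled)
    table = clock.build_tage_table(
        tages, experiment.sample_metadata, c.control_group
    )
    table.to_csv(outdir / "tage_table.tsv", sep="\t", index_label="sample_id")
    comparisons = clock.compare_tage_groups(table, c.reference_group)
    comparisons.to_csv(outdir / "tage_comparisons.tsv", sep="\t", index=False)
    group_delta = table.groupby("group")["delta_tAge"].median()
    return {
        "holdout_age_r": round(holdout_r, 4),
        "median_delta_tage": {g: round(v, 2) for g, v in group_delta.items()},
        "comparisons": {
            row["comparison"]: round(row["p_adj"], 4)
            for _, row in comparisons.iterrows()
        },
    }


def _run_assoc(cfg: PipelineConfig, outdir: Path, state: dict) -> dict:
    results = {"senescence": state["sen_de"]}
    results.update(state["treatment_de"])
    collection = assoc.SignatureCollection.from_de_results(results)
    mat = assoc.association_matrix(collection, top_n=cfg.assoc.top_n)
    mat.rho.to_csv(outdir / "association_rho.tsv", sep="\t")
    mat.p.to_csv(outdir / "association_p.tsv", sep="\t")
    mat.p_adj.to_csv(outdir / "association_p_adj.tsv", sep="\t")
    treatments = [n for n in collection.names() if n != "senescence"]
    return {
        "rho_vs_senescence": {
            g: round(float(mat.rho.loc["senescence", g]), 3) for g in treatments
        }
    }


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute the enabled stages in dependency order and write a report.

    Returns the run report (also written as ``report.json``); a stage
    failure is recorded in the report and re-raised after the report is
    written.  Identical config and seed reproduce identical numbers.
    """
    config.validate_dependencies()
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    config_doc = config.model_dump(mode="json")
    report = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config_doc, sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }

    state: dict = {}
    failure: Exception | None = None
    runners = [
        ("images", _run_images, False),
        ("counts", _run_counts, True),
        ("gsea", _run_gsea, None),
        ("clock", _run_clock, None),
        ("assoc", _run_assoc, None),
    ]
    for name, runner, _ in runners:
        stage_cfg = getattr(config, name)
        if not stage_cfg.enabled:
            report["stages"][name] = {"status": "skipped"}
            continue
        stage_dir = outdir / name
        stage_dir.mkdir(exist_ok=True)
        t0 = time.time()
        try:
            if name == "images":
                key = runner(config, stage_dir)
            elif name == "counts":
                key, state = runner(config, stage_dir)
            else:
                key = runner(config, stage_dir, state)
        except Exception as exc:  # record, then re-raise after writing report
            log.exception("stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            failure = exc
            break
        report["stages"][name] = {
            "status": "ok",
            "seconds": round(time.time() - t0, 2),
            "key_outputs": key,
        }
        log.info("stage %s finished in %.1fs", name, time.time() - t0)

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    lines = [f"epoch {__version__} run (seed {config.seed})"]
    for name, st in report["stages"].items():
        lines.append(f"  {name}: {st['status']}")
        if "key_outputs" in st:
            lines.append("    " + json.dumps(st["key_outputs"], sort_keys=True))
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    if failure is not None:
        raise failure
    return report
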