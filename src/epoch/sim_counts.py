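"""Synthetic bulk RNA-seq counts for senescence / treatment / aging designs.

Counts are negative-binomial with a log2-scale mean model per gene and
sample::

    log2 mu_gs = b_g + senescence(g, group_s) + slope_g * (age_s - 50)

where ``b_g`` is a gene's baseline (Normal on the log2 scale),
``senescence`` adds +/- ``senescence_log2fc`` for the designated
senescence-responsive genes in senescent groups (cancelled for the
"reversed" subset in treated groups), and ``slope_g`` is the per-year
aging slope of the designated age-dependent genes.  Relative abundances
are rescaled so each sample's expected total equals its library size
(sampled log-uniform), and counts are drawn NB with dispersion phi
(variance mu + phi * mu^2).

Group label semantics: ``quiescent`` (or any label not containing
"senescent") is baseline; the label ``senescent`` gets the full
senescence effect; any other label containing "senescent"
(e.g. ``senescent+C1``) is a treated senescent group in which the
reversed genes return to baseline.

The gene-level truth table returned with each matrix can be passed back
via ``gene_truth=`` to simulate further cohorts on the same gene model —
this is how a clock trained on an aging cohort is applied to a
treatment experiment sharing the same age-dependent genes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream_rng

__all__ = [
    "SimCountConfig",
    "CountMatrix",
    "simulate_counts",
    "simulate_clock_cohort",
]

_AGE_REFERENCE = 50.0  # years; age effects are slopes around this pivot
_BASE_LOG2_MEAN = 5.0
_BASE_LOG2_SD = 2.0


@dataclass
class SimCountConfig:
    """Parameters of one simulated count matrix."""

    n_genes: int = 2000
    samples_per_group: int = 4
    groups: tuple[str, ...] = ("quiescent", "senescent")
    n_senescence_genes_up: int = 100
    n_senescence_genes_down: int = 100
    senescence_log2fc: float = 2.0
    reversal_fraction_up: float = 0.5
    reversal_fraction_down: float = 0.5
    n_age_genes: int = 0
    age_slope_sd: float = 0.02
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (2e5, 5e5)
    ages: tuple[float, ...] | None = None
    age_range: tuple[float, float] = (20.0, 90.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.samples_per_group <= 0:
            raise ValueError("n_genes and samples_per_group must be positive")
        if not self.groups:
            raise ValueError("at least one group label required")
        for name in (
            "n_senescence_genes_up",
            "n_senescence_genes_down",
            "n_age_genes",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_special = (
            self.n_senescence_genes_up + self.n_senescence_genes_down + self.n_age_genes
        )
        if n_special > self.n_genes:
            raise ValueError("more special genes requested than n_genes")
        for name in ("reversal_fraction_up", "reversal_fraction_down"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must satisfy 0 < lo <= hi")
        if self.ages is not None and any(a < 0 for a in self.ages):
            raise ValueError("ages must be non-negative")


@dataclass
class CountMatrix:
    """Gene-by-sample integer counts plus per-sample metadata.

    ``sample_metadata`` is indexed by sample id with columns ``group``,
    ``age`` (years, NaN if unknown) and ``library_size``.  For simulated
    matrices ``truth`` carries the gene-level ground truth
    (baseline mean, senescence direction/effect, reversed flag, age
    slope) and the generating config.
    """

    counts: pd.DataFrame
    sample_metadata: pd.DataFrame
    truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.columns.equals(self.sample_metadata.index):
            raise ValueError("sample metadata does not match count columns")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def samples_in_group(self, group: str) -> list[str]:
        md = self.sample_metadata
        return list(md.index[md["group"] == group])


def _make_gene_truth(cfg: SimCountConfig) -> pd.DataFrame:
    rng = stream_rng(cfg.seed, "genes")
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    base = rng.normal(_BASE_LOG2_MEAN, _BASE_LOG2_SD, size=cfg.n_genes)

    order = rng.permutation(cfg.n_genes)
    n_up, n_down, n_age = (
        cfg.n_senescence_genes_up,
        cfg.n_senescence_genes_down,
        cfg.n_age_genes,
    )
    up_idx = order[:n_up]
    down_idx = order[n_up : n_up + n_down]
    age_idx = order[n_up + n_down : n_up + n_down + n_age]

    direction = np.array([""] * cfg.n_genes, dtype=object)
    direction[up_idx] = "up"
    direction[down_idx] = "down"
    effect = np.zeros(cfg.n_genes)
    effect[up_idx] = cfg.senescence_log2fc
    effect[down_idx] = -cfg.senescence_log2fc

    reversed_flag = np.zeros(cfg.n_genes, dtype=bool)
    n_rev_up = int(round(cfg.reversal_fraction_up * n_up))
    n_rev_down = int(round(cfg.reversal_fraction_down * n_down))
    if n_rev_up:
        reversed_flag[rng.choice(up_idx, size=n_rev_up, replace=False)] = True
    if n_rev_down:
        reversed_flag[rng.choice(down_idx, size=n_rev_down, replace=False)] = True

    slope = np.zeros(cfg.n_genes)
    if n_age:
        slope[age_idx] = rng.normal(0.0, cfg.age_slope_sd, size=n_age)

    return pd.DataFrame(
        {
            "gene": genes,
            "base_log2_mean": base,
            "sen_direction": direction,
            "sen_log2fc": effect,
            "reversed": reversed_flag,
            "age_slope": slope,
        }
    ).set_index("gene")


def _group_effect(gene_truth: pd.DataFrame, group: str) -> np.ndarray:
    """Log2 senescence shift of every gene in the given group."""
    if "senescent" not in group:
        return np.zeros(len(gene_truth))
    effect = gene_truth["sen_log2fc"].to_numpy().copy()
    if group != "senescent":  # treated senescent group: reversed genes revert
        effect[gene_truth["reversed"].to_numpy()] = 0.0
    return effect


def _simulate(
    cfg: SimCountConfig, gene_truth: pd.DataFrame, samples: pd.DataFrame
) -> CountMatrix:
    rng = stream_rng(cfg.seed, "counts")
    n_genes, n_samples = len(gene_truth), len(samples)

    log_lo, log_hi = np.log(cfg.library_size_range[0]), np.log(
        cfg.library_size_range[1]
    )
    lib_sizes = np.exp(rng.uniform(log_lo, log_hi, size=n_samples))

    base = gene_truth["base_log2_mean"].to_numpy()
    slope = gene_truth["age_slope"].to_numpy()
    log2_mu = np.empty((n_genes, n_samples))
    for j, (_, row) in enumerate(samples.iterrows()):
        mu_j = base + _group_effect(gene_truth, row["group"])
        if np.isfinite(row["age"]):
            mu_j = mu_j + slope * (row["age"] - _AGE_REFERENCE)
        log2_mu[:, j] = mu_j

    rel = np.exp2(log2_mu)
    mu = rel * (lib_sizes / rel.sum(axis=0))

    phi = cfg.dispersion
    counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))

    metadata = samples.copy()
    metadata["library_size"] = lib_sizes
    counts_df = pd.DataFrame(
        counts, index=gene_truth.index, columns=metadata.index
    )
    return CountMatrix(
        counts=counts_df,
        sample_metadata=metadata,
        truth={"genes": gene_truth.copy(), "config": dataclasses.replace(cfg)},
    )


def simulate_counts(
    config: SimCountConfig,
    *,
    gene_truth: pd.DataFrame | None = None,
    group_ages: dict[str, float] | None = None,
) -> CountMatrix:
    """Simulate a grouped experiment (quiescent / senescent / treated).

    ``gene_truth`` reuses the gene model of a previous simulation (same
    baselines, senescence assignments and age slopes).  ``group_ages``
    optionally assigns one age to every sample of a group, activating the
    age-dependent genes; otherwise ``config.ages`` (one entry per sample,
    group-major order) or no age signal at all.  Seeded determinism.
    """
    config.validate()
    if gene_truth is None:
        gene_truth = _make_gene_truth(config)

    rows = []
    for g in config.groups:
        for k in range(config.samples_per_group):
            rows.append({"sample_id": f"{g}_{k + 1}", "group": g, "age": np.nan})
    samples = pd.DataFrame(rows).set_index("sample_id")
    if group_ages is not None:
        samples["age"] = [group_ages.get(g, np.nan) for g in samples["group"]]
    elif config.ages is not None:
        if len(config.ages) != len(samples):
            raise ValueError("config.ages length must equal the number of samples")
        samples["age"] = list(config.ages)
    return _simulate(config, gene_truth, samples)


def simulate_clock_cohort(
    config: SimCountConfig, *, gene_truth: pd.DataFrame | None = None
) -> CountMatrix:
    """Simulate an aging cohort with known chronological ages.

    Ages come from ``config.ages`` or are sampled uniformly over
    ``config.age_range``; metadata carries the true ages.  The cohort
    uses a single group label per entry of ``config.groups`` (typically
    just ``("cohort",)``), with ``samples_per_group`` samples each.
    """
    config.validate()
    if gene_truth is None:
        gene_truth = _make_gene_truth(config)

    rows = []
    for g in config.groups:
        for k in range(config.samples_per_group):
            rows.append({"sample_id": f"{g}_{k + 1}", "group": g, "age": np.nan})
    samples = pd.DataFrame(rows).set_index("sample_id")
    if config.ages is not None:
        if len(config.ages) != len(samples):
            raise ValueError("config.ages length must equal the number of samples")
        ages = np.asarray(config.ages, dtype=float)
    else:
        lo, hi = config.age_range
        if not (0 <= lo <= hi):
            raise ValueError("age_range must be non-negative and ordered")
        ages = stream_rng(config.seed, "ages").uniform(lo, hi, size=len(samples))
    if np.any(ages < 0) or not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite and non-negative")
    samples["age"] = ages
    return _simulate(config, gene_truth, samples)
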