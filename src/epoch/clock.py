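"""Penalized linear transcriptomic age clock.

The clock is an elastic-net linear regression of chronological age
(years) on scaled log expression: counts are median-of-ratios
normalized, log2(x+1) transformed, and z-scaled per gene.  The trained
model stores everything needed for standalone application — gene ids,
coefficients, intercept, and the per-gene training means/SDs used both
for scaling new cohorts and for imputing clock genes absent from them
(an absent gene is filled with its training mean, i.e. z = 0, so it
contributes nothing beyond the intercept).

Predicted transcriptomic ages (tAge) are reported as deltas centered on
the median tAge of a designated control group (quiescent cells in a
rejuvenation experiment), and group differences are assessed with
two-sided independent t-tests (Welch by default) under BH adjustment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .de import bh_adjust, normalized_counts
from .sim_counts import CountMatrix

__all__ = [
    "ClockModel",
    "ScaledExpression",
    "preprocess_expression",
    "impute_missing",
    "train_clock",
    "predict_tage",
    "center_tage",
    "compare_tage_groups",
    "build_tage_table",
]


@dataclass
class ClockModel:
    """Trained linear age clock with its scaling statistics."""

    genes: list[str]
    coef: np.ndarray
    intercept: float
    gene_means: np.ndarray
    gene_sds: np.ndarray
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        n = len(self.genes)
        for name in ("coef", "gene_means", "gene_sds"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per gene")
        if np.any(self.gene_sds <= 0):
            raise ValueError("gene SDs must be positive")

    def to_json(self, path) -> None:
        doc = {
            "genes": list(self.genes),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "gene_means": self.gene_means.tolist(),
            "gene_sds": self.gene_sds.tolist(),
            "hyperparams": self.hyperparams,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClockModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            genes=doc["genes"],
            coef=np.asarray(doc["coef"], dtype=float),
            intercept=float(doc["intercept"]),
            gene_means=np.asarray(doc["gene_means"], dtype=float),
            gene_sds=np.asarray(doc["gene_sds"], dtype=float),
            hyperparams=doc.get("hyperparams", {}),
            seed=doc.get("seed", 0),
        )


@dataclass
class ScaledExpression:
    """Z-scaled log expression (genes x samples) plus the scaling stats."""

    z: pd.DataFrame
    gene_means: pd.Series
    gene_sds: pd.Series
    from_model: bool = False
    n_imputed: int = 0


def preprocess_expression(
    counts: CountMatrix, model: ClockModel | None = None
) -> ScaledExpression:
    """log2(normalized + 1) then per-gene z-scaling.

    Training mode (no model): cohort means/SDs are computed and returned;
    genes with zero SD are excluded from scaling (they carry no signal).
    Application mode: the model's genes, means and SDs are used; clock
    genes absent from the input are left missing for
    :func:`impute_missing` to fill.
    """
    y = np.log2(normalized_counts(counts) + 1.0)
    if model is None:
        means = y.mean(axis=1)
        sds = y.std(axis=1, ddof=0)
        keep = sds > 0
        y = y.loc[keep]
        z = y.sub(means[keep], axis=0).div(sds[keep], axis=0)
        return ScaledExpression(
            z=z, gene_means=means[keep], gene_sds=sds[keep], from_model=False
        )
    means = pd.Series(model.gene_means, index=model.genes)
    sds = pd.Series(model.gene_sds, index=model.genes)
    y = y.reindex(model.genes)  # absent clock genes become NaN rows
    z = y.sub(means, axis=0).div(sds, axis=0)
    return ScaledExpression(z=z, gene_means=means, gene_sds=sds, from_model=True)


def impute_missing(scaled: ScaledExpression, model: ClockModel) -> ScaledExpression:
    """Fill clock genes absent from the input with their training mean.

    On the z scale the training mean is 0, so imputed genes contribute
    nothing beyond the intercept.  The number of imputed gene rows is
    reported on the result.
    """
    z = scaled.z.reindex(model.genes)
    missing = z.isna().all(axis=1)
    n_imputed = int(missing.sum())
    z = z.fillna(0.0)
    return ScaledExpression(
        z=z,
        gene_means=pd.Series(model.gene_means, index=model.genes),
        gene_sds=pd.Series(model.gene_sds, index=model.genes),
        from_model=True,
        n_imputed=n_imputed,
    )


def train_clock(
    scaled: ScaledExpression,
    ages,
    l1_ratio: float = 0.5,
    alphas=None,
    cv_folds: int = 5,
    seed: int = 0,
    max_iter: int = 5000,
) -> ClockModel:
    """Fit an elastic-net age clock on training-mode scaled expression.

    The penalty strength is chosen by ``cv_folds``-fold cross-validated
    mean squared error over ``alphas`` (default: 30 values log-spaced
    over six decades).  Deterministic for fixed data and seed.
    """
    if scaled.from_model:
        raise ValueError("train_clock requires training-mode scaling")
    ages = np.asarray(ages, dtype=float)
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    n = scaled.z.shape[1]
    if len(ages) != n:
        raise ValueError("one age per sample required")
    if np.ptp(ages) == 0:
        raise ValueError("constant ages: nothing to fit")
    if not 2 <= cv_folds <= n:
        raise ValueError("need n samples >= cv_folds >= 2")
    if alphas is None:
        alphas = np.logspace(-3, 3, 30)

    x = scaled.z.to_numpy().T  # samples x genes
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=int(seed) & 0x7FFFFFFF)
    fit = ElasticNetCV(
        l1_ratio=l1_ratio, alphas=alphas, cv=cv, max_iter=max_iter
    ).fit(x, ages)
    return ClockModel(
        genes=list(scaled.z.index),
        coef=fit.coef_,
        intercept=float(fit.intercept_),
        gene_means=scaled.gene_means.to_numpy(),
        gene_sds=scaled.gene_sds.to_numpy(),
        hyperparams={
            "l1_ratio": l1_ratio,
            "alpha": float(fit.alpha_),
            "cv_folds": cv_folds,
            "n_training_samples": n,
        },
        seed=seed,
    )


def predict_tage(model: ClockModel, scaled: ScaledExpression) -> pd.Series:
    """Transcriptomic age per sample: intercept + coef . z."""
    if not scaled.from_model:
        raise ValueError(
            "input must be preprocessed (and imputed) with this model; "
            "call preprocess_expression(counts, model) then impute_missing"
        )
    z = scaled.z.reindex(model.genes)
    if z.isna().any().any():
        raise ValueError("missing clock genes; run impute_missing first")
    tage = model.intercept + z.to_numpy().T @ model.coef
    return pd.Series(tage, index=scaled.z.columns, name="tAge")


def center_tage(tages: pd.Series, control_ids) -> pd.Series:
    """Delta tAge: tAge minus the median tAge of the control samples."""
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("control set is empty")
    missing = [c for c in control_ids if c not in tages.index]
    if missing:
        raise KeyError(f"control samples not found: {missing}")
    delta = tages - float(tages.loc[control_ids].median())
    delta.name = "delta_tAge"
    return delta


def build_tage_table(
    tages: pd.Series, metadata: pd.DataFrame, control_group: str
) -> pd.DataFrame:
    """Per-sample tAge table with deltas centered on the control group."""
    md = metadata.loc[tages.index]
    controls = md.index[md["group"] == control_group]
    if len(controls) == 0:
        raise ValueError(f"no samples in control group {control_group!r}")
    delta = center_tage(tages, controls)
    return pd.DataFrame(
        {"group": md["group"], "tAge": tages, "delta_tAge": delta}
    )


def compare_tage_groups(
    table: pd.DataFrame,
    reference_group: str,
    test_groups=None,
    *,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sided independent t-tests of delta tAge, reference vs each test.

    Welch form by default; p-values BH-adjusted across the pairs.
    """
    groups = table["group"]
    if test_groups is None:
        test_groups = [g for g in pd.unique(groups) if g != reference_group]
    ref = table.loc[groups == reference_group, "delta_tAge"].to_numpy()
    if ref.size < 2:
        raise ValueError("reference group needs >= 2 samples")
    rows = []
    for g in test_groups:
        vals = table.loc[groups == g, "delta_tAge"].to_numpy()
        if vals.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
        t, p = stats.ttest_ind(vals, ref, equal_var=equal_var)
        p = float(p) if np.isfinite(p) else 1.0
        rows.append(
            {
                "comparison": f"{g} vs {reference_group}",
                "mean_delta": float(vals.mean() - ref.mean()),
                "statistic": float(t) if np.isfinite(t) else 0.0,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
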