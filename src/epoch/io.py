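"""Reading and writing the package's on-disk formats.

Images: per-channel 16-bit TIFF (float channels linearly scaled to the
uint16 range, scale recorded in a sidecar) and integer label TIFFs.
Counts: TSV (genes in rows, header = sample ids) and MatrixMarket with
gene/sample sidecar TSVs.  Gene sets: GMT.  Configs: YAML with every
dataclass field as a key.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from gseapy import read_gmt as _read_gmt
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .sim_counts import CountMatrix, SimCountConfig
from .sim_images import SimImageConfig, SimulatedField

__all__ = [
    "write_field",
    "read_channel_tiff",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_mtx",
    "read_counts_mtx",
    "read_gmt",
    "write_gmt",
    "load_image_config",
    "load_count_config",
    "read_signature_table",
]

_U16_MAX = 65535


def write_field(field: SimulatedField, outdir) -> dict[str, Path]:
    """Write a simulated field: channel TIFFs, label TIFFs, truth TSV.

    Float channels are scaled linearly to 16-bit; the per-channel scale
    factors are stored in ``scales.json`` so intensities are recoverable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    scales = {}
    for name, chan in (("mcherry", field.mcherry), ("egfp", field.egfp)):
        peak = float(chan.max())
        scale = _U16_MAX / peak if peak > 0 else 1.0
        arr = np.round(chan * scale).astype(np.uint16)
        path = outdir / f"{name}.tif"
        tifffile.imwrite(path, arr)
        paths[name] = path
        scales[name] = scale
    for name, lab in (
        ("nucleus_labels", field.nucleus_labels),
        ("cytoplasm_labels", field.cytoplasm_labels),
    ):
        path = outdir / f"{name}.tif"
        tifffile.imwrite(path, lab.astype(np.uint16))
        paths[name] = path
    truth_path = outdir / "per_cell_truth.tsv"
    field.per_cell_truth.to_csv(truth_path, sep="\t", index=False)
    paths["per_cell_truth"] = truth_path
    scales_path = outdir / "scales.json"
    scales_path.write_text(json.dumps(scales))
    paths["scales"] = scales_path
    return paths


def read_channel_tiff(path, scale: float | None = None) -> np.ndarray:
    """Read one channel TIFF as float, undoing a recorded linear scale."""
    arr = tifffile.imread(path).astype(float)
    if scale is not None:
        arr /= scale
    return arr


def write_counts_tsv(counts: CountMatrix, outdir, prefix: str = "counts"):
    """Counts as TSV (genes x samples) plus a sample metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_path = outdir / f"{prefix}.tsv"
    counts.counts.to_csv(counts_path, sep="\t", index_label="gene")
    meta_path = outdir / f"{prefix}_metadata.tsv"
    counts.sample_metadata.to_csv(meta_path, sep="\t", index_label="sample_id")
    return counts_path, meta_path


def read_counts_tsv(counts_path, metadata_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    if "age" not in meta.columns:
        meta["age"] = np.nan
    if list(counts.columns) != list(meta.index):
        raise ValueError("metadata samples do not match count matrix columns")
    counts.columns = meta.index
    return CountMatrix(counts=counts, sample_metadata=meta)


def write_counts_mtx(counts: CountMatrix, outdir, prefix: str = "counts"):
    """Counts as MatrixMarket plus gene / sample sidecar TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mtx_path = outdir / f"{prefix}.mtx"
    mmwrite(str(mtx_path), csr_matrix(counts.counts.to_numpy()))
    genes_path = outdir / f"{prefix}_genes.tsv"
    pd.Series(counts.gene_ids, name="gene").to_csv(
        genes_path, sep="\t", index=False
    )
    meta_path = outdir / f"{prefix}_samples.tsv"
    counts.sample_metadata.to_csv(meta_path, sep="\t", index_label="sample_id")
    return mtx_path, genes_path, meta_path


def read_counts_mtx(mtx_path, genes_path, samples_path) -> CountMatrix:
    mat = np.asarray(mmread(str(mtx_path)).todense())
    genes = pd.read_csv(genes_path, sep="\t")["gene"].tolist()
    meta = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    if "age" not in meta.columns:
        meta["age"] = np.nan
    counts = pd.DataFrame(mat.astype(int), index=genes, columns=meta.index)
    return CountMatrix(counts=counts, sample_metadata=meta)


def read_gmt(path) -> dict[str, list[str]]:
    """Gene sets from a GMT file (name, description, members per line)."""
    return _read_gmt(str(path))


def write_gmt(sets: dict, path, description: str = "") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
    return path


def _load_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping of config keys")
    return doc


def _build_config(cls, doc: dict):
    fields = {f.name for f in cls.__dataclass_fields__.values()}
    unknown = set(doc) - fields
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)} for {cls.__name__}")
    tupled = {
        k: tuple(v) if isinstance(v, list) else v for k, v in doc.items()
    }
    cfg = cls(**tupled)
    cfg.validate()
    return cfg


def load_image_config(path) -> SimImageConfig:
    return _build_config(SimImageConfig, _load_yaml(path))


def load_count_config(path) -> SimCountConfig:
    return _build_config(SimCountConfig, _load_yaml(path))


def read_signature_table(path) -> dict[str, pd.DataFrame]:
    """Signatures from a long-format TSV: signature, gene, log2fc, p."""
    df = pd.read_csv(path, sep="\t")
    needed = {"signature", "gene", "log2fc", "p"}
    if missing := needed - set(df.columns):
        raise ValueError(f"signature table missing columns {sorted(missing)}")
    return {
        name: sub.set_index("gene")[["log2fc", "p"]]
        for name, sub in df.groupby("signature", sort=False)
    }
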