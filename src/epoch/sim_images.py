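"""Synthetic two-channel NCC reporter fields.

Simulates fields of reporter cells carrying a nuclear mCherry (NLS) and a
cytoplasmic eGFP (NES) marker.  In the healthy phenotype the two channels
are spatially separated; the senescent phenotype is emulated by relocating
a fraction of each cell's total mCherry mass from the nucleus into
cytoplasmic puncta, where it colocalizes with eGFP.  Geometry is
deliberately simple — concentric disk nuclei and annular cytoplasms —
because the downstream readouts depend only on how intensity is
co-distributed between the two channels, not on realistic morphology.

Intensity bookkeeping is exact: per-cell channel mass is allocated by
pixel-sum normalization, so total mCherry per cell is conserved across
mislocalization settings (signal is relocated, never created) and the
``per_cell_truth`` table records realized ground truth for every cell.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream_rng

__all__ = ["SimImageConfig", "SimulatedField", "simulate_ncc_field"]

# Per-cell channel masses (arbitrary intensity units). Values only set the
# overall dynamic range; all readouts are invariant to the absolute scale.
_MCHERRY_MASS = 50_000.0
_EGFP_MASS = 30_000.0

_MAX_PLACEMENT_TRIES = 2000


@dataclass
class SimImageConfig:
    """Parameters of one simulated reporter field.

    ``mislocalization_fraction`` is the fraction of each cell's total
    mCherry mass relocated from the nucleus into cytoplasmic puncta;
    ``egfp_nuclear_leak`` is the fraction of eGFP mass leaking into the
    nucleus.  Radii and coordinates are in pixels, intensities in
    arbitrary units.
    """

    height: int = 256
    width: int = 256
    n_cells: int = 20
    nucleus_radius_range: tuple[float, float] = (5.0, 8.0)
    cytoplasm_radius_range: tuple[float, float] = (11.0, 15.0)
    mislocalization_fraction: float = 0.0
    puncta_per_cell: int = 6
    puncta_radius: float = 1.5
    egfp_nuclear_leak: float = 0.05
    background_level: float = 10.0
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.mislocalization_fraction <= 1.0:
            raise ValueError("mislocalization_fraction must lie in [0, 1]")
        if not 0.0 <= self.egfp_nuclear_leak <= 1.0:
            raise ValueError("egfp_nuclear_leak must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.height <= 0 or self.width <= 0 or self.n_cells <= 0:
            raise ValueError("height, width and n_cells must be positive")
        if self.puncta_per_cell <= 0 or self.puncta_radius <= 0:
            raise ValueError("puncta_per_cell and puncta_radius must be positive")
        for name in ("nucleus_radius_range", "cytoplasm_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")
        if self.nucleus_radius_range[1] >= self.cytoplasm_radius_range[0]:
            raise ValueError("cytoplasm radii must exceed nucleus radii")


@dataclass
class SimulatedField:
    """A simulated field plus its ground truth.

    ``nucleus_labels`` / ``cytoplasm_labels`` share cell ids (label 0 is
    background); ``per_cell_truth`` has one row per cell with the realized
    mislocalization fraction and puncta count.
    """

    mcherry: np.ndarray
    egfp: np.ndarray
    nucleus_labels: np.ndarray
    cytoplasm_labels: np.ndarray
    per_cell_truth: pd.DataFrame
    config: SimImageConfig = field(repr=False, default=None)

    def truth_segmentation(self):
        """Ground-truth masks packaged as a segmentation result."""
        from .ncc import SegmentationResult

        ids = sorted(int(i) for i in np.unique(self.nucleus_labels) if i != 0)
        return SegmentationResult(
            nucleus_labels=self.nucleus_labels.copy(),
            cytoplasm_labels=self.cytoplasm_labels.copy(),
            cell_ids=ids,
        )


def _place_cells(cfg: SimImageConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping cell centers that fit the canvas."""
    centers: list[tuple[float, float]] = []
    radii_n: list[float] = []
    radii_c: list[float] = []
    for _ in range(cfg.n_cells):
        rn = rng.uniform(*cfg.nucleus_radius_range)
        rc = rng.uniform(*cfg.cytoplasm_radius_range)
        placed = False
        for _try in range(_MAX_PLACEMENT_TRIES):
            cy = rng.uniform(rc + 1, cfg.height - rc - 1)
            cx = rng.uniform(rc + 1, cfg.width - rc - 1)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 > (rc + oc + 1.0) ** 2
                for (oy, ox), oc in zip(centers, radii_c)
            ):
                centers.append((cy, cx))
                radii_n.append(rn)
                radii_c.append(rc)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"canvas {cfg.height}x{cfg.width} too small to place "
                f"{cfg.n_cells} non-overlapping cells"
            )
    return centers, radii_n, radii_c


def _gaussian_spot(mass: float, cy: float, cx: float, sigma: float, shape):
    """Pixel indices and intensities of a 3-sigma truncated Gaussian spot.

    The spot is normalized by its pixel sum so the deposited mass is exact.
    """
    h, w = shape
    r = 3.0 * sigma
    y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
    x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
    y0, x0 = max(y0, 0), max(x0, 0)
    y1, x1 = min(y1, h), min(x1, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    g = np.exp(-d2 / (2.0 * sigma**2))
    g[d2 > r**2] = 0.0
    total = g.sum()
    if total <= 0:
        return yy[:0], xx[:0], g[:0]
    g *= mass / total
    return yy, xx, g


def simulate_ncc_field(config: SimImageConfig) -> SimulatedField:
    """Simulate one two-channel reporter field with ground truth.

    Identical configs (including seed) produce bit-identical output.
    """
    cfg = config
    cfg.validate()
    rng = stream_rng(cfg.seed, "ncc-field")

    centers, radii_n, radii_c = _place_cells(cfg, rng)
    h, w = cfg.height, cfg.width
    yy, xx = np.mgrid[0:h, 0:w]

    mcherry = np.zeros((h, w), dtype=float)
    egfp = np.zeros((h, w), dtype=float)
    nuc_labels = np.zeros((h, w), dtype=np.int32)
    cyt_labels = np.zeros((h, w), dtype=np.int32)

    f = cfg.mislocalization_fraction
    rows = []
    for cid, ((cy, cx), rn, rc) in enumerate(zip(centers, radii_n, radii_c), start=1):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nuc = d2 <= rn**2
        cyt = (d2 <= rc**2) & ~nuc
        nuc_labels[nuc] = cid
        cyt_labels[cyt] = cid
        n_nuc = int(nuc.sum())
        n_cyt = int(cyt.sum())

        # mCherry: (1-f) of the mass uniform over the nucleus, f split
        # equally over puncta placed in the cytoplasmic annulus.
        mcherry[nuc] += _MCHERRY_MASS * (1.0 - f) / n_nuc
        n_puncta = cfg.puncta_per_cell if f > 0 else 0
        placed_puncta: list[tuple[float, float]] = []
        min_sep = 4.5 * cfg.puncta_radius  # keep spots resolvable when room allows
        for _ in range(n_puncta):
            lo = rn + cfg.puncta_radius
            hi = rc - cfg.puncta_radius
            py = px = None
            for _try in range(100):
                rad = rng.uniform(lo, hi) if lo < hi else 0.5 * (rn + rc)
                theta = rng.uniform(0, 2 * np.pi)
                qy, qx = cy + rad * np.sin(theta), cx + rad * np.cos(theta)
                if all(
                    (qy - oy) ** 2 + (qx - ox) ** 2 >= min_sep**2
                    for oy, ox in placed_puncta
                ):
                    py, px = qy, qx
                    break
            if py is None:  # crowded annulus: accept overlap
                py, px = qy, qx
            placed_puncta.append((py, px))
            sy, sx, sg = _gaussian_spot(
                _MCHERRY_MASS * f / n_puncta, py, px, cfg.puncta_radius, (h, w)
            )
            mcherry[sy, sx] += sg

        # eGFP: leak fraction uniform over the nucleus, rest over cytoplasm.
        leak = cfg.egfp_nuclear_leak
        egfp[nuc] += _EGFP_MASS * leak / n_nuc
        egfp[cyt] += _EGFP_MASS * (1.0 - leak) / n_cyt

        rows.append(
            {
                "cell_id": cid,
                "center_y": cy,
                "center_x": cx,
                "nucleus_radius": rn,
                "cytoplasm_radius": rc,
                "mislocalization_fraction": f,
                "puncta_count": n_puncta,
                "mcherry_total": _MCHERRY_MASS,
                "egfp_total": _EGFP_MASS,
            }
        )

    for chan in (mcherry, egfp):
        chan += cfg.background_level
        if cfg.noise_sd > 0:
            chan += rng.normal(0.0, cfg.noise_sd, size=chan.shape)
        np.clip(chan, 0.0, None, out=chan)

    truth = pd.DataFrame(rows)
    return SimulatedField(
        mcherry=mcherry,
        egfp=egfp,
        nucleus_labels=nuc_labels,
        cytoplasm_labels=cyt_labels,
        per_cell_truth=truth,
        config=dataclasses.replace(cfg),
    )
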