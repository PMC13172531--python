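"""Synthetic-data generators with stored ground truth.

Every input the analysis modules consume can be generated here with a
known truth attached, so each pipeline stage has a recovery oracle:

* EdU time courses: binomial sampling around the ODE-model S-phase
  fraction (the scored-cells-per-day experiment);
* sister-chromatid ratio datasets from the two-component mixture, with
  latent branch labels;
* two-nucleus 3D z-stacks: Gaussian blobs of prescribed integrated
  intensity on a constant background with Poisson and/or Gaussian read
  noise, plus ground-truth ROI masks;
* paired daughter-cell count tables: negative-binomial counts, per-cell
  capture efficiencies scaling genes and ERCC spike-ins identically, and
  a controllable fraction of truly asymmetric pairs.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .division_mixture import MixtureParams, RatioDataset, simulate_ratios
from .image_quant import ZStackROI
from .pair_expression import ERCC_PREFIX, PairTable
from .regen_ode import (
    BASAL_S_FRACTION,
    DEFAULT_PARAMS,
    EdUTimecourse,
    RegenParams,
    basal_state,
    simulate_trajectory,
)

__all__ = [
    "SyntheticTruth",
    "gen_edu_timecourse",
    "gen_ratio_dataset",
    "gen_zstack",
    "gen_pair_counts",
    "DEFAULT_MARKER_GENES",
]

#: Marker genes always present in generated count tables: the H3.3 genes
#: used for asymmetry calls plus stem-cell and proliferation markers.
DEFAULT_MARKER_GENES = ("H3f3a", "H3f3b", "Trp63", "Krt5", "Krt14", "Mki67")


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every generated dataset."""

    generator: str
    seed: int | None
    params: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(f"not serializable: {type(o)}")

        text = json.dumps(dataclasses.asdict(self), default=default, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def gen_edu_timecourse(
    params: RegenParams = DEFAULT_PARAMS,
    days: np.ndarray | None = None,
    n_per_day: int = 300,
    h2_basal: float = BASAL_S_FRACTION,
    seed: int | None = None,
) -> tuple[EdUTimecourse, SyntheticTruth]:
    """EdU scoring experiment: binomial draws around the model trajectory.

    The true fraction at each day is H2(day) from the ODE model (basal
    flux-balance initial condition, activation delay included);
    n_positive ~ Binomial(n_per_day, fraction).
    """
    if days is None:
        days = np.arange(0.0, 8.0)
    days = np.asarray(days, dtype=float)
    grid = days if days[0] == 0 else np.concatenate([[0.0], days])
    init = basal_state(h2_basal, params)
    traj = simulate_trajectory(init, params, grid)
    fracs = traj.H2[-days.size:] if days[0] != 0 else traj.H2
    rng = np.random.default_rng(seed)
    n_pos = rng.binomial(n_per_day, fracs)
    data = EdUTimecourse.from_counts(days, np.full(days.size, n_per_day), n_pos)
    truth = SyntheticTruth(
        generator="edu_timecourse",
        seed=seed,
        params={
            "regen_params": dataclasses.asdict(params),
            "h2_basal": h2_basal,
            "n_per_day": n_per_day,
            "days": days,
            "true_fractions": fracs,
        },
    )
    return data, truth


def gen_ratio_dataset(
    params: MixtureParams,
    n: int = 5000,
    seed: int | None = None,
) -> tuple[RatioDataset, SyntheticTruth]:
    """Sister-chromatid ratio dataset with latent branch labels stored."""
    data = simulate_ratios(params, n, seed)
    truth = SyntheticTruth(
        generator="ratio_dataset",
        seed=seed,
        params={
            "mixture_params": dataclasses.asdict(params),
            "n": n,
            "asymmetric_labels": data.asymmetric,
            "n_redraws": data.n_redraws,
        },
    )
    return data, truth


def _gaussian_blob(shape, center, sigma, total):
    """Separable 3D Gaussian with the given integrated intensity on the
    full grid (before any mask truncation)."""
    axes = []
    for dim, c, s in zip(shape, center, sigma):
        x = np.arange(dim, dtype=float)
        g = np.exp(-0.5 * ((x - c) / s) ** 2)
        axes.append(g / g.sum())
    blob = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return total * blob


def _box_mask(shape, center, sigma, n_sigma):
    # per-axis +-n_sigma box: at 3 SD it holds 0.9973^3 ~ 99.2% of the
    # blob mass (a 3-SD ellipsoid would hold only ~97.1%, chi^2_3)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        (np.abs(zz - center[0]) <= n_sigma * sigma[0])
        & (np.abs(yy - center[1]) <= n_sigma * sigma[1])
        & (np.abs(xx - center[2]) <= n_sigma * sigma[2])
    )


def gen_zstack(
    shape: tuple[int, int, int] = (12, 64, 64),
    centers_a: tuple[float, float, float] = (5.5, 24.0, 20.0),
    centers_b: tuple[float, float, float] = (5.5, 40.0, 44.0),
    total_a: float = 2.0e6,
    total_b: float = 1.25e6,
    psf_sigma: float | tuple[float, float, float] = (1.6, 2.2, 2.2),
    background_level: float = 100.0,
    noise_model: str = "poisson",
    read_noise_sd: float = 3.0,
    seed: int | None = None,
    mask_n_sigma: float = 3.0,
) -> tuple[ZStackROI, SyntheticTruth]:
    """Two-nucleus telophase z-stack with known integrated intensities.

    Each nucleus is an (optionally anisotropic) Gaussian blob whose full
    integrated intensity is ``total_a`` / ``total_b``, on a constant
    background.  Noise is Poisson shot noise, Gaussian read noise, both,
    or none.  Ground-truth signal masks are the blob supports at
    ``mask_n_sigma`` standard deviations; the background mask is the
    region beyond ``mask_n_sigma + 1`` SD of both blobs.  Pixel values
    are clipped to the 16-bit range; more than 0.1% saturated signal
    pixels invalidates the fixture (error).
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("blob totals must be positive")
    if np.isscalar(psf_sigma):
        psf_sigma = (float(psf_sigma),) * 3
    for c in (centers_a, centers_b):
        if not all(0 <= ci < di for ci, di in zip(c, shape)):
            raise ValueError(f"center {c} outside volume of shape {shape}")
    ideal = (
        _gaussian_blob(shape, centers_a, psf_sigma, total_a)
        + _gaussian_blob(shape, centers_b, psf_sigma, total_b)
        + background_level
    )
    rng = np.random.default_rng(seed)
    if noise_model == "poisson":
        img = rng.poisson(ideal).astype(float)
    elif noise_model == "gaussian":
        img = ideal + rng.normal(0.0, read_noise_sd, size=shape)
    elif noise_model == "poisson+gaussian":
        img = rng.poisson(ideal).astype(float) + rng.normal(
            0.0, read_noise_sd, size=shape)
    elif noise_model == "none":
        img = ideal.copy()
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")

    mask_a = _box_mask(shape, centers_a, psf_sigma, mask_n_sigma)
    mask_b = _box_mask(shape, centers_b, psf_sigma, mask_n_sigma)
    if (mask_a & mask_b).any():
        raise ValueError("blob masks overlap; move centers apart")
    far = ~(
        _box_mask(shape, centers_a, psf_sigma, mask_n_sigma + 1.0)
        | _box_mask(shape, centers_b, psf_sigma, mask_n_sigma + 1.0)
    )

    clipped = np.clip(img, 0, 65535)
    saturated = int((img > 65535)[mask_a | mask_b].sum())
    n_signal = int((mask_a | mask_b).sum())
    if saturated > 0.001 * n_signal:
        raise ValueError(
            f"{saturated}/{n_signal} signal pixels saturated; fixture invalid")
    img = np.round(clipped).astype(np.uint16)

    stack = ZStackROI(image=img, mask_a=mask_a, mask_b=mask_b,
                      background_mask=far)
    # mass actually inside each 3-sigma mask (truncation bookkeeping)
    frac_a = float(_gaussian_blob(shape, centers_a, psf_sigma, 1.0)[mask_a].sum())
    frac_b = float(_gaussian_blob(shape, centers_b, psf_sigma, 1.0)[mask_b].sum())
    truth = SyntheticTruth(
        generator="zstack",
        seed=seed,
        params={
            "shape": list(shape),
            "centers_a": list(centers_a),
            "centers_b": list(centers_b),
            "total_a": total_a,
            "total_b": total_b,
            "ratio": max(total_a, total_b) / min(total_a, total_b),
            "psf_sigma": list(psf_sigma),
            "background_level": background_level,
            "noise_model": noise_model,
            "read_noise_sd": read_noise_sd,
            "mask_n_sigma": mask_n_sigma,
            "mask_mass_fraction_a": frac_a,
            "mask_mass_fraction_b": frac_b,
        },
    )
    return stack, truth


def gen_pair_counts(
    n_pairs: int = 48,
    asym_fraction: float = 15 / 48,
    genes: tuple[str, ...] = DEFAULT_MARKER_GENES,
    n_background_genes: int = 200,
    n_ercc: int = 92,
    capture_efficiency_cv: float = 0.2,
    marker_mean: float = 2000.0,
    ercc_total_mean: float = 5.0e4,
    dispersion: float = 500.0,
    asym_genes: tuple[str, ...] = ("H3f3a", "H3f3b"),
    asym_split_range: tuple[float, float] = (2.0, 3.0),
    sym_split_range: tuple[float, float] = (1.0, 1.2),
    seed: int | None = None,
) -> tuple[PairTable, SyntheticTruth]:
    """Paired daughter-cell count table with a known asymmetric fraction.

    ``round(asym_fraction * n_pairs)`` randomly chosen pairs receive a
    true expression split of at least 2-fold (drawn from
    ``asym_split_range``) in the designated genes, applied in the same
    direction for all designated genes of a pair (the asymmetry is a
    property of the daughter cell); the remaining pairs get true ratios
    within ``sym_split_range``.  Counts are negative-binomial around the
    per-cell mean; per-cell capture efficiencies (lognormal with the
    given CV) scale endogenous genes and ERCC spike-ins identically, so
    ERCC size factors recover them.  QC metadata emulate deeply sequenced
    plate-based libraries (~13,000 genes detected, ~2% mitochondrial
    reads), so all generated cells pass the default filters.
    """
    if not 0 <= asym_fraction <= 1:
        raise ValueError("asym_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_cells = 2 * n_pairs
    pair_ids = [f"pair{p:03d}" for p in range(n_pairs)]
    cell_ids = [f"{pid}_{d}" for pid in pair_ids for d in ("a", "b")]

    n_asym = int(round(asym_fraction * n_pairs))
    asym_pairs = np.zeros(n_pairs, dtype=bool)
    asym_pairs[rng.choice(n_pairs, size=n_asym, replace=False)] = True

    # per-cell capture efficiency, mean 1
    if capture_efficiency_cv > 0:
        s2 = np.log1p(capture_efficiency_cv**2)
        capture = rng.lognormal(-s2 / 2, np.sqrt(s2), size=n_cells)
    else:
        capture = np.ones(n_cells)

    gene_names = list(genes) + [f"Gene{i:04d}" for i in range(n_background_genes)]
    base_mean = np.empty(len(gene_names))
    base_mean[: len(genes)] = marker_mean
    base_mean[len(genes):] = rng.lognormal(np.log(50.0), 0.8,
                                           size=n_background_genes)

    # per-pair split multipliers for the designated genes: the favored
    # daughter gets 2f/(f+1), the other 2/(f+1) (pair mean preserved)
    true_ratio = np.where(
        asym_pairs,
        rng.uniform(*asym_split_range, size=n_pairs),
        rng.uniform(*sym_split_range, size=n_pairs),
    )
    favored_first = rng.random(n_pairs) < 0.5

    mean_matrix = np.tile(base_mean[:, None], (1, n_cells)).astype(float)
    asym_idx = [gene_names.index(g) for g in asym_genes]
    for p in range(n_pairs):
        f = true_ratio[p]
        hi_mult, lo_mult = 2 * f / (f + 1), 2 / (f + 1)
        ca, cb = 2 * p, 2 * p + 1
        hi, lo = (ca, cb) if favored_first[p] else (cb, ca)
        for gi in asym_idx:
            mean_matrix[gi, hi] *= hi_mult
            mean_matrix[gi, lo] *= lo_mult
    mean_matrix *= capture[None, :]

    def nb_draw(mu, theta):
        # negative binomial with mean mu and variance mu + mu^2/theta
        p = theta / (theta + mu)
        return rng.negative_binomial(theta, p)

    gene_counts = nb_draw(mean_matrix, dispersion)

    ercc_names = [f"{ERCC_PREFIX}{i:05d}" for i in range(n_ercc)]
    ercc_mean = rng.lognormal(0.0, 1.0, size=n_ercc)
    ercc_mean *= ercc_total_mean / ercc_mean.sum()
    ercc_matrix = ercc_mean[:, None] * capture[None, :]
    ercc_counts = nb_draw(ercc_matrix, 1000.0)

    counts = pd.DataFrame(
        np.vstack([gene_counts, ercc_counts]),
        index=gene_names + ercc_names,
        columns=cell_ids,
    )
    meta = pd.DataFrame(
        {
            "pair_id": np.repeat(pair_ids, 2),
            "genes_detected": rng.normal(13_000, 300, size=n_cells).round().astype(int),
            "mito_fraction": np.clip(rng.normal(0.02, 0.004, size=n_cells), 0, 1),
        },
        index=cell_ids,
    )
    table = PairTable(counts=counts, cell_meta=meta)
    truth = SyntheticTruth(
        generator="pair_counts",
        seed=seed,
        params={
            "n_pairs": n_pairs,
            "asym_fraction": asym_fraction,
            "n_asym_true": n_asym,
            "asym_pair_ids": [pid for pid, a in zip(pair_ids, asym_pairs) if a],
            "true_ratio": dict(zip(pair_ids, true_ratio)),
            "capture_efficiency": dict(zip(cell_ids, capture)),
            "asym_genes": list(asym_genes),
            "dispersion": dispersion,
        },
    )
    return table, truth
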