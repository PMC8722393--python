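"""Synthetic blastoderm embryos with known ground truth.

Every downstream stage of the pipeline (spot detection, geometry,
quantification, model fitting) is exercised on images produced here, so
the generator plants spots whose positions, intensities, column indices
and activation times are all recorded.

The generator emulates the ventral (mesodermal) region of an early
nuclear-cycle-14 embryo:

* a ventral-peaked nuclear Dorsal gradient ``D(x)`` over ~20 nuclear
  columns, normalized to 1 at the ventral midline (column 0);
* stochastic, allele-independent promoter activation with per-minute
  probability ``p(x) = p_mid * D(x)`` (exponential waiting times, so the
  activated fraction after time T is ``1 - exp(-T*p)``);
* a DAPI channel with one blob per nucleus on a hexagonal-offset column
  grid, and an smFISH channel with one bright transcription-site (TS)
  spot per active allele plus dim unit-intensity cytoplasmic mRNA spots;
* Gaussian PSF blur followed by Poisson shot noise and additive Gaussian
  read noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "DorsalProfile",
    "ActivationConfig",
    "RenderConfig",
    "SyntheticGroundTruth",
    "make_dorsal_profile",
    "simulate_activation",
    "render_embryo",
    "write_fixture",
    "read_fixture",
]


@dataclass(frozen=True)
class DorsalProfile:
    """Per-nuclear-column normalized nuclear Dorsal levels D(x).

    ``columns`` are signed integer indices (0 = ventral midline) and
    ``levels`` the dimensionless nuclear Dorsal level of each column,
    rescaled so that the midline level is 1.
    """

    columns: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        columns = np.asarray(self.columns, dtype=int)
        levels = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "columns", columns)
        object.__setattr__(self, "levels", levels)
        if columns.shape != levels.shape or columns.ndim != 1:
            raise ValueError("columns and levels must be 1D arrays of equal length")
        if 0 not in columns:
            raise ValueError("profile must contain the midline column 0")
        if not np.isclose(levels[columns == 0][0], 1.0):
            raise ValueError("midline level must equal 1.0")
        if np.any(levels < 0):
            raise ValueError("Dorsal levels must be non-negative")
        # monotone gradient: non-increasing with |column|
        order = np.argsort(np.abs(columns), kind="stable")
        dist, lev = np.abs(columns)[order], levels[order]
        for d in np.unique(dist)[:-1]:
            if lev[dist > d].max(initial=0.0) > lev[dist == d].min() + 1e-12:
                raise ValueError("levels must be non-increasing with |column|")

    def level(self, column: int) -> float:
        """Exact level at an integer column index."""
        idx = np.nonzero(self.columns == column)[0]
        if idx.size == 0:
            raise KeyError(f"column {column} outside profile support")
        return float(self.levels[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"column": self.columns, "dorsal": self.levels})


def make_dorsal_profile(sigma: float = 4.0, half_width: int = 9) -> DorsalProfile:
    """Gaussian stand-in Dorsal gradient ``D(x) = exp(-x^2 / (2 sigma^2))``.

    Parameters
    ----------
    sigma
        Gradient width in nuclear columns. Default 4 columns over a
        ~20-column mesoderm.
    half_width
        Columns extend from ``-half_width`` to ``+half_width``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if half_width < 1:
        raise ValueError(f"half_width must be >= 1, got {half_width}")
    columns = np.arange(-half_width, half_width + 1)
    levels = np.exp(-(columns.astype(float) ** 2) / (2.0 * sigma**2))
    return DorsalProfile(columns=columns, levels=levels)


@dataclass(frozen=True)
class ActivationConfig:
    """Conditions of the stochastic promoter-activation simulation.

    ``p_mid`` is the per-minute activation probability at the ventral
    midline; ``T`` the exposure time (minutes) to the stable Dorsal
    gradient within nuclear cycle 14.
    """

    p_mid: float
    T: float = 15.0
    n_nuclei_per_column: int = 8
    alleles_per_nucleus: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_mid < 0:
            raise ValueError("p_mid must be >= 0")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.alleles_per_nucleus not in (1, 2):
            raise ValueError("alleles_per_nucleus must be 1 or 2")
        if self.n_nuclei_per_column < 1:
            raise ValueError("n_nuclei_per_column must be >= 1")


def simulate_activation(
    profile: DorsalProfile,
    cfg: ActivationConfig,
    proportional: bool = True,
) -> pd.DataFrame:
    """Sample per-allele activation times under the memoryless model.

    Each allele at column x activates as the first event of a Poisson
    process with rate ``p(x) = p_mid * D(x)`` (or uniformly ``p_mid``
    when ``proportional`` is off, modeling a switch-like gene such as
    *twi*). Times beyond ``T`` are recorded as inactive.

    Returns
    -------
    pandas.DataFrame
        One record per allele with columns ``column``, ``nucleus``,
        ``allele``, ``active`` (bool) and ``t_activate`` (minutes; NaN
        for inactive alleles).
    """
    rng = np.random.default_rng(cfg.seed)
    cols = np.repeat(
        profile.columns, cfg.n_nuclei_per_column * cfg.alleles_per_nucleus
    )
    nuc = np.tile(
        np.repeat(np.arange(cfg.n_nuclei_per_column), cfg.alleles_per_nucleus),
        profile.columns.size,
    )
    allele = np.tile(
        np.arange(cfg.alleles_per_nucleus),
        profile.columns.size * cfg.n_nuclei_per_column,
    )
    levels = np.repeat(
        profile.levels, cfg.n_nuclei_per_column * cfg.alleles_per_nucleus
    )
    rate = cfg.p_mid * levels if proportional else np.full_like(levels, cfg.p_mid)
    with np.errstate(divide="ignore"):
        # exponential waiting time; rate 0 -> infinite waiting time
        t = rng.exponential(1.0, size=rate.size) / np.where(rate > 0, rate, np.nan)
    t = np.where(rate > 0, t, np.inf)
    active = t <= cfg.T
    return pd.DataFrame(
        {
            "column": cols,
            "nucleus": nuc,
            "allele": allele,
            "active": active,
            "t_activate": np.where(active, t, np.nan),
        }
    )


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters for the synthetic image stacks.

    Intensities are in arbitrary fluorescence units; a single cytoplasmic
    mRNA carries integrated intensity ``unit_intensity`` and a TS carries
    ``ratio * unit_intensity`` (``ratio`` plays the role of the planted
    TS-to-mRNA intensity ratio R).
    """

    shape: tuple[int, int, int] = (12, 294, 140)
    voxel_size: tuple[float, float, float] = (0.5, 0.1, 0.1)  # um, informational
    psf_sigma: tuple[float, float, float] = (1.0, 1.3, 1.3)  # voxels
    unit_intensity: float = 500.0
    ratio: float = 70.0
    mrna_per_column: int | dict[int, int] = 20
    shot_noise_scale: float = 1.0  # photons per intensity unit; 0 disables
    read_noise_sigma: float = 2.0  # additive Gaussian; 0 disables
    channels: tuple[str, ...] = ("dapi", "fish")
    column_spacing: float = 14.0  # px between nuclear columns along DV (y) axis
    nucleus_radius: float = 5.0  # px, projected footprint
    sister_separation: float = 5.0  # px, min distance between same-nucleus TSs
    dapi_intensity: float = 5000.0
    dapi_sigma: tuple[float, float, float] = (2.0, 3.0, 3.0)
    baseline: float = 10.0  # uniform background (autofluorescence/offset)
    min_separation: float = 5.0  # px; closer planted spots are flagged crowded
    enforce_separation: bool = False  # reject placements violating min_separation
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.psf_sigma + self.dapi_sigma):
            raise ValueError("PSF sigmas must be positive")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.unit_intensity < 0 or self.dapi_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if self.column_spacing <= 0 or self.nucleus_radius <= 0:
            raise ValueError("geometry lengths must be positive")


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows about a rendered embryo.

    ``spots`` lists every planted fluorescent object (class ``TS`` or
    ``mRNA``) with voxel position, integrated intensity, column and
    nucleus id; ``nuclei`` the nucleus grid; ``midline_y`` / ``spacing``
    the true geometry. ``activation`` is the allele table the TS spots
    were derived from.
    """

    spots: pd.DataFrame
    nuclei: pd.DataFrame
    profile: DorsalProfile
    activation: pd.DataFrame
    render: RenderConfig
    midline_y: float
    spacing: float


def _nucleus_grid(profile: DorsalProfile, n_per_column: int, cfg: RenderConfig):
    """Hexagonal-offset nucleus centers; returns DataFrame and midline y."""
    nz, ny, nx = cfg.shape
    midline_y = ny / 2.0
    s = cfg.column_spacing
    x0 = (nx - (n_per_column - 1) * s) / 2.0
    rows = []
    nucleus_id = 0
    for c in profile.columns:
        y = midline_y + c * s
        if y < cfg.nucleus_radius or y > ny - cfg.nucleus_radius:
            raise ValueError(
                "image too small along y for the configured column grid"
            )
        offset = (s / 2.0) if (c % 2) else 0.0
        for i in range(n_per_column):
            x = x0 + i * s + offset
            if x < cfg.nucleus_radius or x > nx - cfg.nucleus_radius:
                raise ValueError(
                    "image too small along x for the configured nucleus grid"
                )
            rows.append(
                {
                    "nucleus_id": nucleus_id,
                    "column": int(c),
                    "index_in_column": i,
                    "z": (nz - 1) / 2.0,
                    "y": y,
                    "x": x,
                }
            )
            nucleus_id += 1
    return pd.DataFrame(rows), midline_y


def _place_deltas(shape, spots: pd.DataFrame) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    z = np.clip(np.rint(spots["z"]).astype(int), 0, shape[0] - 1)
    y = np.clip(np.rint(spots["y"]).astype(int), 0, shape[1] - 1)
    x = np.clip(np.rint(spots["x"]).astype(int), 0, shape[2] - 1)
    np.add.at(img, (z, y, x), spots["intensity"].to_numpy(dtype=float))
    return img


def render_embryo(
    activation: pd.DataFrame,
    profile: DorsalProfile,
    cfg: RenderConfig,
) -> tuple[dict[str, np.ndarray], SyntheticGroundTruth]:
    """Render multi-channel 3D stacks from an allele-activation table.

    The DAPI channel contains one blob per nucleus; the smFISH channel one
    bright TS spot per active allele (integrated intensity
    ``ratio * unit_intensity``, placed uniformly inside the nucleus
    footprint) plus dim cytoplasmic single-mRNA spots of unit intensity.
    The PSF is applied before noise; with both noise terms disabled the
    rendering is exactly flux-conserving up to PSF truncation at the
    image border.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_place, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    n_per_column = int(activation["nucleus"].max()) + 1
    nuclei, midline_y = _nucleus_grid(profile, n_per_column, cfg)
    nuc_lookup = nuclei.set_index(["column", "index_in_column"])

    nz, ny, nx = cfg.shape
    records = []
    spot_id = 0
    # TS spots: one per active allele, uniform in the nucleus footprint;
    # sister sites of one nucleus are kept >= sister_separation apart,
    # as the two alleles occupy distinct territories in a real nucleus
    def _ts_position(center):
        r = cfg.nucleus_radius * np.sqrt(rng_place.uniform(0, 0.9))
        theta = rng_place.uniform(0, 2 * np.pi)
        return (
            float(center["z"]) + rng_place.uniform(-1, 1),
            float(center["y"]) + r * np.sin(theta),
            float(center["x"]) + r * np.cos(theta),
        )

    active = activation[activation["active"]]
    for (col, nuc_idx), grp in active.groupby(["column", "nucleus"], sort=True):
        center = nuc_lookup.loc[(col, nuc_idx)]
        placed_ts: list[tuple[float, float, float]] = []
        for _rec in grp.itertuples():
            pos = _ts_position(center)
            for _ in range(50):
                if not placed_ts or all(
                    np.hypot(pos[1] - q[1], pos[2] - q[2]) >= cfg.sister_separation
                    for q in placed_ts
                ):
                    break
                pos = _ts_position(center)
            placed_ts.append(pos)
            records.append(
                {
                    "spot_id": spot_id,
                    "channel": "fish",
                    "class": "TS",
                    "z": pos[0],
                    "y": pos[1],
                    "x": pos[2],
                    "intensity": cfg.ratio * cfg.unit_intensity,
                    "column": int(col),
                    "nucleus_id": int(center["nucleus_id"]),
                }
            )
            spot_id += 1

    # cytoplasmic single mRNAs: uniform in the column band, outside nuclei
    nuc_yx = nuclei[["y", "x"]].to_numpy()
    s = cfg.column_spacing
    for c in profile.columns:
        n_mrna = (
            cfg.mrna_per_column[int(c)]
            if isinstance(cfg.mrna_per_column, dict)
            else cfg.mrna_per_column
        )
        y_lo = midline_y + c * s - s / 2.0
        placed = 0
        attempts = 0
        while placed < n_mrna and attempts < 200 * max(n_mrna, 1):
            attempts += 1
            y = rng_place.uniform(max(y_lo, 1.0), min(y_lo + s, ny - 1.0))
            x = rng_place.uniform(1.0, nx - 1.0)
            if np.min(np.hypot(nuc_yx[:, 0] - y, nuc_yx[:, 1] - x)) <= cfg.nucleus_radius:
                continue
            if cfg.enforce_separation and records:
                prev = np.array([(r["y"], r["x"]) for r in records])
                if np.min(np.hypot(prev[:, 0] - y, prev[:, 1] - x)) < cfg.min_separation:
                    continue
            records.append(
                {
                    "spot_id": spot_id,
                    "channel": "fish",
                    "class": "mRNA",
                    "z": rng_place.uniform(1.0, nz - 1.0),
                    "y": y,
                    "x": x,
                    "intensity": cfg.unit_intensity,
                    "column": int(c),
                    "nucleus_id": -1,
                }
            )
            spot_id += 1
            placed += 1

    spots = pd.DataFrame(records)
    if len(spots):
        pos = spots[["z", "y", "x"]].to_numpy()
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pos).query(pos, k=2)
        spots["crowded"] = d[:, 1] < cfg.min_separation
        if spots["crowded"].any():
            logger.warning(
                "%d planted spots closer than %.1f px flagged as crowded",
                int(spots["crowded"].sum()),
                cfg.min_separation,
            )
    else:
        spots["crowded"] = pd.Series(dtype=bool)

    stacks: dict[str, np.ndarray] = {}
    if "dapi" in cfg.channels:
        dapi = _place_deltas(
            cfg.shape,
            nuclei.assign(intensity=cfg.dapi_intensity)[["z", "y", "x", "intensity"]],
        )
        stacks["dapi"] = ndimage.gaussian_filter(dapi, cfg.dapi_sigma, mode="constant")
    if "fish" in cfg.channels:
        fish = _place_deltas(cfg.shape, spots[["z", "y", "x", "intensity"]])
        stacks["fish"] = ndimage.gaussian_filter(fish, cfg.psf_sigma, mode="constant")

    for name, img in stacks.items():
        noisy = img + cfg.baseline
        if cfg.shot_noise_scale > 0:
            noisy = (
                rng_noise.poisson(np.clip(noisy, 0, None) * cfg.shot_noise_scale)
                / cfg.shot_noise_scale
            )
        if cfg.read_noise_sigma > 0:
            noisy = noisy + rng_noise.normal(0, cfg.read_noise_sigma, size=img.shape)
        stacks[name] = np.clip(noisy, 0, None)

    truth = SyntheticGroundTruth(
        spots=spots,
        nuclei=nuclei,
        profile=profile,
        activation=activation,
        render=cfg,
        midline_y=midline_y,
        spacing=cfg.column_spacing,
    )
    return stacks, truth


def write_fixture(
    stacks: dict[str, np.ndarray],
    truth: SyntheticGroundTruth,
    out_dir: str | Path,
    activation_cfg: ActivationConfig | None = None,
) -> dict[str, Path]:
    """Write TIFF per channel, ground-truth CSVs and a YAML config snapshot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, stack in stacks.items():
        p = out / f"{name}.tif"
        tifffile.imwrite(p, stack.astype(np.float32))
        paths[name] = p
    paths["truth"] = out / "truth_spots.csv"
    truth.spots.to_csv(paths["truth"], index=False)
    paths["nuclei"] = out / "truth_nuclei.csv"
    truth.nuclei.to_csv(paths["nuclei"], index=False)
    paths["activation"] = out / "truth_activation.csv"
    truth.activation.to_csv(paths["activation"], index=False)
    paths["profile"] = out / "dorsal_profile.csv"
    truth.profile.to_frame().to_csv(paths["profile"], index=False)
    snapshot = {
        "render": _jsonable(asdict(truth.render)),
        "midline_y": float(truth.midline_y),
        "spacing": float(truth.spacing),
    }
    if activation_cfg is not None:
        snapshot["activation"] = _jsonable(asdict(activation_cfg))
    paths["config"] = out / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(snapshot, fh, sort_keys=True)
    return paths


def read_fixture(out_dir: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Read back stacks and the config snapshot written by :func:`write_fixture`."""
    out = Path(out_dir)
    stacks = {
        p.stem: tifffile.imread(p).astype(float) for p in sorted(out.glob("*.tif"))
    }
    with open(out / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    return stacks, cfg


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, tuple):
            v = list(v)
        if isinstance(v, np.generic):
            v = v.item()
        out[k] = v
    return out
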