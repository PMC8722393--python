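"""Spot classification, Pol II loading and per-column summaries.

The central quantity is the TS-to-single-mRNA intensity ratio R: because
a cytoplasmic smFISH spot is one mature transcript, the ratio of the
median cumulative TS intensity to the median cumulative single-mRNA
intensity estimates the number of nascent-transcript equivalents — i.e.
the Pol II loading N — at an active locus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import argrelextrema
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from embryofish.geometry import EmbryoGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationResult",
    "classify_spots",
    "polII_density",
    "summarize_columns",
    "mrna_profile",
    "match_dual_probes",
]


@dataclass
class ClassificationResult:
    """Outcome of the mRNA / TS split on the max-intensity histogram."""

    cutoff: float  # max-intensity cutoff separating the two populations
    spots: pd.DataFrame  # input table with a "class" column added
    median_mrna: float  # median cumulative intensity of single mRNAs
    median_ts: float  # median cumulative intensity of TSs
    ratio: float  # R = median_ts / median_mrna
    n_polII: float  # estimated Pol II loading N (= R)


class NoSeparationError(ValueError):
    """The max-intensity histogram shows no mRNA/TS bimodality."""

    def __init__(self, message: str, grid: np.ndarray, density: np.ndarray):
        super().__init__(message)
        self.grid = grid
        self.density = density


def classify_spots(spots: pd.DataFrame, bw_method=None) -> ClassificationResult:
    """Split detected spots into single mRNAs and transcription sites.

    Single cytoplasmic mRNAs are numerous but dim; TSs contain many
    nascent transcripts concentrated at one locus and therefore reach far
    higher maximal pixel intensities. The cutoff is placed at the minimum
    of the smoothed log10 max-intensity density between its two largest
    modes (kernel density, Scott's plug-in bandwidth by default) — the
    log-domain choice makes the cutoff invariant to global intensity
    rescaling.
    """
    if len(spots) < 20:
        raise ValueError(f"need >= 20 spots to classify, got {len(spots)}")
    logm = np.log10(spots["max_int"].to_numpy(dtype=float))
    if np.any(~np.isfinite(logm)):
        raise ValueError("max intensities must be positive and finite")

    kde = gaussian_kde(logm, bw_method=bw_method)
    pad = 0.5
    grid = np.linspace(logm.min() - pad, logm.max() + pad, 1024)
    density = kde(grid)
    maxima = argrelextrema(density, np.greater)[0]
    if maxima.size < 2:
        raise NoSeparationError(
            "no TS/mRNA separation: max-intensity histogram is unimodal",
            grid,
            density,
        )
    top2 = maxima[np.argsort(density[maxima])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(density[lo : hi + 1]))
    cutoff = float(10 ** grid[valley])

    out = spots.copy()
    out["class"] = np.where(out["max_int"] > cutoff, "TS", "mRNA")
    med_mrna = float(out.loc[out["class"] == "mRNA", "cum_int"].median())
    med_ts = float(out.loc[out["class"] == "TS", "cum_int"].median())
    ratio = med_ts / med_mrna
    return ClassificationResult(
        cutoff=cutoff,
        spots=out,
        median_mrna=med_mrna,
        median_ts=med_ts,
        ratio=ratio,
        n_polII=ratio,
    )


def polII_density(
    n_polII: float,
    gene,
    reference: tuple[float, "object"] | None = None,
) -> dict[str, float]:
    """Average genomic spacing of engaged Pol II complexes.

    Returns ``bp_per_polII = 1000 * length_kb / N``; when a reference
    ``(N_ref, gene_ref)`` is given, also the density of this gene
    relative to the reference (>1 means denser loading).
    """
    if n_polII <= 0:
        raise ValueError("Pol II count must be positive")
    out = {"bp_per_polII": 1000.0 * gene.length_kb / n_polII}
    if reference is not None:
        n_ref, gene_ref = reference
        ref_bp = 1000.0 * gene_ref.length_kb / n_ref
        out["density_vs_reference"] = ref_bp / out["bp_per_polII"]
    return out


def summarize_columns(
    ts_spots: pd.DataFrame,
    nuclei: pd.DataFrame,
    nucleus_counts: pd.Series,
    alleles_per_nucleus: int = 2,
) -> pd.DataFrame:
    """Per-nuclear-column summary of TS activity.

    ``ts_spots`` must carry ``col`` (integer column) and ``cum_int``;
    ``nuclei`` must carry ``nucleus_id`` and ``column``;
    ``nucleus_counts`` is the per-nucleus TS count from nucleus
    assignment. Returns one row per column with the TS count, the active
    allele fraction ``F_hat = n_TS / (alleles_per_nucleus * n_nuclei)``,
    the 0/1/2-TS nucleus histogram and the median TS cumulative
    intensity (NaN where a column has no TSs).
    """
    spots = ts_spots[~ts_spots.get("excluded", pd.Series(False, index=ts_spots.index))]
    counts_by_nuc = nucleus_counts.reindex(nuclei["nucleus_id"], fill_value=0)
    nuc = nuclei.assign(n_ts=counts_by_nuc.to_numpy())
    rows = []
    for col, grp in nuc.groupby("column"):
        n_nuclei = len(grp)
        col_spots = spots[spots["col"] == col]
        n_ts = len(col_spots)
        hist = {
            f"n_nuc_{k}ts": int((grp["n_ts"].clip(upper=2) == k).sum())
            for k in (0, 1, 2)
        }
        rows.append(
            {
                "column": int(col),
                "n_nuclei": n_nuclei,
                "n_TS": n_ts,
                "F_hat": min(n_ts / (alleles_per_nucleus * n_nuclei), 1.0),
                **hist,
                "median_ts_int": float(col_spots["cum_int"].median())
                if n_ts
                else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("column").reset_index(drop=True)


def mrna_profile(
    image: np.ndarray,
    geom: EmbryoGeometry,
    ts_spots: pd.DataFrame | None = None,
    ts_mask_radius: float = 4.0,
) -> pd.DataFrame:
    """Cytoplasmic mRNA level versus distance from the ventral midline.

    For every integer column distance, the median intensity of all ROI
    pixels at that distance is reported, after masking out disks of
    ``ts_mask_radius`` around the transcription sites so that the bright
    nascent foci do not inflate the cytoplasmic signal.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    mask = np.ones(img.shape, dtype=bool)
    if ts_spots is not None and len(ts_spots):
        yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
        for rec in ts_spots.itertuples():
            mask &= (yy - rec.y) ** 2 + (xx - rec.x) ** 2 > ts_mask_radius**2
    if geom.roi is not None:
        lo_dv, hi_dv, lo_ap, hi_ap = geom.roi
        dv_coord, ap_coord = np.mgrid[: img.shape[0], : img.shape[1]]
        if geom.axis == 1:
            dv_coord, ap_coord = ap_coord, dv_coord
        mask &= (
            (dv_coord >= lo_dv)
            & (dv_coord <= hi_dv)
            & (ap_coord >= lo_ap)
            & (ap_coord <= hi_ap)
        )

    dv = np.arange(img.shape[geom.axis], dtype=float)
    col_of_line = np.rint((dv - geom.midline_px) / geom.spacing_px).astype(int)
    col_of_pixel = (
        col_of_line[:, None] if geom.axis == 0 else col_of_line[None, :]
    ) * np.ones(img.shape, dtype=int)
    rows = []
    for col in np.unique(col_of_line):
        vals = img[(col_of_pixel == col) & mask]
        rows.append(
            {
                "distance": int(col),
                "median_intensity": float(np.median(vals)) if vals.size else np.nan,
                "n_pixels": int(vals.size),
            }
        )
    return pd.DataFrame(rows).sort_values("distance").reset_index(drop=True)


def match_dual_probes(
    spots_a: pd.DataFrame,
    spots_b: pd.DataFrame,
    radius: float = 3.0,
) -> pd.DataFrame:
    """Mutual-nearest-neighbor pairing of two probe channels.

    A locus seen by both probes (e.g. 5' and 3') is transcribing past
    both probe regions; a 5'-only locus has initiated but not completed
    elongation. Returns one row per spot from both tables with columns
    ``channel`` ('a'/'b'), ``spot_id``, ``y``, ``x``, ``state``
    ('both', 'a-only', 'b-only') and, when available, ``col``.
    """
    a = spots_a.reset_index(drop=True)
    b = spots_b.reset_index(drop=True)
    pa = a[["y", "x"]].to_numpy(dtype=float)
    pb = b[["y", "x"]].to_numpy(dtype=float)
    match_a = np.full(len(a), -1)
    if len(a) and len(b):
        ta, tb = cKDTree(pa), cKDTree(pb)
        d_ab, j_ab = tb.query(pa, k=1)
        d_ba, j_ba = ta.query(pb, k=1)
        for i in range(len(a)):
            j = int(j_ab[i])
            if d_ab[i] <= radius and int(j_ba[j]) == i:
                match_a[i] = j

    def _frame(df, channel, states):
        out = df.copy()
        out["channel_pair"] = channel
        out["state"] = states
        return out

    states_a = np.where(match_a >= 0, "both", "a-only")
    matched_b = np.isin(np.arange(len(b)), match_a[match_a >= 0])
    states_b = np.where(matched_b, "both", "b-only")
    return pd.concat(
        [_frame(a, "a", states_a), _frame(b, "b", states_b)], ignore_index=True
    )


def probe_state_fractions(matched: pd.DataFrame) -> pd.DataFrame:
    """Per-column counts and fractions of dual-probe states.

    Expects the output of :func:`match_dual_probes` with a ``col``
    column. 'both' loci are counted once (from channel a).
    """
    if "col" not in matched.columns:
        raise ValueError("spots must carry a 'col' column (run assign_columns)")
    a = matched[matched["channel_pair"] == "a"]
    b = matched[matched["channel_pair"] == "b"]
    rows = []
    for col in sorted(matched["col"].unique()):
        n_both = int((a.loc[a["col"] == col, "state"] == "both").sum())
        n_a_only = int((a.loc[a["col"] == col, "state"] == "a-only").sum())
        n_b_only = int((b.loc[b["col"] == col, "state"] == "b-only").sum())
        total = n_both + n_a_only + n_b_only
        rows.append(
            {
                "col": int(col),
                "n_both": n_both,
                "n_a_only": n_a_only,
                "n_b_only": n_b_only,
                "frac_both": n_both / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)
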