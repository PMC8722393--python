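"""Stochastic promoter-activation model F = 1 - exp(-T*p).

Each gene locus (allele) switches on permanently as the first event of a
memoryless process with per-minute probability p, so after an exposure
time T to the stable Dorsal gradient the expected activated fraction at
a column is ``F = 1 - exp(-T*p)``. Observed per-column fractions are
inverted to per-minute probabilities ``p_hat = -ln(1 - F_hat) / T`` and
both are correlated (Pearson) against the nuclear Dorsal profile: a
Dorsal-proportional p yields near-perfect linear correlation, while a
switch-like uniform p yields none.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from embryofish.synthetic import DorsalProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ActivationFit",
    "activated_fraction",
    "infer_probability",
    "correlate_with_dorsal",
    "fit_activation",
]


def activated_fraction(p, T):
    """Expected activated fraction after T minutes at rate p per minute."""
    p = np.asarray(p, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(p < 0) or np.any(T < 0):
        raise ValueError("p and T must be non-negative")
    out = -np.expm1(-T * p)
    return float(out) if out.ndim == 0 else out


def infer_probability(F_hat, T: float, n_alleles: int = 400):
    """Invert the activated-fraction formula: ``p_hat = -ln(1 - F_hat)/T``.

    A saturated observation ``F_hat = 1`` has an infinite maximum-
    likelihood rate; it is capped to ``1 - 1/(2*n_alleles)`` (half a
    count below saturation) before inversion and flagged.

    Returns ``(p_hat, capped)``; both scalars for scalar input.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    F = np.asarray(F_hat, dtype=float)
    if np.any((F < 0) | (F > 1)):
        raise ValueError("F_hat must lie in [0, 1]")
    cap = 1.0 - 1.0 / (2.0 * n_alleles)
    capped = F > cap
    if np.any(capped):
        logger.warning(
            "%d saturated fraction(s) capped at %.6f before inversion",
            int(np.sum(capped)),
            cap,
        )
    p_hat = -np.log1p(-np.minimum(F, cap)) / T
    if p_hat.ndim == 0:
        return float(p_hat), bool(capped)
    return p_hat, capped


def correlate_with_dorsal(
    values: np.ndarray,
    profile: DorsalProfile,
    columns: np.ndarray | None = None,
) -> float:
    """Pearson correlation of per-column values against Dorsal levels.

    ``columns`` selects which profile columns the values belong to
    (default: the profile's own column order). Zero-variance inputs are
    assigned r = 0 with a degenerate-input warning; fewer than 3 finite
    pairs is an error.
    """
    values = np.asarray(values, dtype=float)
    if columns is None:
        if values.size != profile.columns.size:
            raise ValueError("values length must match the profile")
        levels = profile.levels
    else:
        levels = np.array([profile.level(int(c)) for c in np.asarray(columns)])
    ok = np.isfinite(values) & np.isfinite(levels)
    if ok.sum() < 3:
        raise ValueError("need at least 3 columns with finite values")
    v, d = values[ok], levels[ok]
    if np.ptp(v) == 0 or np.ptp(d) == 0:
        warnings.warn("zero-variance input; Pearson r defined as 0", stacklevel=2)
        return 0.0
    return float(stats.pearsonr(v, d).statistic)


def summarize_activation(
    table: pd.DataFrame, alleles_per_nucleus: int = 2
) -> pd.DataFrame:
    """Per-column activation summary from a simulated allele table.

    Input is the output of
    :func:`embryofish.synthetic.simulate_activation`; the result carries
    ``column``, ``n_nuclei``, ``n_TS`` (active alleles) and ``F_hat``
    and plugs directly into :func:`fit_activation`.
    """
    grouped = table.groupby("column")
    out = pd.DataFrame(
        {
            "column": np.array(sorted(table["column"].unique())),
            "n_nuclei": grouped["nucleus"].nunique().sort_index().to_numpy(),
            "n_TS": grouped["active"].sum().sort_index().to_numpy(),
        }
    )
    out["F_hat"] = out["n_TS"] / (alleles_per_nucleus * out["n_nuclei"])
    return out


@dataclass
class ActivationFit:
    """Per-column activation fit and its correlations with Dorsal."""

    T: float
    table: pd.DataFrame  # column, F_hat, p_hat, capped, dorsal
    r_F: float  # Pearson r of F_hat vs Dorsal
    r_p: float  # Pearson r of p_hat vs Dorsal


def fit_activation(
    summaries: pd.DataFrame,
    profile: DorsalProfile,
    T: float,
    alleles_per_nucleus: int = 2,
) -> ActivationFit:
    """Fit the activation model to per-column summaries.

    ``summaries`` must carry ``column``, ``F_hat`` and ``n_nuclei`` (the
    output of :func:`embryofish.quantify.summarize_columns` or a
    simulation summary). Infers per-column probabilities and reports the
    Pearson correlations of both F_hat and p_hat against Dorsal.
    """
    if len(summaries) < 3:
        raise ValueError("need summaries for at least 3 columns")
    cols = summaries["column"].to_numpy()
    F = summaries["F_hat"].to_numpy(dtype=float)
    n_alleles = alleles_per_nucleus * summaries["n_nuclei"].to_numpy()
    p_hat = np.empty_like(F)
    capped = np.zeros(F.size, dtype=bool)
    for i in range(F.size):
        p_hat[i], capped[i] = infer_probability(F[i], T, int(n_alleles[i]))
    dorsal = np.array([profile.level(int(c)) for c in cols])
    table = pd.DataFrame(
        {"column": cols, "F_hat": F, "p_hat": p_hat, "capped": capped, "dorsal": dorsal}
    )
    r_F = correlate_with_dorsal(F, profile, columns=cols)
    r_p = correlate_with_dorsal(p_hat, profile, columns=cols)
    return ActivationFit(T=T, table=table, r_F=r_F, r_p=r_p)
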