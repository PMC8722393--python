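"""Fit the stochastic activation model F = 1 - exp(-T*p).

Two levels: (a) the image-based fit on the rendered embryo (per-column
active-allele fraction from detected, classified and nucleus-assigned
TSs); (b) the model-level study at desk scale — 20 simulated embryos
with Dorsal-proportional activation and 50 with a uniform switch-like
probability — reporting the mean Pearson correlations of the activated
fraction and the inverted per-minute probability against the Dorsal
profile.
"""

import json
import shutil
from pathlib import Path

import numpy as np

from embryofish.activation import (
    correlate_with_dorsal,
    fit_activation,
    summarize_activation,
)
from embryofish.pipeline import PipelineConfig, run_stage
from embryofish.synthetic import ActivationConfig, DorsalProfile, simulate_activation

SCRATCH = Path("scratch/pipeline")
RESULTS = Path("results")


def one_sided_profile(n, sigma=4.0):
    cols = np.arange(n)
    return DorsalProfile(columns=cols, levels=np.exp(-(cols**2) / (2 * sigma**2)))


def model_level_study():
    T = 15.0
    profile = one_sided_profile(10)
    r_F, r_p = [], []
    for seed in range(20):
        cfg = ActivationConfig(p_mid=1 / T, T=T, n_nuclei_per_column=200, seed=seed)
        fit = fit_activation(
            summarize_activation(simulate_activation(profile, cfg)), profile, T=T
        )
        r_F.append(fit.r_F)
        r_p.append(fit.r_p)
    prof20 = one_sided_profile(20)
    r_unif = []
    for seed in range(50):
        cfg = ActivationConfig(p_mid=3 / T, T=T, n_nuclei_per_column=100, seed=seed)
        summary = summarize_activation(
            simulate_activation(prof20, cfg, proportional=False)
        )
        r_unif.append(
            correlate_with_dorsal(
                summary["F_hat"].to_numpy(), prof20, columns=summary["column"]
            )
        )
    return float(np.mean(r_F)), float(np.mean(r_p)), float(np.mean(r_unif))


def main() -> None:
    cfg = PipelineConfig(seed=7)
    run_stage("fit-activation", cfg, SCRATCH)
    image_fit = json.loads((SCRATCH / "activation_fit.json").read_text())
    shutil.copy(SCRATCH / "activation_fit.csv", RESULTS / "05_activation_fit.csv")

    r_F, r_p, r_unif = model_level_study()
    out = {
        "image_based": image_fit,
        "model_level": {
            "mean_r_F_graded": r_F,
            "mean_r_p_graded": r_p,
            "mean_r_F_uniform": r_unif,
        },
    }
    (RESULTS / "05_activation_correlations.json").write_text(json.dumps(out, indent=1))

    print("image-based fit on the rendered embryo: "
          f"r(F,D) = {image_fit['r_F']:.2f}, r(p,D) = {image_fit['r_p']:.2f}")
    print("model-level (200 nuclei/column, 20 seeds): "
          f"r(F,D) = {r_F:.3f}, r(p,D) = {r_p:.3f} under p ~ Dorsal")
    print(f"switch-like control (uniform p): r(F,D) = {r_unif:.3f} — "
          "the graded response requires a Dorsal-dependent probability")


if __name__ == "__main__":
    main()
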