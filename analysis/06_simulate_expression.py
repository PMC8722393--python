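"""Forward-simulate graded mRNA accumulation and the intron delay.

Accumulated mRNA per column under constant versus Dorsal-graded Pol II
loading (the graded rule sharpens the profile), and the deterministic
elongation model: 25 kb of intron at 2 kb/min delays the first mature
T48 mRNA by 12.5 min relative to the intronless cDNA, inside the
10-15 min window that postpones translation until cellularization ends.
"""

import json
import shutil
from pathlib import Path

import pandas as pd

from embryofish.activation import correlate_with_dorsal
from embryofish.expression import simulate_accumulation, simulate_elongation
from embryofish.genes import T48, T48_CDNA
from embryofish.pipeline import PipelineConfig, run_stage
from embryofish.synthetic import DorsalProfile

SCRATCH = Path("scratch/pipeline")
RESULTS = Path("results")


def main() -> None:
    cfg = PipelineConfig(seed=7)
    run_stage("simulate-expression", cfg, SCRATCH)
    for name in ("expression_sim", "probe_pattern", "maturation_ratio"):
        shutil.copy(SCRATCH / f"{name}.csv", RESULTS / f"06_{name}.csv")

    prof_df = pd.read_csv(SCRATCH / "dorsal_profile.csv")
    profile = DorsalProfile(
        columns=prof_df["column"].to_numpy(), levels=prof_df["dorsal"].to_numpy()
    )
    rs = {}
    for loading in ("constant", "graded"):
        res = simulate_accumulation(profile, cfg.p_mid_expression, cfg.T, loading)
        rs[loading] = correlate_with_dorsal(res.M[-1], profile)
    endo = simulate_elongation(T48)
    cdna = simulate_elongation(T48_CDNA)
    delay = endo.mature - cdna.mature
    (RESULTS / "06_expression_summary.json").write_text(json.dumps({
        "r_M_vs_dorsal_constant": rs["constant"],
        "r_M_vs_dorsal_graded": rs["graded"],
        "t48_maturation_min": endo.mature,
        "cdna_maturation_min": cdna.mature,
        "intron_delay_min": delay,
    }, indent=1))

    print(f"accumulated-mRNA correlation with Dorsal: constant loading "
          f"r = {rs['constant']:.3f}, graded loading r = {rs['graded']:.3f}")
    print(f"first mature T48 mRNA {endo.mature:.1f} min after activation "
          f"(cDNA: {cdna.mature:.1f} min) -> intron delay {delay:.1f} min")


if __name__ == "__main__":
    main()
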