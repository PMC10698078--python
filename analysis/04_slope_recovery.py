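#!/usr/bin/env python
"""Parameter-recovery experiments for the four headline regression slopes.

Regenerates 200 seeded replicates per setting (C/N stoichiometry fits for
13C and 15N; lateral-root coupling fits for both isotopes), fits OLS per
replicate, and summarizes mean recovered slope, its spread, and the power of
the slope-vs-1.0 test for the coupling designs. Also quantifies the
attenuation that zero-rectification induces in the full synthetic pipeline.
Writes results/slope_recovery.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mycotrace import fit_linear, generate_study
from mycotrace.recovery import recover_cn_slope, recover_coupling_slope

OUT = Path(__file__).resolve().parents[1] / "results" / "slope_recovery.tsv"
SEED = 7


def main() -> None:
    rows = []
    settings = [
        ("cn_13c", recover_cn_slope(-2.49, 57.1, 5.0, 33, base_seed=SEED), -2.49),
        ("cn_15n", recover_cn_slope(-0.57, 15.1, 2.0, 38, base_seed=SEED), -0.57),
        ("coupling_13c", recover_coupling_slope(1.23, 3.0, 40, (0, 40),
                                                base_seed=SEED), 1.23),
        ("coupling_15n", recover_coupling_slope(0.53, 1.5, 40, (0, 20),
                                                base_seed=SEED,
                                                direction="less"), 0.53),
    ]
    for name, res, generating in settings:
        rows.append({
            "analysis": name, "generating_slope": generating,
            "mean_recovered_slope": res.mean_slope,
            "sd_recovered_slope": float(np.std(res.slopes, ddof=1)),
            "rejection_rate_vs_1": res.rejection_rate,
            "n_replicates": res.n_replicates,
        })
        power = ("" if res.rejection_rate is None
                 else f", power vs 1.0 = {res.rejection_rate:.2f}")
        print(f"{name}: generating {generating:+.2f}, recovered "
              f"{res.mean_slope:+.4f}{power}")

    # rectification attenuation in the full synthetic pipeline
    rect, untrunc = [], []
    for rep in range(60):
        t = generate_study(seed=1000 + rep).observation_truth
        rect.append(fit_linear(t["cn_obs"], t["em_13c"]).slope)
        untrunc.append(fit_linear(t["cn_obs"], t["em_13c_untruncated"]).slope)
    rows.append({
        "analysis": "cn_13c_pipeline_rectified", "generating_slope": -2.49,
        "mean_recovered_slope": float(np.mean(rect)),
        "sd_recovered_slope": float(np.std(rect, ddof=1)),
        "rejection_rate_vs_1": None, "n_replicates": 60,
    })
    print(f"zero-rectification attenuation (13C ~ C/N, full pipeline): "
          f"emitted-data slope {np.mean(rect):+.3f} vs untruncated "
          f"{np.mean(untrunc):+.3f} (generating -2.49)")

    OUT.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT, sep="\t", index=False)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
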