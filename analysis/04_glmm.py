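#!/usr/bin/env python
"""Per-site mixed models of the scored change score on the seven
overcrowding predictors.

One Gaussian linear mixed model per site with random intercepts for time
slot, participant and gender; reports estimates with 95% CIs and
significance bands, variance components, ICC and marginal/conditional R².
Writes a result-table-shaped CSV to results/.
"""

from pathlib import Path

import pandas as pd

from crowdstress.io import read_fused_csv
from crowdstress.models import GlmmSpec, fit_glmm

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    fused = read_fused_csv(ROOT / "scratch" / "fused.csv")
    results = fit_glmm(fused, GlmmSpec())
    rows = []
    for site, res in results.items():
        for pred, fe in res.fixed_effects.items():
            if pred == "(Intercept)":
                continue
            rows.append(
                {
                    "site": site,
                    "predictor": pred,
                    "estimate": fe["estimate"],
                    "ci_low": fe["ci_low"],
                    "ci_high": fe["ci_high"],
                    "stars": fe["stars"],
                }
            )
        rows.append({"site": site, "predictor": "sigma2", "estimate": res.sigma2})
        for grp, tau in res.tau.items():
            rows.append({"site": site, "predictor": f"tau00 {grp}", "estimate": tau})
        rows.append({"site": site, "predictor": "ICC", "estimate": res.icc})
        rows.append({"site": site, "predictor": "R2 marginal", "estimate": res.r2_marginal})
        rows.append({"site": site, "predictor": "R2 conditional", "estimate": res.r2_conditional})
        rows.append({"site": site, "predictor": "N observations", "estimate": res.n_obs})
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "04_glmm_sites.csv", index=False, float_format="%.4f")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
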