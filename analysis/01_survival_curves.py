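"""Pseudo-IPD pipeline: simulate, digitize, reconstruct, refit.

For each arm and endpoint this script draws pseudo individual-patient
data from the fitted Weibull laws at the trial arm sizes (473 / 482, 36
months of follow-up), produces the digitized-curve surrogate (monthly
survival grid plus a 3-monthly numbers-at-risk table), reconstructs
pseudo-IPD from the digitized curve alone, and refits the Weibull law to
the reconstruction -- demonstrating that every published survival input
is recoverable from figure-level information.

Writes results/fits.csv and results/survival_curves.png.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from gcea.config import default_config
from gcea.ipd import km_estimate, reconstruct_ipd, simulate_ipd
from gcea.survival import fit_weibull, survival_at

OUT = Path("results")
OUT.mkdir(exist_ok=True)
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0

cfg = default_config()
rows = []
fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), sharey=True)

for key, spec in cfg.strategies.items():
    for ax, endpoint in zip(axes, ("PFS", "OS")):
        params = (spec.pfs if endpoint == "PFS" else spec.os).build()
        ipd = simulate_ipd(
            params,
            n=spec.n,
            admin_censor_time=cfg.synthetic.admin_censor_months,
            dropout_annual_prob=cfg.synthetic.dropout_annual_prob,
            seed=SEED,
            arm=key,
            endpoint=endpoint,
        )
        curve = km_estimate(ipd, label=f"{key} {endpoint}")
        refit = fit_weibull(reconstruct_ipd(curve), label=f"{key} {endpoint}")
        rows.append(
            {
                "arm": key,
                "endpoint": endpoint,
                "lambda_true": params.scale_lambda,
                "gamma_true": params.shape_gamma,
                "lambda_refit": refit.scale_lambda,
                "gamma_refit": refit.shape_gamma,
                "lambda_ci_low": refit.ci_scale[0],
                "lambda_ci_high": refit.ci_scale[1],
                "gamma_ci_low": refit.ci_shape[0],
                "gamma_ci_high": refit.ci_shape[1],
                "inside_ci": (
                    refit.ci_scale[0] <= params.scale_lambda <= refit.ci_scale[1]
                    and refit.ci_shape[0] <= params.shape_gamma <= refit.ci_shape[1]
                ),
            }
        )
        ax.step(curve.times, curve.survival, where="post", alpha=0.6,
                label=f"{spec.label} (KM of pseudo-IPD)")
        t = np.linspace(0, 60, 301)
        ax.plot(t, survival_at(params, t), lw=1.2)
        ax.set_title(endpoint)
        ax.set_xlabel("months")

axes[0].set_ylabel("survival probability")
axes[0].legend(fontsize=7)
fig.tight_layout()
fig.savefig(OUT / "survival_curves.png", dpi=150)

fits = pd.DataFrame(rows)
fits.to_csv(OUT / "fits.csv", index=False)
print(fits.round(5).to_string(index=False))
print(
    f"\n{fits['inside_ci'].sum()}/{len(fits)} digitize->reconstruct->refit "
    "round trips recover the generating parameters within the refit 95% CI."
)
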