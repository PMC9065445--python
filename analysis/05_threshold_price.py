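"""Threshold-price search: how cheap must nivolumab be to be cost-effective?

Bisects a multiplier on the nivolumab unit price until the deterministic
ICER equals the willingness-to-pay threshold, and reports the ICER at a
flat 90% price reduction for comparison.  Writes results/threshold_price.csv.
"""

from pathlib import Path

import pandas as pd

from gcea.config import default_config
from gcea.model import run_base_case
from gcea.sensitivity import threshold_price

OUT = Path("results")
OUT.mkdir(exist_ok=True)

cfg = default_config()
res = threshold_price(cfg, cfg.wtp)
print(
    f"Nivolumab becomes cost-effective at {res.multiplier:.1%} of its current "
    f"price (a {res.reduction:.1%} reduction): ICER ${res.icer_at_multiplier:,.2f}/QALY "
    f"at the WTP of ${cfg.wtp:,.2f}/QALY."
)

cut = cfg.model_copy(deep=True)
cut.economics.drug_prices["nivolumab"].price_usd *= 0.10
icer_90 = run_base_case(cut).incremental.icer
print(f"At a flat 90% price reduction the ICER is ${icer_90:,.2f}/QALY.")

pd.DataFrame(
    [
        {
            "target_wtp": cfg.wtp,
            "price_multiplier": res.multiplier,
            "price_reduction": res.reduction,
            "icer_at_multiplier": res.icer_at_multiplier,
            "icer_at_90pct_reduction": icer_90,
        }
    ]
).to_csv(OUT / "threshold_price.csv", index=False)
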