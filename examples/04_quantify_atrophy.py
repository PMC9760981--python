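"""Quantify gland atrophy: MG loss rate, meiboscore, and RMSE.

The MG loss rate is the fraction of the eyelid not covered by glands,
1 - gland area / eyelid area.  The meiboscore grades it into the clinical
0-3 scale in one-third steps.  RMSE summarizes how closely predicted loss
rates track the ground truth over a test set.
"""

import numpy as np

from meibseg import (LossRateRecord, builtin_style, generate_dataset,
                     loss_rate_rmse, meiboscore, mg_loss_rate)

items = generate_dataset(12, None, builtin_style("deviceA"), seed=4)

print("image            loss rate   meiboscore")
records = []
rng = np.random.default_rng(0)
for it in items[:6]:
    rate = mg_loss_rate(it.mask)
    print(f"  {it.image_id}   {rate:8.3f}   {meiboscore(rate)}")

# emulate an imperfect segmenter: perturb the true rates a little
for it in items:
    true = mg_loss_rate(it.mask)
    predicted = float(np.clip(true + rng.normal(0, 0.05), 0, 1))
    records.append(LossRateRecord(it.image_id, predicted, true))

print(f"\nloss-rate RMSE of the simulated predictions: "
      f"{loss_rate_rmse(records):.3f}")
print("grade agreement:",
      sum(r.predicted_grade == r.true_grade for r in records), "/", len(records))
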