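"""Train a small segmentation network on phantoms and score it.

Uses a quarter-width network at 64x64 input so the run finishes in about a
minute on a laptop CPU.  Larger settings (width_scale, input_size, epochs)
trade time for accuracy.
"""

import numpy as np

from meibseg import (NetworkConfig, TrainConfig, build_network, builtin_style,
                     generate_dataset, predict_mask, region_metrics, train)

style = builtin_style("deviceA")
train_set = generate_dataset(16, None, style, seed=1)
val_set = generate_dataset(4, None, style, seed=2)
test_set = generate_dataset(8, None, style, seed=3)

net = build_network(NetworkConfig(width_scale=0.25, input_size=64, seed=0))
cfg = TrainConfig(max_epochs=8, batch_size=4, input_size=64, seed=0)
net, history = train(net, train_set, val_set, cfg, verbose=True)

print(f"\nbest validation epoch: {history.best_epoch}")
for region, name in ((2, "MG"), (1, "eyelid")):
    dscs = [region_metrics(predict_mask(net, it.image), it.mask, region).dsc
            for it in test_set]
    print(f"held-out {name:6s} DSC: {np.mean(dscs):.3f} +/- {np.std(dscs):.3f}")
# DSC (Dice similarity coefficient) is 2|P∩T|/(|P|+|T|): 1 means the
# predicted region coincides with the ground truth, 0 means no overlap.
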