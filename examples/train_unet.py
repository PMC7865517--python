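"""Train a small fusion U-Net on synthetic stacks with LP-fused targets.

Generates 40 stacks, trains a narrow (base_filters=8) network for 10
epochs, and scores the held-out stacks. The held-out SSIM against the
LP targets shows how closely the learned fusion mimics the pyramid
reference; values approach 1 with more data and epochs (a full run uses
200 stacks / 30 epochs).
"""

import numpy as np

from focusfuse import (
    TrainingConfig,
    UNetConfig,
    build_unet,
    fuse_unet,
    make_dataset,
    ssim,
    train_unet,
)

train, test = make_dataset(40, size=64, seed=7)
net = build_unet(UNetConfig(input_side=64, base_filters=8), seed=7)
history = train_unet(net, [(s.stack, t) for s, t in train],
                     TrainingConfig(epochs=10, seed=7))

print(f"epochs run      : {len(history.train_mse)}")
print(f"final train MSE : {history.train_mse[-1]:.6f}")
print(f"best held-out   : {history.best_val_mse:.6f} (epoch {history.best_epoch})")
scores = [ssim(fuse_unet(net, s.stack), t) for s, t in test]
print(f"held-out SSIM vs LP targets: mean {np.mean(scores):.3f}, "
      f"min {min(scores):.3f} over {len(scores)} stacks")
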