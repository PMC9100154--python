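"""Trainable-parameter accounting for the five transfer-learning backbones.

Each backbone gets its classification top replaced by global average
pooling plus a 4-way softmax head.  Under the quarter-freeze fine-tuning
policy the first ~25% of backbone layers are held fixed; the difference in
trainable parameters is exactly the frozen prefix.
"""

from celltax.backbone_accounting import (
    BACKBONE_NAMES,
    FREEZE_PREFIX,
    backbone_layers,
    head_params,
    trainable_parameters,
)

print(f"{'backbone':16s} {'all weights':>12s} {'25% frozen':>12s} "
      f"{'head':>6s} {'frozen layers':>14s}")
for name in BACKBONE_NAMES:
    full = trainable_parameters(name)
    frozen = trainable_parameters(name, freeze_first_quarter=True)
    print(f"{name:16s} {full:>12,} {frozen:>12,} {head_params(name):>6,} "
          f"{FREEZE_PREFIX[name]:>3d} of {len(backbone_layers(name))}")
print("\ncounts are trainable tensors only; batch-norm moving statistics "
      "never count, and the dense head (feature_dim x 4 + 4) is always "
      "trainable")
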