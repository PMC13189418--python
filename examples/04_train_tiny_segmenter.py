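"""Train the tiny segmentation network on a handful of phantoms.

Runs a deliberately short stage-1 training (48 phantoms, a few epochs) so
the whole script finishes in about a minute on one CPU, then reports the
validation macro Dice over kidney and lesion.  For the full scaled protocol
(200 phantoms, Dice ~0.98) see scripts/acceptance.py.
"""

from renalswin.nn.segmodel import SegmentationModel
from renalswin.nn.swin import PROFILES
from renalswin.pipeline import _split_indices, build_phantom_arrays
from renalswin.train import TrainConfig, evaluate_seg, train_segmentation

data, manifest = build_phantom_arrays(n_per_class=12, image_size=64, seed=0)
splits = _split_indices(manifest)
model = SegmentationModel(PROFILES["tiny"], 64, in_channels=2, seed=0)
cfg = TrainConfig(lr=3e-3, epochs=6, patience=6, batch_size=8, seed=0)
state = train_segmentation(model, data, splits["train"], splits["val"], cfg)

print("epoch history (train loss, val Dice):")
for h in state.history:
    print(f"  epoch {h['epoch']}: loss {h['train_loss']:.3f} "
          f"dice {h['val_dice']:.3f}")
print(f"best validation macro Dice: {state.best_metric:.3f}")
print(f"held-out test macro Dice:  {evaluate_seg(model, data, splits['test']):.3f}")
# Dice climbs from ~0.4 toward 0.9+ as the network learns that intensity
# plus the Gamma atypicality channel separate background/kidney/lesion.
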