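"""End-to-end domain-generalization demo on synthetic phantoms.

Source-domain phantoms train a tiny built-in segmenter; target-domain
phantoms share the same anatomy-generation process but are darker, lower
in contrast and noisier (pure covariate shift, like a different scanner
protocol). We compare three augmentation policies by mean foreground Dice
on the unseen target domain: values near 1 mean the predicted organ masks
overlap the truth almost perfectly, and the gap between the source and
target columns is the generalization penalty each policy pays.
"""

import numpy as np

from bucketaugment import (
    DomainShift,
    GaussianFeatureSegmenter,
    PhantomConfig,
    TrainConfig,
    evaluate_dice,
    make_domain_pair,
    patchify,
    train,
)

source_cfg = PhantomConfig(shape=(32, 32, 32), noise_sigma=0.05)
shift = DomainShift(intensity_offset=-0.08, contrast_gamma=0.4,
                    noise_sigma=0.05)
source, target = make_domain_pair(source_cfg, shift, n_source=8, n_target=4,
                                  seed=7)

patch = (16, 16, 16)
train_set = [p for v in source[:6] for p in patchify(v, patch)]
val_set = [p for v in source[6:] for p in patchify(v, patch)]
test_set = [p for v in target for p in patchify(v, patch)]

print(f"{len(train_set)} training / {len(val_set)} validation patches "
      f"(source), {len(test_set)} test patches (shifted target)\n")
print(f"{'policy':18s} {'source Dice':>12s} {'target Dice':>12s}")
for mode in ("none", "trivialaugment", "bucketaugment"):
    cfg = TrainConfig(epochs=24, val_every_k_epochs=2, patch_size=patch,
                      n_buckets=6, n_ops=3, seed=1, augmentation_mode=mode)
    model = GaussianFeatureSegmenter(n_classes=3, seed=1)
    _, controller, log = train(train_set, val_set, model, cfg)
    src_dice = np.mean(list(evaluate_dice(model, val_set).values()))
    tgt_dice = np.mean(list(evaluate_dice(model, test_set).values()))
    print(f"{mode:18s} {src_dice:12.4f} {tgt_dice:12.4f}")
    if mode == "bucketaugment":
        print(f"{'':18s} final Q-table {list(controller.q)}")
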