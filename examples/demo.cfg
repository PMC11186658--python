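# Demo run configuration: synthetic phantoms, small patches, short schedule.
# Any key can be omitted; defaults are sensible for the synthetic demo.
seed = 1
outdir = run
augmentation_mode = bucketaugment
n_buckets = 6
n_ops = 3
epochs = 24
val_every_k_epochs = 2
batch_size = 2
patch_size = 16,16,16
# phantom generator
shape = 32,32,32
n_large_organs = 1
n_small_organs = 1
noise_sigma = 0.05
spacing = 1.0,1.0,1.0
n_train = 4
n_val = 2
# transform-range override example: restrict zooming to gentle factors
range.zooming = 1.0:1.5
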