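# learning setting: skin segmentation
loss: dice_bce
ilr: 0.0003
epochs: 200
batch_size: 8
input_size: 224
augment: true
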