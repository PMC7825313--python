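# learning setting: nuclei segmentation
loss: dice_bce
ilr: 0.0003
epochs: 100
batch_size: 16
input_size: 128
augment: true
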