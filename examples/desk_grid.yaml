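# Desk-scale architecture grid for few-hundred-gene corpora; the first layer
# stays at roughly twice the supervised training-sample count to preserve
# the production setup's over-parameterized regime.
# The production default is layer1 {4096,2048,1024} x layer2 {512,256,128}
# x bottleneck {64,32,16} x batch {128,64} (54 candidates).
layer1_widths: [512]
layer2_widths: [64]
bottleneck_widths: [16]
batch_sizes: [64]
screen_epochs: 20
refit_epochs: 200
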