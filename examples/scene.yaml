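# A translating, uniformly growing synthetic cell (ground truth included
# in the output): lving simulate --scene examples/scene.yaml --out demo/sim
shape: [128, 128]
pixel_size: 0.25        # um/px
frame_interval: 1.0     # min
n_frames: 31
velocity:
  kind: uniform
  u: 0.05               # um/min
  v: 0.02
source:
  kind: uniform_specific
  g: 0.05               # 1/h
noise_sigma: 0.0005     # um OPD (0.5 nm)
seed: 42
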