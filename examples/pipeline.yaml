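# Pipeline settings for the example movie:
# lving run --opd demo/sim/movie.tif --metadata demo/sim/movie.json \
#           --config examples/pipeline.yaml --out demo/out
window_min: 30.0            # growth-map window length (min)
cv_area_um2: 0.7            # control-volume area
window_size_px: 32          # PIV interrogation window
window_overlap: 0.75
search_radius_px: 4
segmentation_threshold_pg_per_um2: 0.05
seed: 0
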