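# Demo pipeline configuration.
# First generate the synthetic inputs:
#   respdiv simulate --outdir demo --seed 42 --category-effect 1200
# then run:
#   respdiv run-all --config examples/demo.yaml
weather_csv: demo/weather.csv
trials_csv: demo/trials.csv
outdir: demo/out
seed: 42
alpha_e: 0.05
alpha_gxe: 0.05
df_method: satterthwaite
year_range: [2000, 2012]
min_obs: 20
log_level: INFO
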