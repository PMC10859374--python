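# Example pipeline configuration for `pollenlag report`.
# Either point [run].input_csv at a daily series CSV or keep the
# [simulation] table to analyse a synthetic season.

[run]
out_dir = "pollenlag_out"
seed = 20190401
probs = [5, 25, 50, 75, 95]
grid_size = 50
reference = 0.0
make_plots = true

[model]
df_exposure = 3
df_lag = 4
max_lag = 30
time_df = "auto"
covariate_df = 3
include_dow = true
include_holiday = true

[simulation]
n_days = 183
seed = 20190401
start_date = "2019-04-01"
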