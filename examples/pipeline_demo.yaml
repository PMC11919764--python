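# A small coated-vesicle population analysed end to end:
# simulate -> corrupt -> clean -> neighbor cloud -> vertex angle ->
# alpha-vs-diameter correlation.  See `coatlattice run --help`.
n_vesicles: 8
diameter_min: 700.0
diameter_max: 1800.0
edge_length: 300.0
five_way_fraction: 0.1
pos_noise_sd: 5.0
ang_noise_sd: 2.0
junk_fraction: 0.2
seed: 11
make_figures: true
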