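# Demo configuration for `frailmark run-all --config examples/demo_config.yaml`
# and `frailmark simulate --config ...`. Flat keys mirror SyntheticConfig /
# the DCV repetition count; anything omitted keeps the study-design default.
n_pfs: 22
n_control: 27
repetitions: 10
sppb_marker_link: 0.6
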