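# A desk-scale run: synthetic affect-labelled EEG, disjoint 4-second
# windows, the proposed BiLSTM-LSTM model, one binary task per label.
synthetic:
  n_participants: 2
  n_trials_per_participant: 20
  label_ratios: {arousal: 0.5, valence: 0.5, dominance: 0.5, liking: 0.5}
labels: [arousal, valence, dominance, liking]
window_size: 512
overlap_param: 512
seg_mode: capped
seg_cap: 5
decimation: 8
stratify: true
seed: 3
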