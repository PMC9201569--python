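{
  "max_output_rate": {
    "default": {"n_neurons_by_index": [1, 192, 1000, 10000], "record_fraction": 1.0, "duration": 1000.0}
  },
  "spike_insertion": {
    "default": {"n_neurons_by_index": [1, 192, 1000, 10000], "spikes_per_neuron": 10, "weight": 6.0}
  },
  "relu_similarity": {
    "default": {"n_neurons_by_index": [1, 16, 64, 192], "rate_min": 10.0, "rate_max": 300.0, "n_rates": 8, "duration": 1000.0, "weight": 0.15}
  },
  "wta": {
    "default": {"style": "mirror", "n_pops": 2, "pop_size_by_index": [1, 8, 32, 96], "noise_rate": 150.0, "duration": 3000.0, "bin_width": 15.0, "n_repetitions": 10},
    "spikey-like": {"style": "mirror"},
    "spinnaker-like": {"style": "direct"}
  },
  "sudoku": {
    "default": {"style": "mirror", "q": 2, "n_clues": 8, "puzzle_seed": 1, "pop_size_by_index": [1, 4, 8, 16], "duration": 2000.0, "bin_width": 20.0, "noise_rate": 150.0, "clue_factor": 4.0, "n_repetitions": 10},
    "spikey-like": {"pop_size_by_index": [1, 2, 2, 2]}
  },
  "binam": {
    "default": {"n_in_by_index": [8, 16, 32, 64], "n_out_by_index": [8, 16, 32, 64], "k_in": 3, "k_out": 3, "m_samples": 5, "recall_samples": 5},
    "spikey-like": {"m_samples": 4}
  },
  "function_approximation": {
    "default": {"n_neurons_by_index": [8, 32, 64, 128], "n_fit_points": 40, "duration": 1500.0, "max_rate_in": 300.0, "max_rate_out": 150.0, "function": "identity"}
  },
  "slam": {
    "default": {"width": 15, "height": 15, "n_obstacles": 4, "trail_length_by_index": [100, 400, 1500, 3000], "world_seed": 1, "step_ms": 20.0}
  },
  "dnn_conversion": {
    "default": {"layout": [16, 8, 2], "task": "separable-blobs", "n_samples": 40, "mlp_seed": 1, "mode": "rate", "max_freq": 500.0, "T": 20.0, "presentation": 200.0, "weight_scale": 0.5, "parallel_instances": 1},
    "spikey-like": {"weight_scale": 0.3}
  }
}
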