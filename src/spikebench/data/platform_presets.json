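{
  "schema_version": 1,
  "description": "Per-neuron normalized cost rows for the brain scale-up comparison. Units: housekeeping and resting in W per neuron, e_ap in J per action potential, e_trans in J per transmission. Raw machine coefficients are user-supplied via the measurement-decomposition protocol; these rows are already normalized to one neuron.",
  "platforms": {
    "brain": {
      "housekeeping": 4.75e-11,
      "resting": 5.77e-11,
      "e_ap": 1.96e-11,
      "e_trans": 8.17e-15
    },
    "spikey": {
      "housekeeping": 1.37e-6,
      "resting": 3.83e-8,
      "e_ap": 4.39e-10,
      "e_trans": 1.08e-11
    },
    "spinnaker": {
      "housekeeping": 1.66e-4,
      "resting": 8.99e-5,
      "e_ap": 1.04e-8,
      "e_trans": 9.59e-9
    },
    "cpu_r2600x": {
      "housekeeping": 4.49e-4,
      "resting": 4.77e-5,
      "e_ap": 3.04e-8,
      "e_trans": 5.82e-8
    },
    "cpu_mobile": {
      "housekeeping": 1.23e-4,
      "resting": 4.25e-5,
      "e_ap": 4.46e-9,
      "e_trans": 2.14e-8
    },
    "gpu_rtx2070": {
      "housekeeping": 9.76e-7,
      "resting": 3.63e-6,
      "e_ap": 4.71e-9,
      "e_trans": 3.4e-9
    }
  }
}
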