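# Training acquisition protocol: 13 rows, 80 closures total.
# Each row: number of closures, object (must exist in the sim config
# catalog), stiffness label, and the control reference used.
protocol:
  - {n_closures: 10, object_name: void,       stiffness_label: void,  control_signal: sinusoidal}
  - {n_closures: 10, object_name: hand_dynam, stiffness_label: rigid, control_signal: sinusoidal}
  - {n_closures: 10, object_name: hand_dynam, stiffness_label: rigid, control_signal: emg}
  - {n_closures: 5,  object_name: 4xS1,       stiffness_label: soft,  control_signal: sinusoidal}
  - {n_closures: 5,  object_name: 4xS1,       stiffness_label: soft,  control_signal: emg}
  - {n_closures: 5,  object_name: 2xS1,       stiffness_label: soft,  control_signal: sinusoidal}
  - {n_closures: 5,  object_name: 2xS1,       stiffness_label: soft,  control_signal: emg}
  - {n_closures: 5,  object_name: 4xS2,       stiffness_label: rigid, control_signal: sinusoidal}
  - {n_closures: 5,  object_name: 4xS2,       stiffness_label: rigid, control_signal: emg}
  - {n_closures: 5,  object_name: 4xS3,       stiffness_label: rigid, control_signal: sinusoidal}
  - {n_closures: 5,  object_name: 4xS3,       stiffness_label: rigid, control_signal: emg}
  - {n_closures: 5,  object_name: 2xS1-2xS4,  stiffness_label: soft,  control_signal: sinusoidal}
  - {n_closures: 5,  object_name: 2xS1-2xS4,  stiffness_label: soft,  control_signal: emg}
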