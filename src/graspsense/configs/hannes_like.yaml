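# Synthetic drivetrain + controller parameter set ("hannes_like").
#
# Every number here is invented: the set is tuned so that the three grasp
# regimes (void / soft / rigid) produce separated steady-state currents
# while overlapping during transients, with void closures peaking below the
# 300 mA labeling gate.  It is NOT measured from any physical prosthesis.

motor:
  torque_constant: 0.03          # N·m/A at the output shaft
  armature_resistance: 1.0       # ohm
  electrical_time_constant: 0.005  # s
  reflected_inertia: 1.0e-4      # kg·m²
  viscous_friction: 2.0e-3       # N·m·s/rad
  current_limit: 2000.0          # mA
  voltage_limit: 12.0            # V

gains:
  kp_pos: 8.0                    # mA/deg
  kd_pos: 0.05                   # mA·s/deg
  pos_to_current_gain: 2.0
  kp_cur: 0.004                  # V/mA
  ki_cur: 0.05                   # V/(mA·s)
  sample_rate: 1000.0            # Hz

# Object catalog.  Spring rates follow a parallel-spring story: unit springs
# S1 = 2.0e-4, S2 = 2.0e-3, S3 = 3.0e-3, S4 = 1.25e-4 N·m/deg; "4xS2" means
# four S2 springs in parallel, etc.  "hand_dynam" is the rigid dynamometer
# body.  The active single-closure object defaults to void.
object: void
objects:
  void:
    stiffness_class: void
    spring_rate: 0.0
    contact_angle: 40.0
    contact_damping: 5.0e-4
  hand_dynam:
    stiffness_class: rigid
    spring_rate: 0.05
    contact_angle: 40.0
    contact_damping: 5.0e-4
  4xS2:
    stiffness_class: rigid
    spring_rate: 8.0e-3
    contact_angle: 40.0
    contact_damping: 5.0e-4
  4xS3:
    stiffness_class: rigid
    spring_rate: 1.2e-2
    contact_angle: 40.0
    contact_damping: 5.0e-4
  4xS1:
    stiffness_class: soft
    spring_rate: 8.0e-4
    contact_angle: 40.0
    contact_damping: 5.0e-4
  2xS1:
    stiffness_class: soft
    spring_rate: 4.0e-4
    contact_angle: 40.0
    contact_damping: 5.0e-4
  2xS1-2xS4:
    stiffness_class: soft
    spring_rate: 6.5e-4
    contact_angle: 40.0
    contact_damping: 5.0e-4

reference:
  sinusoidal:
    kind: sinusoidal
    amplitude: 90.0              # deg; full closure command
    frequency: 0.25              # Hz -> close by 2 s, reopen by 4 s
  emg_like:
    kind: emg_like
    amplitude: 90.0
    drive_level: 1.0             # nominal closing speed 30 deg/s
    residual_creep_rate: 2.0     # deg/s creep past the plateau
    noise_sd: 0.2

sim:
  duration: 4.0                  # s per closure
  sample_rate: 1000.0            # Hz (also the control rate)
  amplitude_jitter_sd: 3.0       # deg; per-closure command variability
  seed: 0
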