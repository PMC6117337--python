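# Two-electrode study: 10 µm fiber, transverse 400 µm pair, defaults
# matching the reference configuration.
fiber_diameter: 10.0
cathodic_width: 200.0          # µs
resistivities: {rho_x: 1211.0, rho_y: 1211.0, rho_z: 175.0}
electrodes:
  - [0.0, 0.0, 0.0]            # µm (x transverse, y depth, z longitudinal)
  - [400.0, 0.0, 0.0]
search: {accuracy: 0.1, amplitude_min: 0.0, amplitude_max: 30.0}
solver: {dt: 5.0, post_stimulus_time: 400.0, temperature: 36.0, spike_threshold: 10.0}
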