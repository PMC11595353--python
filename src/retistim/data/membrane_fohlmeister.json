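{
  "schema": "retistim.membrane-params.v1",
  "name": "fohlmeister-rgc-5conductance",
  "comment": "Five-conductance retinal ganglion cell membrane model (Na, Ca, delayed-rectifier K, A-type K, Ca-activated K, leak) in its published room-temperature parameterization. Units: conductances mS/cm^2, capacitance uF/cm^2, potentials mV, calcium mM, time ms.",
  "capacitance_uF_cm2": 1.0,
  "conductances_mS_cm2": {
    "g_na": 50.0,
    "g_ca": 2.2,
    "g_k": 12.0,
    "g_a": 36.0,
    "g_kca": 0.05,
    "g_leak": 0.05
  },
  "reversals_mV": {
    "e_na": 35.0,
    "e_k": -75.0,
    "e_leak": -65.0
  },
  "calcium": {
    "ca_external_mM": 1.8,
    "ca_resting_mM": 1e-4,
    "ca_dissociation_mM": 1e-3,
    "removal_tau_ms": 1.5,
    "shell_radius_um": 5.0,
    "temperature_K": 295.15
  }
}
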