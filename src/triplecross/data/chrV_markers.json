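{
  "names": ["unc-60", "dpy-11", "rol-9"],
  "mutant_phenotypes": ["Unc", "Dpy", "Rol"],
  "recessive": [true, true, true],
  "phase": "cis"
}
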