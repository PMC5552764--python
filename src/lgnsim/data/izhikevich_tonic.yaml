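# Tonic-mode Izhikevich parameterizations of the three LGN cell classes.
# TCR and TRN fire in regular-spiking (RS) mode, IN in fast-spiking (FS) mode.
TCR: {a: 0.02, b: 0.2, c: -65, d: 6, v_init: -65, u_init: -13}
IN:  {a: 0.1,  b: 0.2, c: -65, d: 6, v_init: -70, u_init: -14}
TRN: {a: 0.02, b: 0.2, c: -65, d: 6, v_init: -75, u_init: -15}
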