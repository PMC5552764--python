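# Base configuration of the 140-neuron LGN building block.
#
# Population sizes follow the 8:2:4 TCR:IN:TRN ratio over 140 neurons; the
# retinal spike source (RET) has one channel per pixel of the 12x12 crop.
# Projection rows give connection probability p_conn, synaptic weight w_syn
# (nA), transmission delay d_conn (ms) and sign.  The two inhibitory
# probabilities onto TCR split the measured 30.9% inhibitory fan-in 3:1
# between feed-forward (IN) and feedback (TRN) sources.
populations:
  TCR: {size: 80, preset: TCR}
  IN:  {size: 20, preset: IN}
  TRN: {size: 40, preset: TRN}
  RET: {size: 144}

projections:
  TCR->TRN: {p_conn: 0.35,  w_syn: 3, d_conn: 8,  sign: excitatory}
  IN->TCR:  {p_conn: 0.232, w_syn: 8, d_conn: 6,  sign: inhibitory}
  IN->IN:   {p_conn: 0.236, w_syn: 2, d_conn: 4,  sign: inhibitory}
  TRN->TCR: {p_conn: 0.077, w_syn: 2, d_conn: 8,  sign: inhibitory}
  TRN->TRN: {p_conn: 0.20,  w_syn: 2, d_conn: 4,  sign: inhibitory}
  RET->TCR: {p_conn: 0.071, w_syn: 5, d_conn: 10, sign: excitatory}
  RET->IN:  {p_conn: 0.474, w_syn: 4, d_conn: 10, sign: excitatory}

kinetics: {tau_e: 2.0, tau_i: 6.0}

# Feed-forward-inhibition suppression (feedback-dominant variant): the IN->TCR
# pathway is weakened and the whole 30.9% inhibitory budget moves to TRN->TCR.
in_suppressed_overrides:
  IN->TCR:  {p_conn: 0.07, w_syn: 1}
  TRN->TCR: {p_conn: 0.309}
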