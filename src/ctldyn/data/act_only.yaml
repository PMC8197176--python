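# Best-fitting parameter set for adoptive CTL transfer without anti-CD137
# costimulation.  Units: g, k_i, d_i, k_r, d_r, d_q in day^-1; k_e, k_q in
# CTL^-1 day^-1; s in TC^-2/3 day^-1.
g: 0.5
s: 0.7
k_e: 0.75
k_i: 49.6
d_i: 10.0
k_r: 3.8
d_r: 0.0
k_q: 9.2
d_q: 0.03
transfer_day: 3.0
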