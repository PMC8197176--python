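# Best-fitting parameter set for adoptive CTL transfer plus agonist
# anti-CD137 antibody costimulation.  Units as in act_only.yaml.
g: 0.5
s: 0.87
k_e: 0.5
k_i: 1.3
d_i: 0.32
k_r: 1.4
d_r: 0.0
k_q: 41.2
d_q: 0.97
transfer_day: 3.0
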