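# Fenton-Karma three-variable model, parameter set 2.
model: FK
name: FK2
D: 0.20
C_m: 1.0
tau_v_plus: 3.330
tau_v1_minus: 9.0
tau_v2_minus: 8.0
tau_w_plus: 250.0
tau_w_minus: 60.0
tau_d: 0.395
tau_0: 9.0
tau_r: 33.33
tau_si: 29.0
K: 15.0
u_c_si: 0.50
u_c: 0.13
u_v: 0.04
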