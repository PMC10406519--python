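# Fenton-Karma three-variable model, parameter set 1 (Beeler-Reuter-like).
# Units: D mm^2/ms; C_m ms; tau_* ms unless noted; K 1/a.u.; thresholds a.u.
model: FK
name: FK1
D: 0.20
C_m: 1.0
tau_v_plus: 13.030
tau_v1_minus: 19.6
tau_v2_minus: 1250.0
tau_w_plus: 800.0
tau_w_minus: 40.0
tau_d: 0.450
tau_0: 12.5
tau_r: 33.25
tau_si: 29.0
K: 10.0
u_c_si: 0.85
u_c: 0.13
u_v: 0.04
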