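# Bueno-Orovio-Cherry-Fenton minimal ventricular model (TNNP-emulating set).
# Units: D mm^2/ms; C_m ms; tau_* ms (tau_fi, tau_o*, tau_so*, tau_si printed
# dimensionless in the source table but act as time constants, ms); slopes
# k_* 1/a.u.; thresholds and voltages a.u.
model: BOCF
name: BOCF
D: 0.30
C_m: 1.0
theta_v: 0.3
theta_v_minus: 0.015
theta_w: 0.015
theta_o: 0.006
tau_v_plus: 1.4506
tau_v1_minus: 60.0
tau_v2_minus: 1150.0
tau_w_plus: 280.0
tau_w1_minus: 70.0
tau_w2_minus: 20.0
tau_fi: 0.11
tau_o1: 6.0
tau_o2: 6.0
tau_so1: 43.0
tau_so2: 0.2
tau_s1: 2.7342
tau_s2: 3.0
tau_si: 2.8723
tau_w_inf: 0.07
w_inf_star: 0.94
k_w_minus: 65.0
k_so: 2.0
k_s: 2.0994
u_o: 0.0
u_u: 1.58
u_w_minus: 0.03
u_so: 0.65
u_s: 0.9087
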