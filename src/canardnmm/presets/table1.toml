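# Bursting-discharge reference parameter set (delta = 0.3, epsilon = 0.2)
[params]
A = 5.0
B = 5.0
G = 35.0
p_mean = 90.0
sigma = 0.0
C1 = 135.0
C2 = 108.0
C3 = 80.0
C4 = 25.0
C5 = 450.0
C6 = 121.0
C7 = 121.0
tau_a = 0.01
tau_b = 0.05
tau_g = 0.003
vmax = 5.0
steepness = 0.56
v_half = 6.0
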