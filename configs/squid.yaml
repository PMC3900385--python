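membrane_capacitance: 1.0
g_na_max: 120.0
g_k_max: 36.0
g_leak: 0.3
e_na: 50.0
e_k: -77.0
e_leak: -54.4
area: 100.0
n_na: 6000
n_k: 1800
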