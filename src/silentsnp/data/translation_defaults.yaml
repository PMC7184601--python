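# Default translation-model parameters.
# Rates in 1/s (bimolecular: 1/(molecule*s)), delays in s, counts in molecules.
k_p1: 0.01
k_release: 1.0
k_P_decay: 3.0e-4
tau_p1: 10.0
tau_p2: 25.0
tau_mRNA: 5.0
tau_Rib: 50.0
tau_prot: 300.0
rib0: 100
mrna1_0: 50
mrna2_0: 50
trna0: 50
prot0: 0
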