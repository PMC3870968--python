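id	family
Aminotran_3_ref1	Aminotran_3
Aminotran_3_ref2	Aminotran_3
Aminotran_1_2_ref1	Aminotran_1_2
Aminotran_1_2_ref2	Aminotran_1_2
Beta_elim_lyase_ref1	Beta_elim_lyase
Beta_elim_lyase_ref2	Beta_elim_lyase
Pyridoxal_deC_ref1	Pyridoxal_deC
Pyridoxal_deC_ref2	Pyridoxal_deC
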