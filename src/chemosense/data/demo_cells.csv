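name,diameter_um,speed_um_s,l_bc_per_s,motility_class
Escherichia coli,2.0,20.0,2.2,flagellar
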