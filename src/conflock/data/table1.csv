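pair,kind,electrostatic_kJ_mol,vdw_kJ_mol,total_kJ_mol
Ile149A-Gly49B,hydrogen_bond,-14.42,-1.66,-16.08
Ile149A-Gly112B,hydrogen_bond,-10.21,-3.33,-13.54
Ile149B-Gly49A,hydrogen_bond,-15.32,-0.65,-15.97
Ile149B-Gly112A,hydrogen_bond,-9.62,-2.48,-12.10
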