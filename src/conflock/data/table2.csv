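pair,kind,electrostatic_kJ_mol,vdw_kJ_mol,total_kJ_mol
Val5A-Gly49B,hydrophobic,1.51,-1.94,-0.43
Val5A-Asp50B,hydrophobic,-0.25,-2.86,-3.11
Val7A-Asn51B,hydrophobic,0.13,-2.96,-2.83
Val7A-Thr52B,hydrophobic,-0.02,-2.08,-2.10
Thr17A-Thr52B,hydrophobic,0.05,-1.43,-1.37
Phe48A-Ala150B,hydrophobic,-1.33,-3.34,-4.67
Phe48A-Lys151B,hydrophobic,1.52,-5.42,-3.90
Gly49A-Val5B,hydrophobic,1.01,-1.87,-0.86
Gly49A-Gly148B,hydrophobic,-0.62,-2.36,-2.97
Asp50A-Val5B,hydrophobic,-0.22,-2.65,-2.87
Asn51A-Val7B,hydrophobic,0.62,-3.02,-2.40
Thr52A-Val7B,hydrophobic,0.03,-2.04,-2.02
Ile111A-Gly112B,hydrophobic,-0.07,-1.81,-1.88
Ile111A-Ile149B,hydrophobic,-0.42,-1.94,-2.36
Gly112A-Ile111B,hydrophobic,-0.05,-1.84,-1.89
Gly112A-Gly148B,hydrophobic,-3.45,-1.57,-5.02
Arg113A-Ile149B,hydrophobic,-1.01,-5.85,-6.86
Val146A-Gly148B,hydrophobic,0.03,-1.31,-1.29
Gly148A-Gly49B,hydrophobic,-0.67,-2.49,-3.16
Gly148A-Gly112B,hydrophobic,-3.32,-1.81,-5.13
Ile149A-Phe48B,hydrophobic,-3.85,-6.17,-10.02
Ile149A-Ile111B,hydrophobic,-0.34,-2.32,-2.66
Ile149A-Arg113B,hydrophobic,-0.51,-5.39,-5.89
Ala150A-Phe48B,hydrophobic,-1.80,-3.83,-5.62
Lys151A-Phe48B,hydrophobic,-0.52,-5.83,-6.34
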