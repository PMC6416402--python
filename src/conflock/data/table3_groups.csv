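pair,group
Ile149A-Gly112B,1
Val7A-Asn51B,1
Val7A-Thr52B,1
Thr17A-Thr52B,1
Gly49A-Gly148B,1
Asp50A-Val5B,1
Asn51A-Val7B,1
Thr52A-Val7B,1
Ile149A-Gly49B,2
Ile149B-Gly49A,2
Ile149B-Gly112A,2
Val5A-Gly49B,2
Val5A-Asp50B,2
Phe48A-Ala150B,2
Phe48A-Lys151B,2
Gly49A-Val5B,2
Ile111A-Gly112B,2
Ile111A-Ile149B,2
Gly112A-Ile111B,2
Gly112A-Gly148B,2
Arg113A-Ile149B,2
Val146A-Gly148B,2
Gly148A-Gly49B,2
Gly148A-Gly112B,2
Ile149A-Phe48B,2
Ile149A-Ile111B,2
Ile149A-Arg113B,2
Ala150A-Phe48B,2
Lys151A-Phe48B,2
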