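disease_id,parent_term,child_term
d000,C0_L1,C0_L2
d000,C0_L2,C0_L3
d000,C0_L3,d000
d000,ROOT,C0_L1
d001,C0_L1,C0_L2
d001,C0_L2,C0_L3
d001,C0_L3,d001
d001,ROOT,C0_L1
d002,C0_L1,C0_L2
d002,C0_L2,C0_L3
d002,C0_L3,d002
d002,ROOT,C0_L1
d003,C0_L1,C0_L2
d003,C0_L2,C0_L3
d003,C0_L3,d003
d003,ROOT,C0_L1
d004,C0_L1,C0_L2
d004,C0_L2,C0_L3
d004,C0_L3,d004
d004,ROOT,C0_L1
d005,C1_L1,C1_L2
d005,C1_L2,C1_L3
d005,C1_L3,d005
d005,ROOT,C1_L1
d006,C1_L1,C1_L2
d006,C1_L2,C1_L3
d006,C1_L3,d006
d006,ROOT,C1_L1
d007,C1_L1,C1_L2
d007,C1_L2,C1_L3
d007,C1_L3,d007
d007,ROOT,C1_L1
d008,C1_L1,C1_L2
d008,C1_L2,C1_L3
d008,C1_L3,d008
d008,ROOT,C1_L1
d009,C1_L1,C1_L2
d009,C1_L2,C1_L3
d009,C1_L3,d009
d009,ROOT,C1_L1
d010,C2_L1,C2_L2
d010,C2_L2,C2_L3
d010,C2_L3,d010
d010,ROOT,C2_L1
d011,C2_L1,C2_L2
d011,C2_L2,C2_L3
d011,C2_L3,d011
d011,ROOT,C2_L1
d012,C2_L1,C2_L2
d012,C2_L2,C2_L3
d012,C2_L3,d012
d012,ROOT,C2_L1
d013,C2_L1,C2_L2
d013,C2_L2,C2_L3
d013,C2_L3,d013
d013,ROOT,C2_L1
d014,C2_L1,C2_L2
d014,C2_L2,C2_L3
d014,C2_L3,d014
d014,ROOT,C2_L1
d015,C3_L1,C3_L2
d015,C3_L2,C3_L3
d015,C3_L3,d015
d015,ROOT,C3_L1
d016,C3_L1,C3_L2
d016,C3_L2,C3_L3
d016,C3_L3,d016
d016,ROOT,C3_L1
d017,C3_L1,C3_L2
d017,C3_L2,C3_L3
d017,C3_L3,d017
d017,ROOT,C3_L1
d018,C3_L1,C3_L2
d018,C3_L2,C3_L3
d018,C3_L3,d018
d018,ROOT,C3_L1
d019,C3_L1,C3_L2
d019,C3_L2,C3_L3
d019,C3_L3,d019
d019,ROOT,C3_L1
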