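experiment,throughput_kg_h,screw_speed_rpm,ls_ratio
N1,5,450,0.3
N2,5,675,0.3
N3,5,900,0.3
N4,12.5,450,0.3
N5,12.5,675,0.3
N6,12.5,900,0.3
N7,25,450,0.3
N8,25,675,0.3
N9,25,900,0.3
N10,5,450,0.45
N11,5,675,0.45
N12,5,900,0.45
N13,12.5,450,0.45
N14,12.5,675,0.45
N15,12.5,900,0.45
N16,25,900,0.45
N17,25,450,0.45
N18,5,900,0.6
N19,5,450,0.6
N20,12.5,450,0.6
N21,12.5,675,0.6
N22,12.5,900,0.6
N23,25,900,0.6
N24,25,675,0.6
N25,25,450,0.6
N26,12.5,675,0.375
N27,12.5,675,0.525
N28,12.5,675,0.337
N29,12.5,675,0.563
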