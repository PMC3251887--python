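{
  "name": "hg18-approx",
  "comment": "Approximate hg18 chromosome lengths and p/q arm boundaries (bp, 0-based half-open). Arm boundaries are cytoband-derived approximations; the gap between p_end and q_start is the centromeric region and carries no probes.",
  "chromosomes": [
    {"label": "1",  "length": 247249719, "p_end": 121100000, "q_start": 128000000},
    {"label": "2",  "length": 242951149, "p_end": 91000000,  "q_start": 95700000},
    {"label": "3",  "length": 199501827, "p_end": 89400000,  "q_start": 93500000},
    {"label": "4",  "length": 191273063, "p_end": 48700000,  "q_start": 52400000},
    {"label": "5",  "length": 180857866, "p_end": 45800000,  "q_start": 50500000},
    {"label": "6",  "length": 170899992, "p_end": 58500000,  "q_start": 63400000},
    {"label": "7",  "length": 158821424, "p_end": 57400000,  "q_start": 61100000},
    {"label": "8",  "length": 146274826, "p_end": 43200000,  "q_start": 48100000},
    {"label": "9",  "length": 140273252, "p_end": 46700000,  "q_start": 60300000},
    {"label": "10", "length": 135374737, "p_end": 38800000,  "q_start": 42100000},
    {"label": "11", "length": 134452384, "p_end": 51400000,  "q_start": 56400000},
    {"label": "12", "length": 132349534, "p_end": 34700000,  "q_start": 37800000},
    {"label": "13", "length": 114142980, "p_end": 16000000,  "q_start": 18400000},
    {"label": "14", "length": 106368585, "p_end": 15600000,  "q_start": 19100000},
    {"label": "15", "length": 100338915, "p_end": 15900000,  "q_start": 20000000},
    {"label": "16", "length": 88827254,  "p_end": 34400000,  "q_start": 44900000},
    {"label": "17", "length": 78774742,  "p_end": 22100000,  "q_start": 23200000},
    {"label": "18", "length": 76117153,  "p_end": 15400000,  "q_start": 17300000},
    {"label": "19", "length": 63811651,  "p_end": 26700000,  "q_start": 30200000},
    {"label": "20", "length": 62435964,  "p_end": 25700000,  "q_start": 28300000},
    {"label": "21", "length": 46944323,  "p_end": 10000000,  "q_start": 13200000},
    {"label": "22", "length": 49691432,  "p_end": 9600000,   "q_start": 14700000},
    {"label": "X",  "length": 154913754, "p_end": 58100000,  "q_start": 63000000},
    {"label": "Y",  "length": 57772954,  "p_end": 11200000,  "q_start": 12500000}
  ]
}
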