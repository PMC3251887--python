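{
  "comment": "Printed counts transcribed from the original INES infant-neuroblastoma study report. marker_by_* rows are [normal, altered]; columns as labelled. Times in months.",
  "sca_total": 48,
  "cohort_total": 218,
  "non_silent_total": 210,
  "table1": {
    "source": "published frequency table: segmental alterations by study group and clinical characteristics",
    "trial_cols": ["INES99.1", "INES99.2", "INES99.3"],
    "binary_cols": ["No", "Yes"],
    "markers": {
      "1p":  {"trial": [[85, 81, 24], [3, 10, 7]],  "liver": [[107, 83], [10, 10]], "skin": [[168, 22], [16, 4]], "bone_marrow": [[105, 85], [9, 11]],  "bone": [[171, 19], [14, 6]]},
      "2p":  {"trial": [[85, 82, 22], [3, 9, 9]],   "liver": [[111, 78], [6, 15]],  "skin": [[166, 23], [18, 3]], "bone_marrow": [[105, 84], [9, 12]],  "bone": [[171, 18], [14, 7]]},
      "3p":  {"trial": [[88, 90, 25], [0, 1, 6]],   "liver": [[112, 91], [5, 2]],   "skin": [[177, 26], [7, 0]],  "bone_marrow": [[111, 92], [3, 4]],   "bone": [[183, 20], [2, 5]]},
      "4p":  {"trial": [[84, 87, 25], [4, 4, 6]],   "liver": [[109, 87], [8, 6]],   "skin": [[171, 25], [13, 1]], "bone_marrow": [[105, 91], [9, 5]],   "bone": [[176, 20], [9, 5]]},
      "11q": {"trial": [[85, 85, 21], [3, 6, 10]],  "liver": [[105, 86], [12, 7]],  "skin": [[167, 24], [17, 2]], "bone_marrow": [[105, 86], [9, 10]],  "bone": [[175, 16], [10, 9]]},
      "17q": {"trial": [[81, 75, 15], [7, 16, 16]], "liver": [[97, 74], [20, 19]],  "skin": [[150, 21], [34, 5]], "bone_marrow": [[96, 75], [18, 21]],  "bone": [[160, 11], [25, 14]]}
    }
  },
  "table2": {
    "source": "published ploidy repartition table",
    "rows": ["NCA", "SCA", "SILENT"],
    "cols": ["DI_TETRAPLOID", "PSEUDOTRIPLOID"],
    "counts": [[16, 65], [16, 8], [1, 2]]
  },
  "fig3_bone": {
    "source": "published metastatic-status figure legend",
    "sca_with_bone": 17,
    "bone_total": 26,
    "sca_without_bone": 31,
    "no_bone_total": 185
  },
  "table3": {
    "source": "published relapse listing",
    "columns": ["patient", "protocol", "presentation", "profile", "months_to_relapse", "high_dose_salvage", "died_of_disease"],
    "rows": [
      [150, "INES99.1", null, "SILENT", 16, false, false],
      [165, "INES99.1", null, "SILENT", 1,  false, false],
      [279, "INES99.1", null, "NCA",    13, false, false],
      [100, "INES99.1", null, "NCA",    9,  false, false],
      [124, "INES99.1", null, "NCA",    15, false, false],
      [63,  "INES99.1", null, "NCA",    1,  false, false],
      [26,  "INES99.1", null, "NCA",    4,  false, false],
      [31,  "INES99.1", null, "NCA",    33, false, false],
      [168, "INES99.1", null, "NCA",    26, false, false],
      [227, "INES99.1", null, "SCA",    19, false, false],
      [235, "INES99.1", null, "SCA",    1,  false, false],
      [144, "INES99.1", null, "SCA",    3,  false, false],
      [174, "INES99.2", "no_symptoms", "SILENT", 3,  false, false],
      [23,  "INES99.2", "no_symptoms", "NCA",    4,  false, false],
      [183, "INES99.2", "no_symptoms", "NCA",    3,  false, false],
      [184, "INES99.2", "no_symptoms", "SCA",    7,  true,  false],
      [121, "INES99.2", "no_symptoms", "SCA",    4,  false, true],
      [196, "INES99.2", "no_symptoms", "SCA",    7,  false, false],
      [14,  "INES99.2", "no_symptoms", "SCA",    4,  false, false],
      [6,   "INES99.2", "no_symptoms", "SCA",    11, true,  false],
      [89,  "INES99.2", "no_symptoms", "SCA",    4,  true,  false],
      [118, "INES99.2", "symptoms",    "NCA",    7,  true,  false],
      [111, "INES99.2", "symptoms",    "NCA",    14, true,  true],
      [61,  "INES99.2", "symptoms",    "NCA",    7,  false, false],
      [172, "INES99.2", "symptoms",    "NCA",    0,  false, true],
      [75,  "INES99.2", "symptoms",    "SCA",    41, true,  true],
      [109, "INES99.2", "symptoms",    "SCA",    21, true,  false],
      [81,  "INES99.3", null, "SCA",    2,  false, false],
      [185, "INES99.3", null, "SCA",    15, false, false],
      [234, "INES99.3", null, "SCA",    9,  false, true]
    ]
  },
  "table4": {
    "source": "published marker-wise progression-free survival table",
    "rows": {
      "1p":  {"normal_n": 190, "altered_n": 20, "pfs_normal": 88.5, "pfs_altered": 74.3},
      "2p":  {"normal_n": 189, "altered_n": 21, "pfs_normal": 89.4, "pfs_altered": 66.3},
      "3p":  {"normal_n": 203, "altered_n": 7,  "pfs_normal": 86.6, "pfs_altered": 100.0},
      "4p":  {"normal_n": 196, "altered_n": 14, "pfs_normal": 87.7, "pfs_altered": 78.6},
      "11q": {"normal_n": 191, "altered_n": 19, "pfs_normal": 89.2, "pfs_altered": 63.2},
      "17q": {"normal_n": 171, "altered_n": 39, "pfs_normal": 91.2, "pfs_altered": 69.0}
    },
    "genomic_profile": {"NCA_n": 162, "SCA_n": 48, "SILENT_n": 8, "pfs": {"NCA": 92.0, "SCA": 70.7, "SILENT": 62.5}}
  }
}
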