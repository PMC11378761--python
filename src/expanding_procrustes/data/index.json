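{
  "table1": {"file": "table1.tsv", "title": "Group demographics: age, gender, arm length, eye height"},
  "table2": {"file": "table2.tsv", "title": "Average time to complete one trial of each task"},
  "table3": {"file": "table3.tsv", "title": "Inter-limb expanding-Procrustes DI and percent similarity, Group 1"},
  "table4": {"file": "table4.tsv", "title": "Inter-limb expanding-Procrustes DI and percent similarity, Group 2"},
  "table5": {"file": "table5.tsv", "title": "Intra-limb (dominant arm) DI and percent similarity, Group 1, Tasks 1-2"},
  "table6": {"file": "table6.tsv", "title": "Intra-limb (dominant arm) DI and percent similarity, Group 2, Tasks 1-2"},
  "table7": {"file": "table7.tsv", "title": "Intra-limb DI and percent similarity, both arms, Group 1, Task 3"},
  "table8": {"file": "table8.tsv", "title": "Intra-limb DI and percent similarity, both arms, Group 2, Task 3"},
  "tableA1": {"file": "tableA1.tsv", "title": "Maximum angular velocities in the positive y-direction (deg/s)"},
  "tableA2": {"file": "tableA2.tsv", "title": "Peak roll angle of limb segments (deg)"},
  "tableA3": {"file": "tableA3.tsv", "title": "Inter-limb traditional Procrustes dissimilarity indices"},
  "tableA4": {"file": "tableA4.tsv", "title": "Intra-limb traditional Procrustes dissimilarity indices"}
}
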