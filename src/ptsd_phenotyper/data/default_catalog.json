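{
  "measurable_criteria": ["B", "C", "D", "E", "G"],
  "parameters": [
    {
      "name": "cs_pre_inactivity_pct",
      "assay": "conditioned-stimulus reminder",
      "kind": "continuous",
      "transform": "log",
      "criteria": ["B"],
      "direction_of_pathology": "either"
    },
    {
      "name": "cs_post_inactivity_pct",
      "assay": "conditioned-stimulus reminder",
      "kind": "continuous",
      "transform": "log",
      "criteria": ["B"],
      "direction_of_pathology": "either"
    },
    {
      "name": "epm_open_closed_ratio",
      "assay": "elevated plus maze",
      "kind": "continuous",
      "transform": "sqrt",
      "criteria": ["C", "E"],
      "direction_of_pathology": "either"
    },
    {
      "name": "ld_dark_duration",
      "assay": "light/dark box",
      "kind": "continuous",
      "transform": "identity",
      "criteria": ["C", "E"],
      "direction_of_pathology": "either"
    },
    {
      "name": "barnes_probe",
      "assay": "Barnes maze",
      "kind": "binary",
      "transform": "identity",
      "criteria": ["D"],
      "direction_of_pathology": "either",
      "pathological_outcome": "fail"
    },
    {
      "name": "water_consumed_48h",
      "assay": "sucrose preference test",
      "kind": "continuous",
      "transform": "identity",
      "criteria": ["D"],
      "direction_of_pathology": "either"
    },
    {
      "name": "sucrose_consumed_24h",
      "assay": "sucrose preference test",
      "kind": "continuous",
      "transform": "identity",
      "criteria": ["D"],
      "direction_of_pathology": "either"
    },
    {
      "name": "social_novel_duration_t2",
      "assay": "Crawley sociability",
      "kind": "continuous",
      "transform": "identity",
      "criteria": ["G"],
      "direction_of_pathology": "either"
    },
    {
      "name": "social_novel_latency_t3",
      "assay": "Crawley sociability",
      "kind": "continuous",
      "transform": "log",
      "criteria": ["G"],
      "direction_of_pathology": "either"
    }
  ],
  "auxiliary": [
    {
      "name": "of_avg_velocity",
      "assay": "open field arena",
      "kind": "continuous",
      "transform": "sqrt",
      "criteria": [],
      "direction_of_pathology": "high"
    }
  ],
  "design_notes": {
    "A": "trauma exposure: all exposed mice underwent the stress paradigm",
    "F": "duration: behavioral testing conducted 4 weeks post-exposure",
    "H": "exclusion: phenotype not attributable to substance misuse or another medical condition"
  }
}
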