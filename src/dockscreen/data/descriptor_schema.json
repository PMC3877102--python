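[
 {
  "name": "MolWt",
  "group": "constitutional"
 },
 {
  "name": "HeavyAtomCount",
  "group": "constitutional"
 },
 {
  "name": "NumHeteroatoms",
  "group": "constitutional"
 },
 {
  "name": "NumValenceElectrons",
  "group": "constitutional"
 },
 {
  "name": "NHOHCount",
  "group": "constitutional"
 },
 {
  "name": "NOCount",
  "group": "constitutional"
 },
 {
  "name": "RingCount",
  "group": "constitutional"
 },
 {
  "name": "NumAromaticRings",
  "group": "constitutional"
 },
 {
  "name": "NumSaturatedRings",
  "group": "constitutional"
 },
 {
  "name": "NumAliphaticRings",
  "group": "constitutional"
 },
 {
  "name": "NumRotatableBonds",
  "group": "constitutional"
 },
 {
  "name": "FractionCSP3",
  "group": "constitutional"
 },
 {
  "name": "BalabanJ",
  "group": "topological"
 },
 {
  "name": "BertzCT",
  "group": "topological"
 },
 {
  "name": "HallKierAlpha",
  "group": "topological"
 },
 {
  "name": "Kappa1",
  "group": "topological"
 },
 {
  "name": "Kappa2",
  "group": "topological"
 },
 {
  "name": "Kappa3",
  "group": "topological"
 },
 {
  "name": "Chi0",
  "group": "connectivity_shape"
 },
 {
  "name": "Chi0n",
  "group": "connectivity_shape"
 },
 {
  "name": "Chi0v",
  "group": "connectivity_shape"
 },
 {
  "name": "Chi1",
  "group": "connectivity_shape"
 },
 {
  "name": "Chi1n",
  "group": "connectivity_shape"
 },
 {
  "name": "Chi1v",
  "group": "connectivity_shape"
 },
 {
  "name": "Chi2n",
  "group": "connectivity_shape"
 },
 {
  "name": "Chi2v",
  "group": "connectivity_shape"
 },
 {
  "name": "Chi3n",
  "group": "connectivity_shape"
 },
 {
  "name": "Chi3v",
  "group": "connectivity_shape"
 },
 {
  "name": "Chi4n",
  "group": "connectivity_shape"
 },
 {
  "name": "Chi4v",
  "group": "connectivity_shape"
 },
 {
  "name": "MaxPartialCharge",
  "group": "electronic_charge"
 },
 {
  "name": "MinPartialCharge",
  "group": "electronic_charge"
 },
 {
  "name": "MaxAbsPartialCharge",
  "group": "electronic_charge"
 },
 {
  "name": "MinAbsPartialCharge",
  "group": "electronic_charge"
 },
 {
  "name": "MaxEStateIndex",
  "group": "electronic_charge"
 },
 {
  "name": "MinEStateIndex",
  "group": "electronic_charge"
 },
 {
  "name": "MaxAbsEStateIndex",
  "group": "electronic_charge"
 },
 {
  "name": "MinAbsEStateIndex",
  "group": "electronic_charge"
 },
 {
  "name": "PEOE_VSA1",
  "group": "electronic_charge"
 },
 {
  "name": "PEOE_VSA2",
  "group": "electronic_charge"
 },
 {
  "name": "PEOE_VSA3",
  "group": "electronic_charge"
 },
 {
  "name": "PEOE_VSA4",
  "group": "electronic_charge"
 },
 {
  "name": "PEOE_VSA5",
  "group": "electronic_charge"
 },
 {
  "name": "PEOE_VSA6",
  "group": "electronic_charge"
 },
 {
  "name": "PEOE_VSA7",
  "group": "electronic_charge"
 },
 {
  "name": "PEOE_VSA8",
  "group": "electronic_charge"
 },
 {
  "name": "PEOE_VSA9",
  "group": "electronic_charge"
 },
 {
  "name": "PEOE_VSA10",
  "group": "electronic_charge"
 },
 {
  "name": "MolLogP",
  "group": "lipophilicity_solubility"
 },
 {
  "name": "MolMR",
  "group": "lipophilicity_solubility"
 },
 {
  "name": "SlogP_VSA1",
  "group": "lipophilicity_solubility"
 },
 {
  "name": "SlogP_VSA2",
  "group": "lipophilicity_solubility"
 },
 {
  "name": "SlogP_VSA3",
  "group": "lipophilicity_solubility"
 },
 {
  "name": "SlogP_VSA4",
  "group": "lipophilicity_solubility"
 },
 {
  "name": "SlogP_VSA5",
  "group": "lipophilicity_solubility"
 },
 {
  "name": "SlogP_VSA6",
  "group": "lipophilicity_solubility"
 },
 {
  "name": "SlogP_VSA7",
  "group": "lipophilicity_solubility"
 },
 {
  "name": "SlogP_VSA8",
  "group": "lipophilicity_solubility"
 },
 {
  "name": "SlogP_VSA9",
  "group": "lipophilicity_solubility"
 },
 {
  "name": "SlogP_VSA10",
  "group": "lipophilicity_solubility"
 },
 {
  "name": "NumHDonors",
  "group": "druglikeness_surface"
 },
 {
  "name": "NumHAcceptors",
  "group": "druglikeness_surface"
 },
 {
  "name": "TPSA",
  "group": "druglikeness_surface"
 },
 {
  "name": "LabuteASA",
  "group": "druglikeness_surface"
 },
 {
  "name": "qed",
  "group": "druglikeness_surface"
 },
 {
  "name": "SMR_VSA1",
  "group": "druglikeness_surface"
 },
 {
  "name": "SMR_VSA2",
  "group": "druglikeness_surface"
 },
 {
  "name": "SMR_VSA3",
  "group": "druglikeness_surface"
 },
 {
  "name": "SMR_VSA4",
  "group": "druglikeness_surface"
 },
 {
  "name": "SMR_VSA5",
  "group": "druglikeness_surface"
 },
 {
  "name": "SMR_VSA6",
  "group": "druglikeness_surface"
 },
 {
  "name": "SMR_VSA7",
  "group": "druglikeness_surface"
 },
 {
  "name": "SMR_VSA9",
  "group": "druglikeness_surface"
 },
 {
  "name": "SMR_VSA10",
  "group": "druglikeness_surface"
 }
]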