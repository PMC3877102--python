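{
 "cutoff_A": 12.0,
 "ligand_elements": [
  "C",
  "N",
  "O",
  "F",
  "P",
  "S",
  "Cl",
  "Br",
  "I"
 ],
 "protein_elements": [
  "C",
  "N",
  "O",
  "S"
 ],
 "labels": [
  "C_C",
  "C_N",
  "C_O",
  "C_S",
  "N_C",
  "N_N",
  "N_O",
  "N_S",
  "O_C",
  "O_N",
  "O_O",
  "O_S",
  "F_C",
  "F_N",
  "F_O",
  "F_S",
  "P_C",
  "P_N",
  "P_O",
  "P_S",
  "S_C",
  "S_N",
  "S_O",
  "S_S",
  "Cl_C",
  "Cl_N",
  "Cl_O",
  "Cl_S",
  "Br_C",
  "Br_N",
  "Br_O",
  "Br_S",
  "I_C",
  "I_N",
  "I_O",
  "I_S"
 ]
}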