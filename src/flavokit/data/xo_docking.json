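{
  "description": "Reference bovine xanthine-oxidase (PDB 3NVY) docking interaction tables for blumeatin and for quercetin (the co-crystallised natural ligand), plus the nine human-XO (PDB 2E1Q) pose affinities.",
  "hbond_distances": {
    "blumeatin": [
      {"residue": "Thr1010", "distance": 2.70, "type": "C=O"},
      {"residue": "Thr1010", "distance": 3.26, "type": "O-H"},
      {"residue": "Thr1010", "distance": 2.93, "type": "C=O"},
      {"residue": "Thr1010", "distance": 2.97, "type": "O-H"},
      {"residue": "Val1011", "distance": 3.08, "type": "C=O"},
      {"residue": "Arg880", "distance": 2.03, "type": "O-H"},
      {"residue": "Phe914", "distance": 4.04, "type": "(O-H) pi-sigma"},
      {"residue": "Ala1078", "distance": 3.58, "type": "O-H"}
    ]
  },
  "residues": {
    "blumeatin": {
      "typed": ["Thr1010", "Val1011", "Arg880", "Phe914", "Phe1009", "Ala1078",
                "Ala1079", "Leu1014", "Leu873", "Leu648", "Ala910"],
      "vdw": ["Glu802", "Asn768", "Ser1008", "Glu1261", "Phe1013", "Phe1150",
              "Ser876", "Lys771", "Thr803"]
    },
    "quercetin": {
      "typed": ["Arg880", "Thr1010", "Glu802", "Phe914", "Ala1079", "Phe1009",
                "Leu873", "Leu1014", "Leu648", "Val1011"],
      "vdw": ["Ser1008", "Phe1150", "Ser876", "Phe1013", "Lys771", "Pro1076",
              "Ala1078"]
    }
  },
  "mutual_bold": ["Thr1010", "Val1011", "Arg880", "Phe914", "Phe1009",
                  "Ala1079", "Leu1014", "Leu873", "Leu648"],
  "pose_affinities": [
    {"pose": 1, "affinity": -9.6},
    {"pose": 2, "affinity": -9.4},
    {"pose": 3, "affinity": -9.2},
    {"pose": 4, "affinity": -9.2},
    {"pose": 5, "affinity": -9.0},
    {"pose": 6, "affinity": -9.0},
    {"pose": 7, "affinity": -9.0},
    {"pose": 8, "affinity": -8.8},
    {"pose": 9, "affinity": -8.7}
  ]
}
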