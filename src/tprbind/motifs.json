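{
  "comment": "Interface/motif residue sets on the reference sequences (1-based author numbering). KLC motifs are numbered on KLC2, the JIP3 motif on JIP3. Exempt positions are allowed to vary; exemptions outside the residue set apply only if present.",
  "motifs": {
    "jip3_binding_site_on_klc": {
      "reference": "KLC2",
      "residues": ["200-201", 204, 208, 213, "215-216", "219-220", 223, 227]
    },
    "trp_acidic_cargo_site_on_klc": {
      "reference": "KLC2",
      "residues": ["244-245", 248, 251, 263, 270, "283-284", "286-287", "290-291", 294, 305, 312, 325, 329, "332-333", "335-336"]
    },
    "tpr1_dimerisation_site": {
      "reference": "KLC2",
      "residues": [197, "200-201", 204, "207-208", 213, "215-216", "219-220", 223]
    },
    "lfp_motif": {
      "reference": "KLC2",
      "residues": ["167-169"]
    },
    "klc_binding_site_on_jip3": {
      "reference": "JIP3",
      "residues": ["432-434", "436-445", "448-449"],
      "exempt": ["432-433", 439, 442, "446-447"]
    }
  }
}
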