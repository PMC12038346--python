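{
  "name": "triple-network-24",
  "description": "24 cortical regions of interest (12 bilateral Brodmann-area regions) grouped into the visual, auditory, default-mode, salience and central-executive networks.",
  "networks": {
    "VN": "Visual network",
    "AN": "Auditory network",
    "DMN": "Default mode network",
    "SN": "Salience network",
    "CEN": "Central executive network"
  },
  "regions": [
    {"region": "Primary visual cortex", "brodmann": "BA17", "abbr": "V1", "network": "VN"},
    {"region": "Secondary visual cortex", "brodmann": "BA18", "abbr": "V2", "network": "VN"},
    {"region": "Primary auditory cortex", "brodmann": "BA41", "abbr": "A1", "network": "AN"},
    {"region": "Secondary auditory cortex", "brodmann": "BA42", "abbr": "A2", "network": "AN"},
    {"region": "Parahippocampal gyrus", "brodmann": "BA27", "abbr": "PHC", "network": "DMN"},
    {"region": "Posterior cingulate cortex", "brodmann": "BA23", "abbr": "PCC", "network": "DMN"},
    {"region": "Angular gyrus", "brodmann": "BA39", "abbr": "AG", "network": "DMN"},
    {"region": "Medial prefrontal cortex", "brodmann": "BA46", "abbr": "MPFC", "network": "DMN"},
    {"region": "Insula", "brodmann": "BA13", "abbr": "INS", "network": "SN"},
    {"region": "Dorsolateral anterior cingulate gyrus", "brodmann": "BA24", "abbr": "dACC", "network": "SN"},
    {"region": "Dorsolateral prefrontal cortex", "brodmann": "BA09", "abbr": "DLPFC", "network": "CEN"},
    {"region": "Posterior parietal cortex", "brodmann": "BA40", "abbr": "PPC", "network": "CEN"}
  ]
}
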