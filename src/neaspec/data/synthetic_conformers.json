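{
  "glycolaldehyde": {
    "smiles": "O=CCO",
    "comment": "Synthetic stand-in conformer set for testing: hand-constructed geometries of the hydrogen-bonded (cc) and an open (tt-like) conformer of glycolaldehyde with a force-field-like relative energy chosen to give ~0.6% minor population at 298 K. Not quantum-chemistry results.",
    "conformers": [
      {
        "label": "cc-hbond",
        "energy_kj_mol": 0.0,
        "symbols": ["C", "O", "H", "C", "H", "H", "O", "H"],
        "coords": [
          [0.0, 0.43, 0.0],
          [1.13, 0.9, 0.0],
          [-0.19, -0.64, 0.0],
          [-1.2, 1.33, 0.0],
          [-1.79, 1.14, 0.9],
          [-1.79, 1.14, -0.9],
          [-0.85, 2.7, 0.0],
          [0.11, 2.75, 0.0]
        ]
      },
      {
        "label": "open",
        "energy_kj_mol": 12.67,
        "symbols": ["C", "O", "H", "C", "H", "H", "O", "H"],
        "coords": [
          [0.0, 0.43, 0.0],
          [1.13, 0.9, 0.0],
          [-0.19, -0.64, 0.0],
          [-1.2, 1.33, 0.0],
          [-1.76, 1.15, 0.92],
          [-0.82, 2.35, -0.05],
          [-2.1, 1.2, -1.12],
          [-2.75, 1.9, -1.1]
        ]
      }
    ]
  }
}
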