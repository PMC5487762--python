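n_inhibitors: 113
n_non_inhibitors: 295
seed: 0
score_params:
  ChemScore:
    inhibitor:
    - 37.5
    - 5.0
    non-inhibitor:
    - 25.0
    - 7.0
  GoldScore:
    inhibitor:
    - 60.0
    - 10.0
    non-inhibitor:
    - 47.0
    - 11.0
  GlideXP:
    inhibitor:
    - -8.5
    - 1.5
    non-inhibitor:
    - -5.5
    - 1.8
  XScore:
    inhibitor:
    - 6.6
    - 0.55
    non-inhibitor:
    - 5.6
    - 0.65
mw_params:
  inhibitor:
  - 480.0
  - 80.0
  non-inhibitor:
  - 300.0
  - 80.0
logp_params:
  inhibitor:
  - 4.6
  - 1.5
  non-inhibitor:
  - 2.6
  - 1.5
fingerprint_bit_probs:
  inhibitor:
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  non-inhibitor:
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
  - 0.15
group_probs:
  halide:
  - 0.6
  - 0.3
  ether:
  - 0.65
  - 0.4
  carbonyl:
  - 0.8
  - 0.55
  vinyl_carbon:
  - 0.5
  - 0.25
  amide:
  - 0.6
  - 0.3
  arene:
  - 0.95
  - 0.85
  hydroxyl:
  - 0.45
  - 0.55
  carboxylic_acid:
  - 0.15
  - 0.3
interaction_probs:
  Phe334|hydrophobic:
  - 0.8
  - 0.3
  Tyr772|hydrophobic:
  - 0.8
  - 0.35
  Leu364|hydrophobic:
  - 0.7
  - 0.3
  Phe776|hydrophobic:
  - 0.65
  - 0.3
  Leu1026|hydrophobic:
  - 0.65
  - 0.3
  Tyr337|hbond_donor:
  - 0.35
  - 0.5
  Asn996|hbond_acceptor:
  - 0.3
  - 0.55
  Thr211|hbond_donor:
  - 0.25
  - 0.45
  Arg1001|ionic:
  - 0.1
  - 0.2
  Leu339|surface_contact:
  - 0.5
  - 0.4
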