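# Lipid subclass registry: chain counts, backbone elemental formulas and
# head-group product ions used when assembling reference OAD spectra.
#
# backbone: formula of the head-group/backbone scaffold before chain
#   condensation (chains contribute per their linkage; ester/amide chains are
#   added as acid minus H2O, ethers as alcohol minus H2O, sphingoid bases carry
#   their own N and hydroxyls).
# head_ions: kind "fragment" carries the ion formula (with charge) directly;
#   kind "neutral_loss" is subtracted from the precursor m/z.
aliases:
  Cer: Cer-NS
  HexCer: HexCer-NS
subclasses:
  PC:
    chains: 2
    backbone: C8H20NO6P
    linkages: [ester, ester]
    default_adduct: "[M+H]+"
    head_ions:
      - {kind: fragment, formula: "C5H15NO4P+", rel_intensity: 1.0, label: phosphocholine}
  LPC:
    chains: 1
    backbone: C8H20NO6P
    linkages: [ester]
    default_adduct: "[M+H]+"
    head_ions:
      - {kind: fragment, formula: "C5H15NO4P+", rel_intensity: 1.0, label: phosphocholine}
  PE:
    chains: 2
    backbone: C5H14NO6P
    linkages: [ester, ester]
    default_adduct: "[M+H]+"
    head_ions:
      - {kind: neutral_loss, formula: C2H8NO4P, rel_intensity: 0.5, label: phosphoethanolamine-NL}
  LPE:
    chains: 1
    backbone: C5H14NO6P
    linkages: [ester]
    default_adduct: "[M+H]+"
    head_ions:
      - {kind: neutral_loss, formula: C2H8NO4P, rel_intensity: 0.5, label: phosphoethanolamine-NL}
  PE-N(FA):
    chains: 3
    backbone: C5H14NO6P
    linkages: [amide, ester, ester]
    default_adduct: "[M+H]+"
    head_ions: []
  PS:
    chains: 2
    backbone: C6H14NO8P
    linkages: [ester, ester]
    default_adduct: "[M+H]+"
    head_ions:
      - {kind: neutral_loss, formula: C3H8NO6P, rel_intensity: 0.5, label: phosphoserine-NL}
  PG:
    chains: 2
    backbone: C6H15O8P
    linkages: [ester, ester]
    default_adduct: "[M+H]+"
    head_ions:
      - {kind: neutral_loss, formula: C3H9O6P, rel_intensity: 0.5, label: glycerophosphate-NL}
  LPG:
    chains: 1
    backbone: C6H15O8P
    linkages: [ester]
    default_adduct: "[M+H]+"
    head_ions:
      - {kind: neutral_loss, formula: C3H9O6P, rel_intensity: 0.5, label: glycerophosphate-NL}
  PI:
    chains: 2
    backbone: C9H19O11P
    linkages: [ester, ester]
    default_adduct: "[M+H]+"
    head_ions:
      - {kind: neutral_loss, formula: C6H13O9P, rel_intensity: 0.5, label: inositolphosphate-NL}
  DG:
    chains: 2
    backbone: C3H8O3
    linkages: [ester, ester]
    default_adduct: "[M+NH4]+"
    head_ions: []
  TG:
    chains: 3
    backbone: C3H8O3
    linkages: [ester, ester, ester]
    default_adduct: "[M+NH4]+"
    head_ions: []
  CAR:
    chains: 1
    backbone: C7H15NO3
    linkages: [ester]
    default_adduct: "[M+H]+"
    head_ions:
      - {kind: fragment, formula: "C4H5O2+", rel_intensity: 0.3, label: carnitine-85}
  SM:
    chains: 2
    backbone: C5H12NO3P
    linkages: [sphingoid, amide]
    default_adduct: "[M+H]+"
    head_ions:
      - {kind: fragment, formula: "C5H15NO4P+", rel_intensity: 1.0, label: phosphocholine}
  Cer-NS:
    chains: 2
    backbone: ""
    linkages: [sphingoid, amide]
    default_adduct: "[M+H]+"
    head_ions: []
  Cer-NDS:
    chains: 2
    backbone: ""
    linkages: [sphingoid, amide]
    default_adduct: "[M+H]+"
    head_ions: []
  Cer-EOS:
    chains: 3
    backbone: ""
    linkages: [sphingoid, amide_hydroxy, ester]
    default_adduct: "[M+H]+"
    head_ions: []
  HexCer-NS:
    chains: 2
    backbone: C6H10O5
    linkages: [sphingoid, amide]
    default_adduct: "[M+H]+"
    head_ions: []
  SPB:
    chains: 1
    backbone: ""
    linkages: [sphingoid]
    default_adduct: "[M+H]+"
    head_ions: []
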