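# Additive 13C / 1H chemical-shift increment scheme (fast prediction).
#
# Textbook-style scheme: a base value per carbon class plus substituent
# increments read off the topological environment.  sp3 carbons follow a
# Grant-Paul alpha/beta/gamma/delta carbon count with per-element
# corrections for heteroatoms on the same paths; olefinic carbons use
# same-side / far-side substituent counts; aromatic-ring carbons use
# ipso/ortho/meta/para substituent increments plus aza (ring nitrogen)
# corrections; carbonyl carbons are classified by their heteroatom
# neighbours.  All values are ppm.
c13:
  sp3:
    base: -2.3
    alpha: {C: 9.1, N: 28.3, O: 48.0, S: 20.0, F: 68.0, Cl: 31.0, Br: 20.0, I: -6.0, P: 11.0, B: 6.0, Si: -6.0}
    beta:  {C: 9.4, N: 11.3, O: 10.1, S: 7.0, F: 9.0, Cl: 10.0, Br: 10.0, I: 11.0, P: 6.0, B: 4.0, Si: 3.0}
    gamma: {C: -2.5, N: -5.1, O: -6.2, S: -3.0, F: -4.0, Cl: -4.6, Br: -3.1, I: -1.0, P: -2.0, B: -1.0, Si: -1.0}
    delta: {C: 0.3, N: 0.0, O: 0.0, S: 0.0, F: 0.0, Cl: 0.0, Br: 0.0, I: 0.0, P: 0.0, B: 0.0, Si: 0.0}
  alkene:
    base: 123.3
    same_side_c: 10.6    # per heavy substituent on this carbon
    far_side_c: -7.9     # per heavy substituent on the double-bond partner
    same_side_o: 29.0
    far_side_o: -39.0
    same_side_n: 17.0
    far_side_n: -28.0
  aromatic:
    base: 128.5
    # substituent-type -> [ipso, ortho, meta, para] increments
    alkyl:    [9.3, 0.7, -0.1, -2.9]
    vinyl:    [7.6, -1.8, -1.8, -3.5]
    oxy:      [31.4, -14.4, 1.0, -7.7]
    amino:    [19.2, -12.4, 1.3, -9.5]
    carbonyl: [2.1, 1.2, 0.0, 4.4]
    halogen:  [6.2, 0.4, 1.3, -1.9]
    # ring nitrogen at topological distance 1..3 (pyridine-like)
    aza:      [21.4, -4.7, 7.5]
  alkyne:
    base: 71.9
    alpha_c: 7.0
    far_c: -1.0
  nitrile: {base: 117.7}
  imine: {base: 155.0}
  carbonyl:
    ester: 170.0      # C(=O) with a single-bonded O neighbour
    amide: 168.5      # C(=O) with an N neighbour
    aldehyde: 200.0   # C(=O)H
    ketone: 205.0
    extra_conjugation: -7.0   # attached to sp2/sp carbon
h1:
  aromatic_ch: 7.26
  aromatic_aza_alpha: 1.3    # added per ring N adjacent to the carbon
  alkene_ch: 5.40
  alkyne_ch: 2.05
  aldehyde_ch: 9.70
  sp3_base: {CH3: 0.90, CH2: 1.25, CH: 1.50}
  sp3_alpha: {O: 2.45, N: 1.55, aryl: 1.40, carbonyl: 1.15, halogen: 1.9}
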