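# Atom Property Correlation Table: carbon shift ranges -> atom properties.
#
# Each rule matches carbons whose 13C shift lies in [lo, hi) ppm (and whose
# multiplicity is listed, when a filter is given).  Matching rules are
# intersected: the hybridization sets are intersected and the first
# hetero verdict wins.  The table is deliberately conservative - a rule
# never excludes a hybridization or hetero environment that a real carbon
# in its window could have - so pruning with it is sound.
#
# hetero: fb = bonding to a heteroatom forbidden, ob = obligatory,
# omitted = not defined.
rules:
  # saturated carbons without hetero neighbours: alkyl CH3/CH2/CH up to ~25 ppm
  - {lo: 0.0,   hi: 25.0,  multiplicity: [CH3],      hybridization: [sp3], hetero: fb}
  - {lo: 0.0,   hi: 25.0,  multiplicity: [CH2],      hybridization: [sp3], hetero: fb}
  - {lo: 0.0,   hi: 25.0,  multiplicity: [CH],       hybridization: [sp3], hetero: fb}
  - {lo: 0.0,   hi: 25.0,  multiplicity: [C],        hybridization: [sp3], hetero: fb}
  - {lo: 0.0,   hi: 25.0,  multiplicity: [undefined], hybridization: [sp3], hetero: fb}
  # saturated carbons, hetero neighbour possible (N-CH3 ~30-45, branch points)
  - {lo: 25.0,  hi: 58.0,  hybridization: [sp3]}
  # O-CH window overlaps internal/terminal alkynes: sp3 or sp
  - {lo: 58.0,  hi: 90.0,  hybridization: [sp3, sp]}
  # anomeric / O2CH sp3 carbons overlap early olefinics: "not sp"
  - {lo: 90.0,  hi: 115.0, hybridization: [sp3, sp2]}
  # olefinic and aromatic carbons
  - {lo: 115.0, hi: 145.0, hybridization: [sp2]}
  - {lo: 145.0, hi: 166.0, hybridization: [sp2]}
  # carboxyl/ester/amide carbons and, above ~185, ketones/aldehydes: the
  # sp2 carbon is bonded to at least one heteroatom throughout
  - {lo: 166.0, hi: 185.0, hybridization: [sp2], hetero: ob}
  - {lo: 185.0, hi: 230.0, hybridization: [sp2], hetero: ob}
  # exotic far-downfield signals: leave everything open
  - {lo: 230.0, hi: 240.0, hybridization: [sp3, sp2, sp]}
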