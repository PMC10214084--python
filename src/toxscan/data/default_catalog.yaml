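# Default okadaic-acid binding-site catalog, anchored to human PP1 numbering.
#
# Each site row: catalog index (1-10), position in the ungapped reference
# sequence (1-based), expected reference residue (numbering guard), and the
# name of the acceptance class evaluated at that site.
reference_id: PP1_HUMAN
loop_region: [268, 280]

sites:
  - {index: 1, position: 96, residue: R, class: site1}
  - {index: 2, position: 130, residue: I, class: site2}
  - {index: 3, position: 134, residue: Y, class: site3}
  - {index: 4, position: 206, residue: W, class: site4}
  - {index: 5, position: 221, residue: R, class: site5}
  - {index: 6, position: 250, residue: V, class: site6}
  - {index: 7, position: 272, residue: Y, class: site7}
  - {index: 8, position: 273, residue: C, class: site8}
  - {index: 9, position: 275, residue: E, class: site9}
  - {index: 10, position: 276, residue: F, class: site10}

# Residue sets. The hydrophobic set deliberately excludes G and Y; the
# polar-or-charged set excludes C and W.  Sites 1-5 and 7 are permissive
# (near-universally conserved); sites 6, 8, 9, 10 are the consensus sites
# that drive the sensitivity call.
classes:
  site1: R
  site2: ILMVC
  site3: YF
  site4: W
  site5: R
  site6: CAVLIMFW      # C or hydrophobic
  site7: Y
  site8: C             # C only
  site9: STNQYDEKRH    # polar or charged
  site10: CAVLIMFW     # C or hydrophobic

consensus_sites: [6, 8, 9, 10]

# Four-level decision table (ordered worst -> best:
# GrosslyInsensitive < Insensitive < ModeratelySensitive < Sensitive).
decision:
  gross_min_violations: 3
  gross_insert_min_length: 6
  gross_insert_intervals: [5, 6, 7]   # inter-site intervals between sites 5 and 8
  insensitive_sites: [8, 10]
  insensitive_residues: FWYDEKRH      # aromatic or charged
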