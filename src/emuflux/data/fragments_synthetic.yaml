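# Synthetic-default fragment library for the bundled TOY networks.
#
# These are NOT real GC-MS amino-acid fragments: the precursor metabolites
# belong to the synthetic preset networks, and the derivatization formulas
# are illustrative TBDMS-style element counts chosen so that the
# natural-abundance correction has realistic structure.  Replace this file
# with a measured fragment library when analyzing real data.
#
# Schema:
#   <fragment id>:
#     amino_acid: <label>
#     precursors: [{metabolite: <id>, positions: [<1-based carbons>]}]
#     formula: {<element>: <count of non-backbone atoms>}

frag_A:
  amino_acid: synthetic
  precursors:
    - {metabolite: A, positions: [1, 2, 3]}
  formula: {C: 8, H: 26, N: 1, O: 2, Si: 2}

frag_B:
  amino_acid: synthetic
  precursors:
    - {metabolite: B, positions: [1, 2, 3]}
  formula: {C: 8, H: 26, N: 1, O: 2, Si: 2}

frag_B23:
  amino_acid: synthetic
  precursors:
    - {metabolite: B, positions: [2, 3]}
  formula: {C: 7, H: 24, N: 1, O: 1, Si: 2}

frag_C:
  amino_acid: synthetic
  precursors:
    - {metabolite: C, positions: [1, 2]}
  formula: {C: 7, H: 24, N: 1, O: 1, Si: 2}

frag_D:
  amino_acid: synthetic
  precursors:
    - {metabolite: D, positions: [1, 2, 3, 4]}
  formula: {C: 9, H: 28, N: 1, O: 3, Si: 2}
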