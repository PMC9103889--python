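# Probe presets: template coordinates (Å), the atoms used for structural
# alignment, and the symmetry-equivalent orderings of those atoms.
# Alignment uses all carbons for benzamidine and all heavy atoms for
# catechol and benzene; "vprobe" is a small C2v test probe used by the
# synthetic generator.

benzene:
  resname: BNZ
  atoms:
    C1: [1.3960, 0.0000, 0.0000]
    C2: [0.6980, 1.2090, 0.0000]
    C3: [-0.6980, 1.2090, 0.0000]
    C4: [-1.3960, 0.0000, 0.0000]
    C5: [-0.6980, -1.2090, 0.0000]
    C6: [0.6980, -1.2090, 0.0000]
  alignment_atoms: [C1, C2, C3, C4, C5, C6]
  symmetry_mappings:
    - [C1, C2, C3, C4, C5, C6]
    - [C2, C3, C4, C5, C6, C1]
    - [C3, C4, C5, C6, C1, C2]
    - [C4, C5, C6, C1, C2, C3]
    - [C5, C6, C1, C2, C3, C4]
    - [C6, C1, C2, C3, C4, C5]
    - [C1, C6, C5, C4, C3, C2]
    - [C2, C1, C6, C5, C4, C3]
    - [C3, C2, C1, C6, C5, C4]
    - [C4, C3, C2, C1, C6, C5]
    - [C5, C4, C3, C2, C1, C6]
    - [C6, C5, C4, C3, C2, C1]

catechol:
  resname: CTL
  atoms:
    C1: [1.3960, 0.0000, 0.0000]
    C2: [0.6980, 1.2090, 0.0000]
    C3: [-0.6980, 1.2090, 0.0000]
    C4: [-1.3960, 0.0000, 0.0000]
    C5: [-0.6980, -1.2090, 0.0000]
    C6: [0.6980, -1.2090, 0.0000]
    O1: [2.7560, 0.0000, 0.0000]
    O2: [1.3780, 2.3868, 0.0000]
  alignment_atoms: [C1, C2, C3, C4, C5, C6, O1, O2]
  symmetry_mappings:
    - [C1, C2, C3, C4, C5, C6, O1, O2]
    - [C2, C1, C6, C5, C4, C3, O2, O1]

benzamidine:
  resname: BEN
  atoms:
    C1: [1.3960, 0.0000, 0.0000]
    C2: [0.6980, 1.2090, 0.0000]
    C3: [-0.6980, 1.2090, 0.0000]
    C4: [-1.3960, 0.0000, 0.0000]
    C5: [-0.6980, -1.2090, 0.0000]
    C6: [0.6980, -1.2090, 0.0000]
    C7: [2.8860, 0.0000, 0.0000]
    N1: [3.5560, 1.1200, 0.0000]
    N2: [3.5560, -1.1200, 0.0000]
  alignment_atoms: [C1, C2, C3, C4, C5, C6, C7]
  symmetry_mappings:
    - [C1, C2, C3, C4, C5, C6, C7]
    - [C1, C6, C5, C4, C3, C2, C7]

# C2v three-heavy-atom probe for synthetic/planted-truth work; the twofold
# axis passes through C1 along z.
vprobe:
  resname: PRB
  atoms:
    C1: [0.0000, 0.0000, 0.8000]
    O1: [-1.1000, 0.0000, -0.4000]
    O2: [1.1000, 0.0000, -0.4000]
  alignment_atoms: [C1, O1, O2]
  symmetry_mappings:
    - [C1, O1, O2]
    - [C1, O2, O1]
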