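# Residue-type scheme: five categories over the 19 Cβ-bearing amino acids.
# Glycine carries no Cβ atom and is excluded from typing.
acidic: [ASP, GLU]
basic: [ARG, HIS, LYS]
hydrophilic: [ASN, CYS, GLN, SER, THR]
hydrophobic: [ALA, ILE, LEU, MET, PRO, VAL]
aromatic: [PHE, TRP, TYR]
excluded: [GLY]
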