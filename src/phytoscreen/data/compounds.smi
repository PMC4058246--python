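# Named structures for the screening worked example and the descriptor oracles.
# Format: SMILES<space>name. Lines starting with '#' are comments.
#
# 5-hydroxy-L-tryptophan and abrine are canonical literature structures
# (C11H12N2O3 and C12H14N2O2). The saussureamine A-C and T2384 entries are
# best-effort reconstructions: saussureamines drawn as dehydrocostus-lactone
# amino-acid Michael adducts (proline/alanine/methionine), T2384 as a
# sulfonamide-bearing oxazole acid; no authoritative machine-readable
# structures are available for these four, and no quantitative result in this
# package depends on them beyond drug-likeness passage and injected scores.
C1=CC2=C(C=C1O)C(=CN2)C[C@@H](C(=O)O)N 5-hydroxy-L-tryptophan
CN[C@@H](CC1=CNC2=CC=CC=C21)C(=O)O abrine
C=C1CCC2C(=C)CCC3C(C12)OC(=O)C3CN4CCCC4C(=O)O saussureamine A
C=C1CCC2C(=C)CCC3C(C12)OC(=O)C3CNC(C)C(=O)O saussureamine B
C=C1CCC2C(=C)CCC3C(C12)OC(=O)C3CNC(CCSC)C(=O)O saussureamine C
CC1=C(COc2cccc(CN(CC(=O)O)S(C)(=O)=O)c2)N=C(c3ccccc3)O1 T2384
# descriptor-oracle molecules
CC ethane
CCC propane
CCCC n-butane
CCCCC n-pentane
CCCCCC n-hexane
c1ccccc1 benzene
c1ccncc1 pyridine
c1ccc2[nH]ccc2c1 indole
CCO ethanol
CC(C)C isobutane
NC(C(=O)O)C alanine
NCC(=O)O glycine
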