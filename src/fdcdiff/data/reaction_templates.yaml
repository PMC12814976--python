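# Reaction-based slicing templates (SMIRKS).
#
# Each entry cleaves exactly one acyclic bond — the bond between the atoms
# carrying map numbers :1 and :2 on the reactant side — so that every cut
# corresponds to a feasible synthetic disconnection.  This is a 10-template
# starter subset of the common experimentally verified transformations used
# for scaffold/R-group slicing; users can extend the file with their own
# entries (id, smirks, description).
templates:
  - id: amide
    smirks: "[C:1](=[O])-!@[N;X3:2]>>[C:1](=[O]).[N:2]"
    description: amide C-N disconnection (acylation)
  - id: ester
    smirks: "[C:1](=[O])-!@[O;X2:2]>>[C:1](=[O]).[O:2]"
    description: ester C-O disconnection (esterification)
  - id: aromatic_ether
    smirks: "[c:1]-!@[O;X2:2]>>[c:1].[O:2]"
    description: aryl ether C-O disconnection (O-arylation)
  - id: alkyl_ether
    smirks: "[C;X4;!$(C=O):1]-!@[O;X2;!$(O[C]=O):2]>>[C:1].[O:2]"
    description: alkyl ether C-O disconnection (Williamson)
  - id: sulfonamide
    smirks: "[S:1](=[O])(=[O])-!@[N;X3:2]>>[S:1](=[O])(=[O]).[N:2]"
    description: sulfonamide S-N disconnection
  - id: aromatic_amine
    smirks: "[c:1]-!@[N;X3;!$(N=*):2]>>[c:1].[N:2]"
    description: aryl amine C-N disconnection (Buchwald-Hartwig)
  - id: alkyl_amine
    smirks: "[C;X4:1]-!@[N;X3;!$(N[C]=O):2]>>[C:1].[N:2]"
    description: alkyl amine C-N disconnection (reductive amination)
  - id: biaryl
    smirks: "[c:1]-!@[c:2]>>[c:1].[c:2]"
    description: biaryl C-C disconnection (Suzuki coupling)
  - id: benzyl
    smirks: "[c:1]-!@[C;X4:2]>>[c:1].[C:2]"
    description: aryl-alkyl C-C disconnection
  - id: thioether
    smirks: "[C:1]-!@[S;X2;!$(S=O):2]>>[C:1].[S:2]"
    description: thioether C-S disconnection
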