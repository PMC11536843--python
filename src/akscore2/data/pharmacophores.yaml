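# Pharmacophore atom typing, SMARTS-based. Seven categories; an atom may
# carry several (multi-hot). Versioned so featurization is reproducible.
version: 1
categories:
  aromatic:
    - "[a]"
  ring:
    - "[R]"
  hydrophobic:
    - "[c]"
    - "[C;!$(C~[O,N,S,P])]"
    - "[S;X2;H0]"
    - "[F,Cl,Br,I]"
  donor:
    - "[N;!H0]"
    - "[O;!H0]"
    - "[S;!H0]"
  acceptor:
    - "[O]"
    - "[n;X2]"
    - "[N;X2;!$([N+])]"
    - "[N;X1]"
  acidic:
    - "[O;$(O[C,S,P]=O);H1,-]"
    - "[O;X1;$(O=[C,S,P][O;H1,-])]"
  basic:
    - "[N;X3;!$(N~[O,S])!$(N-C=[O,N,S]);!$(N-a);!a]"
    - "[N;X2;$(N=C-N);!$(N~[O,S])]"
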