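# Default screening exclusion patterns: reactive or otherwise undesirable
# moieties removed after the top-K selection. One SMARTS per line; lines
# starting with '#' are comments. Edit freely — the list is a configurable
# stand-in for any in-house exclusion set.
[N+](=O)[O-]                  nitro
C(=O)Cl                       acyl_chloride
C(=O)Br                       acyl_bromide
S(=O)(=O)Cl                   sulfonyl_chloride
[CX4][Cl,Br,I]                alkyl_halide
C1OC1                         epoxide
C1NC1                         aziridine
N=[N+]=[N-]                   azide
OO                            peroxide
[N;!R]=[N;!R]                 acyclic_azo
C=C[CX3](=O)[!N]              michael_acceptor_enone
N=C=O                         isocyanate
N=C=S                         isothiocyanate
[CX3](=O)[CX3](=O)            1,2-dicarbonyl
[SX2][SX2]                    disulfide
C(=O)OC(=O)                   anhydride
[CH1]=O                       aldehyde
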