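# Default domain map for the tapasin-MHC I (HLA-B*44:02) system.
# Chains: A = MHC I heavy chain, B = beta-2 microglobulin, C = antigenic
# peptide (Ag), T = tapasin.
#
# The MHC I alpha1/alpha2/alpha3 boundaries below are the canonical class I
# domain boundaries and are APPROXIMATE — override them for quantitative
# per-domain work. The tapasin TN/TC split at residue 270 follows the
# crystal-structure domain definition (TC = residues 270-381).
selections:
  alpha1: [{chain: A, first: 1,   last: 90}]
  alpha2: [{chain: A, first: 91,  last: 182}]
  alpha3: [{chain: A, first: 183, last: 276}]
  alpha1alpha2: [{chain: A, first: 1, last: 182}]
  b2m:    [{chain: B, first: 1,   last: 99}]
  Ag:     [{chain: C, first: 1,   last: 9}]
  TN:     [{chain: T, first: 1,   last: 269}]
  TC:     [{chain: T, first: 270, last: 381}]
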