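PROT0001
PROT0002
PROT0003
PROT0004
PROT0005
PROT0006
PROT0007
PROT0008
PROT0009
PROT0010
PROT0011
PROT0012
PROT0013
PROT0014
PROT0015
PROT0016
PROT0017
PROT0018
PROT0019
PROT0020
PROT0021
PROT0022
PROT0023
PROT0024
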