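# United-atom 12-6 Lennard-Jones parameters.
#   TYPE  EPSILON(kcal/mol)  RMIN_HALF(Angstrom)
# Values follow common AMBER-family united/all-atom conventions; the file is
# editable and none of the package's correctness tests depend on these numbers.
C.ar   0.0860  1.9080   # aromatic carbon
C.3    0.1094  1.9080   # sp3 carbon
C.2    0.0860  1.9080   # sp2 carbon
N.ar   0.1700  1.8240   # aromatic nitrogen
N.3    0.1700  1.8240
O.2    0.2100  1.6612   # carbonyl oxygen
O.3    0.2104  1.7210   # ether/hydroxyl oxygen
S.3    0.2500  2.0000
F      0.0610  1.7500
Cl     0.2650  1.9480
Br     0.3200  2.2200
P.3    0.2000  2.1000
H      0.0157  0.6000   # polar hydrogen; nonpolar H folded into carbons

# element fallbacks used when a pose carries no explicit atom types
default  C   C.ar
default  N   N.ar
default  O   O.2
default  S   S.3
default  F   F
default  Cl  Cl
default  Br  Br
default  P   P.3
default  H   H
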