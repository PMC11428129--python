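# Physical constants (CODATA 2018) used by rpsb2pa
# name                 value                  unit
alpha                  7.2973525693e-03   dimensionless (fine-structure constant)
a0                     5.2917721090e-09   cm (Bohr radius)
c                      2.9979245800e+10   cm/s (speed of light)
hartree                27.211386245988   eV
au_dipole              2.5417464731   Debye per atomic unit
GM                     1.0e-50   cm^4 s / photon
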