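# Published glycan-related genes on each side of the integration:
# 'network' = glycan-transfer genes found in the screened network signature
# (heparan-sulfate genes EXT1/HS6ST2 are excluded from the enzyme union);
# 'glycan' = glycosyltransferases backing the 16-lectin glycan signature.
gene	side
ST6GAL1	network
B3GNT3	network
GCNT2	network
ST6GAL1	glycan
ST3GAL1	glycan
FUT2	glycan
GALNT6	glycan
GALNT8	glycan
GALNT10	glycan
GALNT12	glycan
GALNT14	glycan
GALNTL2	glycan
B3GALT5	glycan
B3GALT1	glycan
B3GNT2	glycan
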