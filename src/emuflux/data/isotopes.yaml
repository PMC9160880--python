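# Natural isotope abundances as mass-shift distributions (M+0, M+1, ...).
# Standard IUPAC terrestrial values; edit to match your calibration.
C: [0.9893, 0.0107]
H: [0.999885, 0.000115]
N: [0.99636, 0.00364]
O: [0.99757, 0.00038, 0.00205]
Si: [0.92223, 0.04685, 0.03092]
S: [0.9499, 0.0075, 0.0425, 0.0, 0.0001]
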