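# Codon usage table for Escherichia coli K-12 (synthetic reference,
# per-mille frequencies typed from standard published usage values).
# Codon AA Fraction Frequency Number
AAA K 0.765  33.6   33600
AAC N 0.551  21.7   21700
AAG K 0.235  10.3   10300
AAT N 0.449  17.7   17700
ACA T 0.132   7.1    7100
ACC T 0.434  23.4   23400
ACG T 0.267  14.4   14400
ACT T 0.167   9.0    9000
AGA R 0.038   2.1    2100
AGC S 0.277  16.1   16100
AGG R 0.022   1.2    1200
AGT S 0.151   8.8    8800
ATA I 0.074   4.4    4400
ATC I 0.420  25.1   25100
ATG M 1.000  27.9   27900
ATT I 0.507  30.3   30300
CAA Q 0.347  15.3   15300
CAC H 0.429   9.7    9700
CAG Q 0.653  28.8   28800
CAT H 0.571  12.9   12900
CCA P 0.190   8.4    8400
CCC P 0.125   5.5    5500
CCG P 0.526  23.2   23200
CCT P 0.159   7.0    7000
CGA R 0.065   3.6    3600
CGC R 0.399  22.0   22000
CGG R 0.098   5.4    5400
CGT R 0.379  20.9   20900
CTA L 0.037   3.9    3900
CTC L 0.104  11.0   11000
CTG L 0.496  52.6   52600
CTT L 0.104  11.0   11000
GAA E 0.689  39.4   39400
GAC D 0.373  19.1   19100
GAG E 0.311  17.8   17800
GAT D 0.627  32.1   32100
GCA A 0.213  20.1   20100
GCC A 0.270  25.5   25500
GCG A 0.356  33.6   33600
GCT A 0.162  15.3   15300
GGA G 0.109   8.0    8000
GGC G 0.403  29.6   29600
GGG G 0.151  11.1   11100
GGT G 0.337  24.7   24700
GTA V 0.154  10.9   10900
GTC V 0.216  15.3   15300
GTG V 0.372  26.4   26400
GTT V 0.258  18.3   18300
TAA * 0.645   2.0    2000
TAC Y 0.430  12.2   12200
TAG * 0.065   0.2     200
TAT Y 0.570  16.2   16200
TCA S 0.124   7.2    7200
TCC S 0.148   8.6    8600
TCG S 0.153   8.9    8900
TCT S 0.146   8.5    8500
TGA * 0.290   0.9     900
TGC C 0.552   6.4    6400
TGG W 1.000  15.2   15200
TGT C 0.448   5.2    5200
TTA L 0.131  13.9   13900
TTC F 0.428  16.6   16600
TTG L 0.129  13.7   13700
TTT F 0.572  22.2   22200
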