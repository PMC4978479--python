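# Preset set3: Miscanthus sinensis-like karyotype.
#
# 19 chromosome pairs, sizes 87-244 Mbp, condensed lengths 1.4-3.9 um.
# As for set2, only ranges are published; sizes and condensed lengths are
# interpolated uniformly across chromosomes and all pairs are treated as
# metacentric. Total model size: 6290 beads.

chr_pair: 19

l_arm_c:
  - [3, 4]
  - [3, 4]
  - [3, 3]
  - [3, 3]
  - [3, 3]
  - [2, 3]
  - [2, 3]
  - [2, 3]
  - [2, 3]
  - [2, 2]
  - [2, 2]
  - [2, 2]
  - [1, 2]
  - [1, 2]
  - [1, 2]
  - [1, 2]
  - [1, 1]
  - [1, 1]
  - [1, 1]

l_arm_d:
  - [121, 122]
  - [117, 117]
  - [113, 113]
  - [108, 109]
  - [104, 104]
  - [99, 100]
  - [95, 96]
  - [91, 91]
  - [86, 87]
  - [82, 83]
  - [78, 78]
  - [73, 74]
  - [69, 69]
  - [65, 65]
  - [60, 61]
  - [56, 56]
  - [51, 52]
  - [47, 48]
  - [43, 43]

min_rad_nu: 9000.0
max_rad_nu: 11000.0
min_vol_no: 0.02
max_vol_no: 0.06
rad_bead: 250.0
eps_1: 25.0
eps_2: 50.0
multi: 1
restart_after: 500000
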