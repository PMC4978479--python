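# Preset set2: human-like karyotype.
#
# 23 chromosome pairs, sizes 57-249 Mbp, condensed lengths 1.5-10.9 um.
# Only the ranges are published for this benchmark set, so per-chromosome
# sizes and condensed lengths are interpolated uniformly from the largest
# (249 Mbp, 10.9 um) to the smallest (57 Mbp, 1.5 um) chromosome, and all
# chromosomes are treated as metacentric (50:50 arm split, odd remainders
# to the bottom arm). Condensed chains = round(length / 0.5 um), min 3
# beads. Total model size: 7038 beads.
#
# Nucleus radius set for a ~20 um fibroblast-like nucleus so the bead
# volume fraction stays comparable to set1.

chr_pair: 23

l_arm_c:
  - [10, 11]
  - [10, 10]
  - [9, 10]
  - [9, 9]
  - [8, 9]
  - [8, 9]
  - [8, 8]
  - [7, 8]
  - [7, 7]
  - [6, 7]
  - [6, 6]
  - [5, 6]
  - [5, 6]
  - [5, 5]
  - [4, 5]
  - [4, 4]
  - [3, 4]
  - [3, 3]
  - [2, 3]
  - [2, 3]
  - [2, 2]
  - [1, 2]
  - [1, 1]

l_arm_d:
  - [124, 124]
  - [119, 120]
  - [115, 116]
  - [111, 111]
  - [106, 107]
  - [102, 102]
  - [98, 98]
  - [93, 94]
  - [89, 89]
  - [84, 85]
  - [80, 81]
  - [76, 76]
  - [71, 72]
  - [67, 68]
  - [63, 63]
  - [58, 59]
  - [54, 54]
  - [50, 50]
  - [45, 46]
  - [41, 41]
  - [36, 37]
  - [32, 33]
  - [28, 28]

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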