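# Preset set1: Brachypodium distachyon karyotype.
#
# Five chromosome pairs, Bd1..Bd5. Decondensed totals per chromosome equal
# the DNA contents 75, 59, 60, 48, 28 Mbp (one bead per 1 Mbp domain,
# centromere bead included). Condensed chain lengths follow the 3.5-7.0 um
# metaphase lengths at 500 nm bead diameter: Bd1 = 14 beads, Bd5 = 7 beads;
# Bd2-Bd4 lengths are not tabulated anywhere, so they are interpolated
# linearly in Mbp content between those endpoints (12, 12, 10 beads).
#
# Arm splits are an ASSUMPTION (no published arm-resolved lengths):
# metacentric Bd1-Bd3 split 50:50 (odd remainders favour the bottom arm),
# acrocentric Bd4-Bd5 split 25:75. Edit freely.
#
# Arm lengths below exclude the centromere bead (chain total = top + bottom + 1).
#
# Nucleus radius and nucleolus volume fraction are set to typical root
# meristem values (7.5-8.5 um nuclear diameter, nucleolus 2-6 % of nuclear
# volume); adjust to your own measurements.

chr_pair: 5

# (top, bottom) condensed arm lengths, beads    chain totals: 14 12 12 10 7
l_arm_c:
  - [6, 7]     # Bd1, metacentric
  - [5, 6]     # Bd2, metacentric
  - [5, 6]     # Bd3, metacentric
  - [2, 7]     # Bd4, acrocentric
  - [1, 5]     # Bd5, acrocentric

# (top, bottom) decondensed arm lengths, 1 Mbp domains    totals: 75 59 60 48 28
l_arm_d:
  - [37, 37]   # Bd1
  - [29, 29]   # Bd2
  - [29, 30]   # Bd3
  - [11, 36]   # Bd4
  - [6, 21]    # Bd5

min_rad_nu: 3750.0     # nm
max_rad_nu: 4250.0     # nm
min_vol_no: 0.02       # fraction of nucleus volume
max_vol_no: 0.06
rad_bead: 250.0        # nm (500 nm domain diameter)
eps_1: 25.0            # nm
eps_2: 50.0            # nm
multi: 1
restart_after: 500000
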