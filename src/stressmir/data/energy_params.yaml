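# Energy parameter table for the simplified nearest-neighbour folding model.
# All values in kcal/mol. Stacking energies are keyed "<outer pair>/<inner pair>"
# where a pair "XY" means X at the 5' position i and Y at its partner j, and the
# inner pair sits at (i+1, j-1). The table is symmetric in pair strength and is
# deliberately coarser than the full Turner 2004 set: the hairpin gate consumed
# downstream only uses MFE per nucleotide.
stack:
  GC/GC: -3.15
  GC/CG: -3.15
  CG/GC: -3.15
  CG/CG: -3.15
  GC/AU: -2.25
  GC/UA: -2.25
  CG/AU: -2.25
  CG/UA: -2.25
  AU/GC: -2.25
  AU/CG: -2.25
  UA/GC: -2.25
  UA/CG: -2.25
  GC/GU: -2.10
  GC/UG: -2.10
  CG/GU: -2.10
  CG/UG: -2.10
  GU/GC: -2.10
  GU/CG: -2.10
  UG/GC: -2.10
  UG/CG: -2.10
  AU/AU: -1.35
  AU/UA: -1.35
  UA/AU: -1.35
  UA/UA: -1.35
  AU/GU: -1.20
  AU/UG: -1.20
  UA/GU: -1.20
  UA/UG: -1.20
  GU/AU: -1.20
  GU/UA: -1.20
  UG/AU: -1.20
  UG/UA: -1.20
  GU/GU: -1.05
  GU/UG: -1.05
  UG/GU: -1.05
  UG/UG: -1.05
# Hairpin loop of u unpaired bases (u >= 3): hairpin_init + hairpin_slope * ln(u / 3)
hairpin_init: 5.0
hairpin_slope: 1.75
min_hairpin_loop: 3
# Bulge / internal loop of u unpaired bases (u >= 1): internal_init + internal_slope * ln(u)
internal_init: 3.0
internal_slope: 1.1
max_interior_loop: 30
# Multibranch loop: multi_init + multi_branch * (number of helices including the
# closing pair) + multi_unpaired * (number of unpaired bases in the loop)
multi_init: 4.6
multi_branch: 0.4
multi_unpaired: 0.1
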