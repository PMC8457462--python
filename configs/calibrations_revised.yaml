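# Revised fossil/geology calibration strategy: Oligocene Calosoma fossil,
# ~99 Ma Harpalinae amber fossil at the root, Gondwanan (Australia-
# Antarctica/South America) split for Pamborini-Ceroglossini, Canary hotspot
# maxima, with a 163.5 Ma Carabidae fossil ceiling on the log-normal priors.
# Taxon sets are placeholders; `taxa: all` marks the tree root.
seed: 1
calibrations:
  - name: C1
    taxa: [nesaeocarabus_coarctatus, nesaeocarabus_abbreviatus]
    kind: lognormal_realmean
    params: {mu_real: 16.7, sigma_log: 0.82}   # emergence of Tenerife, 11.9 Ma mode
    group: C
  - name: C2
    taxa: [nesaeocarabus_coarctatus, nesaeocarabus_abbreviatus, eurycarabus_genei]
    kind: uniform
    params: {lower: 0.0, upper: 60.0}   # age of the Canary hotspot
    group: C
  - name: F1
    taxa: [tachypus_cancellatus, tachypus_sp]
    kind: lognormal_realmean
    params: {mu_real: 25.0, sigma_log: 1.5}    # Messinian fossil, Cantal
    offset: 5.0
    hard_max: 163.5
    group: F
  - name: F2
    taxa: [calosoma_sp1, calosoma_sp2]
    placement: stem   # minimum age for stem Calosoma (Calosoma-Carabus split)
    kind: uniform
    params: {lower: 23.0, upper: 160.0}   # upper Oligocene Calosoma fossil
    group: F
  - name: GO
    taxa: [pamborus_sp, maoripamborus_sp, ceroglossus_sp]
    kind: lognormal_realmean
    params: {mu_real: 78.0, sigma_log: 0.42}   # split of Australia
    hard_max: 163.5
    group: GO
  - name: J1
    taxa: [damaster_sp1, damaster_sp2]
    kind: uniform
    params: {lower: 0.0, upper: 15.0}   # marked relief emergence in Japan
    group: J
  - name: J2
    taxa: [leptocarabus_sp1, leptocarabus_sp2]
    kind: uniform
    params: {lower: 0.0, upper: 15.0}
    group: J
  - name: J3
    taxa: [ohomopterus_sp1, ohomopterus_sp2]
    kind: uniform
    params: {lower: 0.0, upper: 15.0}
    group: J
  - name: M2
    taxa: [eurycarabus_genei, eurycarabus_famini]
    kind: uniform
    params: {lower: 5.5, upper: 15.0}   # North African surface uplift
    group: M
  - name: M3
    taxa: [rhabdotocarabus_melancholicus_a, rhabdotocarabus_melancholicus_b]
    kind: uniform
    params: {lower: 5.5, upper: 15.0}
    group: M
  - name: RO
    taxa: all
    kind: lognormal_realmean
    params: {mu_real: 130.0, sigma_log: 4.25}  # Harpalinae in Burmese amber, ~99 Ma
    offset: 98.17
    hard_max: 163.5
    group: RO
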