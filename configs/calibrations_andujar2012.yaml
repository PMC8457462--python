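# Calibration scheme of the original Andujar et al. (2012) nd5 dating study.
# Taxon sets are placeholders standing for the clades named in each row; only
# the densities matter for `carabclock prior-report`.
seed: 1
calibrations:
  - name: C
    taxa: [nesaeocarabus_coarctatus, nesaeocarabus_abbreviatus]
    kind: uniform
    params: {lower: 0.0, upper: 14.5}   # emergence of Gran Canaria
    group: C
  - name: F
    taxa: [tachypus_cancellatus, tachypus_sp]
    kind: lognormal_realmean
    params: {mu_real: 25.0, sigma_log: 1.5}   # Messinian fossil, Cantal
    offset: 5.0
    group: F
  - name: J1
    taxa: [damaster_sp1, damaster_sp2]
    kind: truncated_normal
    params: {mu: 3.5, sigma: 1.0, a: 0.1, b: 1000.0}  # final disconnection of Japan
    group: J
  - name: J2
    taxa: [leptocarabus_sp1, leptocarabus_sp2]
    kind: truncated_normal
    params: {mu: 3.5, sigma: 1.0, a: 0.1, b: 1000.0}
    group: J
  - name: J3
    taxa: [ohomopterus_sp1, ohomopterus_sp2]
    kind: truncated_normal
    params: {mu: 3.5, sigma: 1.0, a: 0.1, b: 1000.0}
    group: J
  - name: J4
    taxa: [isiocarabus_sp, ohomopterus_sp1]
    kind: truncated_normal
    params: {mu: 15.0, sigma: 1.0, a: 0.0, b: 1000.0}  # effectively Normal(15, 1)
    group: J
  - name: M2
    taxa: [eurycarabus_genei, eurycarabus_famini]
    kind: exponential
    params: {mean: 0.5}   # opening of the Gibraltar Strait
    offset: 5.3
    group: M
  - name: M3
    taxa: [rhabdotocarabus_melancholicus_a, rhabdotocarabus_melancholicus_b]
    kind: exponential
    params: {mean: 0.5}
    offset: 5.3
    group: M
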