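# Default decision-tree topologies for the three screening strategies.
#
# Each branch probability `p` is a parameter name, an arithmetic expression
# over parameter names, or "~" (the complement of the node's other branches).
# `costs` lists one-time cost parameters charged to every newborn passing
# through the node; `tally` adds the node's incoming mass to a named tally.
#
# Reading notes (the published branch tables are not mutually consistent
# between arms; this file is the documented default reading):
#  * Delayed (post-screening) hearing loss has marginal probability
#    hl_given_pass among all UNHS-passers in EVERY arm; the concurrent arm
#    detects the share not hidden behind a double-pass, via the derived
#    expression on the `delayed_detected` branch.
#  * Latent mtDNA 12S rRNA carrier mass is anchored to what concurrent
#    screening identifies (genfail x mtdna fractions); arms that do not
#    screen a subpopulation send that same mass to mtdna_unwarned_carrier.
#  * Carriers are split out of normal-hearing branches only.

defs:
  mm_diagnosed: &mm_diagnosed
    label: mm_diagnosed
    branches:
      - {p: uptake_ha, leaf: mm_intervened}
      - {p: "~", leaf: mm_unintervened}
  sp_diagnosed: &sp_diagnosed
    label: sp_diagnosed
    branches:
      - {p: uptake_ci, leaf: sp_ci}
      - {p: "~", leaf: sp_no_ci}
  severity_fail: &severity_fail     # diagnosed hearing loss among UNHS referrals
    label: diagnosed_hl
    branches:
      - {p: mm_given_hl_fail, node: *mm_diagnosed}
      - {p: "~", node: *sp_diagnosed}
  hidden_hl_pass: &hidden_hl_pass   # delayed loss that no one detects
    label: hidden_hl
    branches:
      - {p: mm_given_hl_pass, leaf: mm_undetected}
      - {p: "~", leaf: sp_undetected}
  passed_unscreened: &passed_unscreened   # pass-UNHS subtree without gene screening
    label: passed
    branches:
      - p: hl_given_pass
        node: *hidden_hl_pass
      - p: "~"
        node:
          label: passed_normal
          branches:
          - p: genfail_given_pass * mtdna_given_pass_genfail / normal_given_pass
            leaf: mtdna_unwarned_carrier
          - {p: "~", leaf: normal_hearing}

unhs_only:
  label: cohort
  costs: [cost_hearing_screening]
  branches:
    - p: fail_unhs
      node:
        label: referred
        costs: [cost_hearing_diagnosis]
        branches:
          - p: hl_given_fail
            node: *severity_fail
          - p: "~"
            node:
              label: referred_normal
              branches:
                - p: genfail_given_fail * mtdna_given_fail_genfail / normal_given_fail
                  leaf: mtdna_unwarned_carrier
                - {p: "~", leaf: normal_hearing}
    - p: "~"
      node: *passed_unscreened

targeted:
  label: cohort
  costs: [cost_hearing_screening]
  branches:
    - p: fail_unhs
      node:
        label: referred
        costs: [cost_hearing_diagnosis, cost_genetic_screening]
        tally: genetic_screened
        branches:
          - p: hl_given_fail
            node:
              label: diagnosed_hl_gene_split
              branches:
                - p: genfail_given_fail_hl
                  node:
                    label: diagnosed_genfail
                    costs: [cost_genetic_diagnosis]
                    branches:
                      - {p: mm_given_hl_fail, node: *mm_diagnosed}
                      - {p: "~", node: *sp_diagnosed}
                - p: "~"
                  node:
                    label: diagnosed_genpass
                    branches:
                      - {p: mm_given_hl_fail, node: *mm_diagnosed}
                      - {p: "~", node: *sp_diagnosed}
          - p: "~"
            node:
              label: referred_normal
              branches:
                - p: genfail_given_fail_normal
                  node:
                    label: referred_normal_genfail
                    costs: [cost_genetic_diagnosis]
                    branches:
                      - {p: mtdna_given_fail_normal_genfail, leaf: mtdna_warned}
                      - {p: "~", leaf: normal_hearing}
                - p: "~"
                  node:
                    label: referred_normal_genpass
                    branches:
                      - p: (genfail_given_fail * mtdna_given_fail_genfail / normal_given_fail
                           - genfail_given_fail_normal * mtdna_given_fail_normal_genfail)
                           / genpass_given_fail_normal
                        leaf: mtdna_unwarned_carrier
                      - {p: "~", leaf: normal_hearing}
    - p: "~"
      node: *passed_unscreened

concurrent:
  label: cohort
  costs: [cost_hearing_screening, cost_genetic_screening]
  tally: genetic_screened
  branches:
    - p: fail_unhs
      node:
        label: referred
        costs: [cost_hearing_diagnosis]
        branches:
          - p: genfail_given_fail
            node:
              label: referred_genfail
              costs: [cost_genetic_diagnosis]
              branches:
                - {p: mtdna_given_fail_genfail, leaf: mtdna_warned}
                - p: positive_given_fail_genfail
                  node:
                    label: chip_positive
                    branches:
                      - {p: mm_given_positive, node: *mm_diagnosed}
                      - {p: "~", node: *sp_diagnosed}
                - p: "~"
                  node:
                    label: chip_carrier_sequenced
                    branches:
                      - p: positive_seq
                        node:
                          label: seq_positive
                          branches:
                            - {p: nh_given_positive_seq, leaf: normal_hearing}
                            - {p: mm_given_positive_seq, node: *mm_diagnosed}
                            - {p: "~", node: *sp_diagnosed}
                      - p: "~"
                        node:
                          label: seq_carrier
                          branches:
                            - p: hl_given_fail
                              node: *severity_fail
                            - {p: "~", leaf: normal_hearing}
          - p: "~"
            node:
              label: referred_genpass
              branches:
                - p: hl_given_fail_genpass
                  node:
                    label: referred_genpass_hl
                    branches:
                      - {p: mm_given_fail_genpass_hl, node: *mm_diagnosed}
                      - {p: "~", node: *sp_diagnosed}
                - {p: "~", leaf: normal_hearing}
    - p: "~"
      node:
        label: passed
        branches:
          - p: genfail_given_pass
            node:
              label: passed_genfail
              costs: [cost_hearing_diagnosis, cost_genetic_diagnosis]
              branches:
                - {p: mtdna_given_pass_genfail, leaf: mtdna_warned}
                - p: "~"
                  node:
                    label: passed_genfail_nonmtdna
                    branches:
                      - p: (hl_given_pass - genpass_given_pass * hl_given_passboth)
                           / (genfail_given_pass * (1 - mtdna_given_pass_genfail))
                        node:
                          label: delayed_detected
                          branches:
                            - {p: mm_given_hl_pass, node: *mm_diagnosed}
                            - {p: "~", node: *sp_diagnosed}
                      - {p: "~", leaf: normal_hearing}
          - p: "~"
            node:
              label: passed_genpass
              branches:
                - p: hl_given_passboth
                  node: *hidden_hl_pass
                - {p: "~", leaf: normal_hearing}
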