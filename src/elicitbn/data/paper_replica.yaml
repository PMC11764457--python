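# Twelve-variable pancreatic-cancer prognosis network with the published
# pooled informative priors.
#
# Continuous nodes carry location-scale Student-T priors built from the
# published pooled mean/SD with df = complete-case experts - 1, truncated
# to [0, inf). Categorical nodes carry the published Beta(alpha, beta)
# priors; the first-listed category is the one whose proportion the prior
# describes. Year-of-diagnosis's published pooled SD (0.65) is
# beta-infeasible; the published shape parameters are used directly.
#
# The edge set below is ILLUSTRATIVE: the true clinical structure is a
# modelling decision that the pooled priors do not determine. Neoadjuvant
# treatment is modelled as a CPT child of resectability and year of
# diagnosis, with rows anchored so its marginal stays near the published
# pooled proportion (0.61); replace the edges and models to encode a real
# structure.
nodes:
  - id: ca19_9
    kind: continuous
    support: [0, null]
    prior: {kind: student_t, location: 130.29, scale: 207.84, df: 7}
  - id: age
    kind: continuous
    support: [0, null]
    prior: {kind: student_t, location: 69.49, scale: 15.69, df: 6}
  - id: tumor_size
    kind: continuous
    support: [0, null]
    prior: {kind: student_t, location: 23.86, scale: 11.42, df: 7}
  - id: gender
    kind: categorical
    categories: [male, female]
    prior: {kind: beta, alpha: 7.62, beta: 5.76}
  - id: bmi
    kind: categorical
    categories: [normal_overweight, obese]
    prior: {kind: beta, alpha: 10.07, beta: 6.69}
  - id: year_of_diagnosis
    kind: categorical
    categories: [before_2015, after_2015]
    prior: {kind: beta, alpha: 3.85, beta: 2.08}
  - id: tumor_location
    kind: categorical
    categories: [head, body_tail]
    prior: {kind: beta, alpha: 4.26, beta: 3.63}
  - id: diabetes
    kind: categorical
    categories: [absent, present]
    prior: {kind: beta, alpha: 12.52, beta: 10.00}
  - id: symptoms
    kind: categorical
    categories: [absent, present]
    prior: {kind: beta, alpha: 3.46, beta: 2.15}
  - id: asa_score
    kind: categorical
    categories: [asa_1_2, asa_3_4]
    prior: {kind: beta, alpha: 4.75, beta: 2.94}
  - id: resectability
    kind: categorical
    categories: [resectable, borderline_locally_advanced]
    prior: {kind: beta, alpha: 3.83, beta: 2.13}
  - id: neoadjuvant
    kind: categorical
    categories: [performed, not_performed]
    parents: [resectability, year_of_diagnosis]
    model:
      class: cpt
      table:
        - {given: [resectable, before_2015], probs: [0.45, 0.55]}
        - {given: [resectable, after_2015], probs: [0.60, 0.40]}
        - {given: [borderline_locally_advanced, before_2015], probs: [0.60, 0.40]}
        - {given: [borderline_locally_advanced, after_2015], probs: [0.85, 0.15]}
options:
  categorical_mode: prior_predictive
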