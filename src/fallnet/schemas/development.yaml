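# Development-style model schema: layered guideline-derived DAG with a
# Hendrich-II-flavored risk tool (score node with subscore parents;
# high-risk cutoff >= 5 binned as low/high).
# Layers: demographics/administrative -> patient contributing factors ->
# risk-tool subscores -> risk-tool score -> fall; factors and mitigating
# interventions -> fall.
name: development
nodes:
  - name: sex
    states: [male, female]
    subgroup: demographics
  - name: age_bin
    states: [lt50, "50_60", "60_70", "70_80", gt80]
    subgroup: demographics
    numeric_values: [40, 55, 65, 75, 85]
  - name: diagnosis_group
    states: [neoplasm, benign, circulatory, resp_gi, surgical, neurological,
             infectious, other]
    subgroup: administrative
  - name: secondary_dx
    states: ["no", "yes"]
    subgroup: administrative
  - name: kpcs_group
    states: [g1, g2, g3, g4, g5_6]
    subgroup: kpcs
    numeric_values: [1, 2, 3, 4, 5.5]
  - name: mobility_impairment
    states: ["no", "yes"]
    subgroup: assessment_diagnosis
    parents: [age_bin]
  - name: cognitive_impairment
    states: ["no", "yes"]
    subgroup: assessment_diagnosis
    parents: [age_bin]
  - name: elimination_problem
    states: ["no", "yes"]
    subgroup: assessment_diagnosis
    parents: [kpcs_group]
  - name: fall_history
    states: ["no", "yes"]
    subgroup: assessment_diagnosis
  - name: sedative_use
    states: ["no", "yes"]
    subgroup: medication
    parents: [diagnosis_group]
  - name: hendrich_confusion
    states: [s0, s1]
    subgroup: risk_tool
    parents: [cognitive_impairment]
  - name: hendrich_mobility
    states: [s0, s1]
    subgroup: risk_tool
    parents: [mobility_impairment]
  - name: hendrich_score
    states: [low, high]
    subgroup: risk_tool
    parents: [hendrich_confusion, hendrich_mobility, sedative_use]
  - name: fall_precaution
    states: ["no", "yes"]
    subgroup: intervention
    parents: [hendrich_score]
  - name: toileting_assist
    states: ["no", "yes"]
    subgroup: intervention
    parents: [elimination_problem]
  - name: fall
    states: ["no", "yes"]
    subgroup: outcome
    parents: [mobility_impairment, cognitive_impairment, fall_history,
              sedative_use, fall_precaution, hendrich_score]
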