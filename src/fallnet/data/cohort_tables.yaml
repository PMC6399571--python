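# Two-site cohort comparison fixture: published summary counts for the two
# hospital cohorts (site1 = development, 14,307 admissions / 122,179
# hospital days; site2 = validation, 21,172 admissions / 172,592 days).
# Counts only — the statistics are always recomputed from these.
meta:
  site1: {admissions: 14307, hospital_days: 122179}
  site2: {admissions: 21172, hospital_days: 172592}

contingency:
  sex:
    rows: [site1, site2]
    cols: [female, male]
    counts:
      - [6157, 8150]
      - [11199, 9973]
  age:
    rows: [site1, site2]
    cols: [lt50, 50_60, 60_70, 70_80, gt80]
    counts:
      - [3165, 3251, 3356, 3281, 1254]
      - [5593, 3844, 3517, 5039, 3179]
  medical_diagnosis:
    rows: [site1, site2]
    cols: [neoplasm, benign, circulatory, resp_gi, surgical, neurological,
           infectious, other]
    counts:
      - [4639, 385, 5670, 655, 517, 998, 115, 1328]
      - [4869, 1066, 769, 5630, 2163, 263, 813, 5599]
  secondary_diagnosis:
    rows: [site1, site2]
    cols: [present, absent]
    counts:
      - [14242, 65]
      - [13421, 7751]
  minor_injury:
    # among injurious falls: minor vs more-than-minor
    rows: [site1, site2]
    cols: [minor, moderate]
    counts:
      - [49, 5]
      - [52, 17]
  faller_admissions:
    # admissions with at least one fall vs none
    rows: [site1, site2]
    cols: [faller, nonfaller]
    counts:
      - [238, 14069]
      - [292, 20880]

summary:
  length_of_stay:
    mean1: 8.54
    sd1: 11.52
    n1: 14307
    mean2: 8.15
    sd2: 11.28
    n2: 21172

rates:
  falls:
    events1: 238
    days1: 122179
    events2: 292
    days2: 172592
  injurious_falls:
    events1: 54
    days1: 122179
    events2: 69
    days2: 172592
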