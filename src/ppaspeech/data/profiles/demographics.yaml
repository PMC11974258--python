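# Baseline sociodemographics per group: published mean / SD / range for age
# and education, and the female/male split (sex is simulated as Bernoulli
# with the group's female proportion).
# One typo correction relative to the printed source, applied once:
#   - nfvPPA age range printed as (51.6-3.9); corrected to (51.6-83.9).
schema_version: 1
kind: demographics
groups:
  HC:
    n: 23
    age:       {mean: 66.2, sd: 6.3, min: 56.5, max: 81.4}
    education: {mean: 9.5, sd: 3.3, min: 5.0, max: 17.0}
    sex_female: 13
    sex_male: 10
  nfvPPA:
    n: 40
    age:       {mean: 70.2, sd: 8.5, min: 51.6, max: 83.9}
    education: {mean: 9.7, sd: 4.9, min: 3.0, max: 22.0}
    sex_female: 24
    sex_male: 16
  svPPA:
    n: 35
    age:       {mean: 66.6, sd: 8.7, min: 42.1, max: 81.6}
    education: {mean: 11.9, sd: 4.6, min: 5.0, max: 18.0}
    sex_female: 20
    sex_male: 15
  lvPPA:
    n: 20
    age:       {mean: 72.4, sd: 7.0, min: 56.4, max: 81.3}
    education: {mean: 12.1, sd: 3.6, min: 5.0, max: 17.0}
    sex_female: 11
    sex_male: 9
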