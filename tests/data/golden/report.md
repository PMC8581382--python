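# Dual-source dementia ascertainment report

## Overlap

- primary-care documented: 80
- specialist documented: 87
- both sources: 60
- union: 107
- both as share of union: 56%
- primary also in specialist: 75%
- specialist also in primary: 69%

Population denominator aged 65+ at reference date: 379
Consultation median used for categorisation: 23

## Stratified characteristics

### age_group

| category | BOTH | SPECIALIST_ONLY | PRIMARY_ONLY |
|---|---|---|---|
| 65_74 | 24 (40%, 29%–53%) | 5 (19%, 8.2%–37%)- | 5 (25%, 11%–47%) |
| 75_84 | 16 (27%, 17%–39%) | 11 (41%, 25%–59%) | 10 (50%, 30%–70%)+ |
| 85_PLUS | 20 (33%, 23%–46%) | 11 (41%, 25%–59%) | 5 (25%, 11%–47%) |

Chi-squared = 6.67, df = 4, P = 0.155

### sex

| category | BOTH | SPECIALIST_ONLY | PRIMARY_ONLY |
|---|---|---|---|
| F | 35 (58%, 46%–70%) | 17 (63%, 44%–78%) | 12 (60%, 39%–78%) |
| M | 25 (42%, 30%–54%) | 10 (37%, 22%–56%) | 8 (40%, 22%–61%) |

Chi-squared = 0.17, df = 2, P = 0.920

### ethnicity6

| category | BOTH | SPECIALIST_ONLY | PRIMARY_ONLY |
|---|---|---|---|
| ASIAN | 2 (3.6%, 1.0%–12%) | 0 (0.0%, 0.0%–14%) | 0 (0.0%, 0.0%–19%) |
| BLACK | 16 (29%, 19%–42%) | 7 (29%, 15%–49%) | 2 (13%, 3.5%–36%) |
| MISSING | 5 (omitted) | 3 (omitted) | 4 (omitted) |
| MIXED | 0 (0.0%, 0.0%–6.5%) | 0 (0.0%, 0.0%–14%) | 1 (6.3%, 1.1%–28%)+ |
| OTHER | 1 (1.8%, 0.3%–9.6%) | 0 (0.0%, 0.0%–14%) | 0 (0.0%, 0.0%–19%) |
| WHITE_BRITISH | 26 (47%, 35%–60%) | 13 (54%, 35%–72%) | 9 (56%, 33%–77%) |
| WHITE_NON_BRITISH | 10 (18%, 10%–30%) | 4 (17%, 6.7%–36%) | 4 (25%, 10%–49%) |

Chi-squared = 9.19, df = 10, P = 0.514

### imd_q1

| category | BOTH | SPECIALIST_ONLY | PRIMARY_ONLY |
|---|---|---|---|
| False | 56 (93%, 84%–97%) | 25 (96%, 81%–99%) | 14 (70%, 48%–85%)- |
| MISSING | 0 (omitted) | 1 (omitted) | 0 (omitted) |
| True | 4 (6.7%, 2.6%–16%) | 1 (3.8%, 0.7%–19%) | 6 (30%, 15%–52%)+ |

Chi-squared = 10.36, df = 2, P = 0.006

### smoking

| category | BOTH | SPECIALIST_ONLY | PRIMARY_ONLY |
|---|---|---|---|
| CURRENT | 8 (15%, 8.0%–28%) | 7 (29%, 15%–49%) | 8 (42%, 23%–64%)+ |
| FORMER | 25 (48%, 35%–61%) | 12 (50%, 31%–69%) | 7 (37%, 19%–59%) |
| MISSING | 8 (omitted) | 3 (omitted) | 1 (omitted) |
| NEVER | 19 (37%, 25%–50%) | 5 (21%, 9.2%–40%) | 4 (21%, 8.5%–43%) |

Chi-squared = 6.85, df = 4, P = 0.144

### consult_cat

| category | BOTH | SPECIALIST_ONLY | PRIMARY_ONLY |
|---|---|---|---|
| ABOVE_AVERAGE | 29 (48%, 36%–61%) | 12 (44%, 28%–63%) | 11 (55%, 34%–74%) |
| AVERAGE_OR_LESS | 31 (52%, 39%–64%) | 15 (56%, 37%–72%) | 9 (45%, 26%–66%) |

Chi-squared = 0.52, df = 2, P = 0.772

### care_home

| category | BOTH | SPECIALIST_ONLY | PRIMARY_ONLY |
|---|---|---|---|
| False | 55 (92%, 82%–96%) | 26 (96%, 82%–99%) | 18 (90%, 70%–97%) |
| True | 5 (8.3%, 3.6%–18%) | 1 (3.7%, 0.7%–18%) | 2 (10%, 2.8%–30%) |

Chi-squared = 0.80, df = 2, P = 0.669

### charlson_cat

| category | BOTH | SPECIALIST_ONLY | PRIMARY_ONLY |
|---|---|---|---|
| 0 | 20 (33%, 23%–46%) | 10 (37%, 22%–56%) | 6 (30%, 15%–52%) |
| 1 | 10 (17%, 9.3%–28%) | 6 (22%, 11%–41%) | 3 (15%, 5.2%–36%) |
| 2_3 | 21 (35%, 24%–48%) | 7 (26%, 13%–45%) | 8 (40%, 22%–61%) |
| 4_5 | 6 (10%, 4.7%–20%) | 3 (11%, 3.9%–28%) | 3 (15%, 5.2%–36%) |
| 6_PLUS | 3 (5.0%, 1.7%–14%) | 1 (3.7%, 0.7%–18%) | 0 (0.0%, 0.0%–16%) |

Chi-squared = 2.69, df = 8, P = 0.952

### died_in_followup

| category | BOTH | SPECIALIST_ONLY | PRIMARY_ONLY |
|---|---|---|---|
| False | 48 (80%, 68%–88%) | 20 (74%, 55%–87%) | 17 (85%, 64%–95%) |
| True | 12 (20%, 12%–32%) | 7 (26%, 13%–45%) | 3 (15%, 5.2%–36%) |

Chi-squared = 0.87, df = 2, P = 0.649

### subtype

| category | BOTH | SPECIALIST_ONLY | PRIMARY_ONLY |
|---|---|---|---|
| ALZHEIMERS_MIXED | 38 (68%, 55%–79%) | 20 (77%, 58%–89%) | 10 (63%, 39%–82%) |
| OTHER_SPECIFIED | 1 (1.8%, 0.3%–9.4%) | 0 (0.0%, 0.0%–13%) | 1 (6.3%, 1.1%–28%) |
| UNSPECIFIED | 4 (omitted) | 1 (omitted) | 4 (omitted) |
| VASCULAR | 17 (30%, 20%–43%) | 6 (23%, 11%–42%) | 5 (31%, 14%–56%) |

Chi-squared = 2.66, df = 4, P = 0.617

### medicated

| category | BOTH | SPECIALIST_ONLY | PRIMARY_ONLY |
|---|---|---|---|
| False | 44 (73%, 61%–83%) | 24 (89%, 72%–96%) | 15 (75%, 53%–89%) |
| True | 16 (27%, 17%–39%) | 3 (11%, 3.9%–28%) | 5 (25%, 11%–47%) |

Chi-squared = 2.68, df = 2, P = 0.261

## Overlapping-cohort comparison (specialist : primary care)

| characteristic | specialist x/n | primary x/n | PR (CI) |
|---|---|---|---|
| age_85_plus | 31/87 | 25/80 | 1.14 (0.74–1.75) |
| female | 52/87 | 47/80 | 1.02 (0.79–1.31) |
| white_british | 39/87 | 35/80 | 1.02 (0.73–1.44) |
| charlson_high | 13/87 | 12/80 | 1.00 (0.48–2.05) |
| consult_high | 41/87 | 40/80 | 0.94 (0.69–1.29) |
| care_home | 6/87 | 7/80 | 0.79 (0.28–2.25) |
| died_in_followup | 19/87 | 15/80 | 1.16 (0.64–2.13) |
| alzheimers_mixed | 58/87 | 48/80 | 1.11 (0.88–1.40) |
| medicated | 11/53 | 12/52 | 0.90 (0.44–1.85) |

## Missing data

- ethnicity: 12 (11%)
- smoking: 12 (11%)
- lsoa_address: 1 (0.9%)

Footnote: a stratified-table cell is flagged + or - when its Wilson CI excludes the both-sources stratum point estimate.
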