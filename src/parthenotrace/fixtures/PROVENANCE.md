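# Golden fixture data

Transcribed outcomes of a published artificial-insemination and
parthenogenesis study of captive whitespotted bamboo sharks
(*Chiloscyllium plagiosum*).

- `panel.yaml` — the nine-locus microsatellite panel (four previously
  published loci plus five study-specific loci).
- `table4_offspring.csv` — 15 genotyped parthenote offspring: P1-P12 from a
  48-female habitat housed without males, AI-P1-AI-P3 from two inseminated
  females. `-/-` marks failed loci.
- `table4_dams.csv` — known genotypes of inseminated females 854 and 307.
- `table4_reconstructed.csv` — the study's published maternal
  reconstructions ("Female 1"-"Female 4"); half-missing cells are loci the
  reconstruction could not pin.  Note: the published "Female 2" row was
  reconstructed without P8 (whose four failed loci left it unconfirmed);
  including P8 pins Cpl962 to 356/368 and does not change the minimum dam
  count.
- `table3_trials.csv` — per-female insemination-trial outcomes for 20
  females.  `n_eggs` is the non-wind denominator back-computed from the
  printed fertility/hatchability percentages and hatchling counts
  (`eggs_laid` and `n_eggs` disagree for some females, e.g. 793: 27 laid
  vs 23 implied — both are recorded).  `duration_printed` follows the
  published inclusive convention (a single fertile egg prints 1, while
  last-minus-first gives 0).  Row 307's printed fertility (7.7% = 3/39)
  includes its two parthenotes, unlike every other row
  (`fertility_printed_is_raw`).  Groups: `fresh` inseminates, `cold24` /
  `cold48` = 24 h / 48 h cold-stored semen.
- `table2_sperm.csv` — spermatozoa morphometrics (mean ± SE, 10 cells per
  shark, five sharks).
- `habitat_survey.yaml` — egg counts for the 48-female habitat survey.
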