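# parthenotrace

Inference tools for captive-breeding programs of facultatively
parthenogenetic, egg-laying sharks:

- **`genotypes_io`** — read/write multilocus microsatellite genotype tables
  (`a1/a2` cells, half-missing `194/-` and failed `-/-` loci first-class)
  and Genepop export/import with a stable allele-code sidecar.
- **`parentage`** — classify each offspring against its putative dam (and
  optionally a sire) as `PARTHENOTE` (homozygous for maternal alleles at
  every scored locus), `SEXUAL`, `CONSISTENT_UNCONFIRMED` (parthenote-like
  but too many failed loci to confirm) or `MISMATCH`; rank candidate sires
  by paternal-exclusion count.
- **`matriline`** — reconstruct maternal genotypes from parthenote
  offspring (per-locus allele unions, wildcards where fewer than two
  alleles are pinned) and compute the exact minimum number of dams needed
  to explain a parthenote collection (branch-and-bound set-partition
  search, greedy upper bound past 20 individuals).
- **`repro_metrics`** — per-female fertility / hatchability / fertility
  duration from oviposition event logs (wind cases excluded from
  denominators, parthenotes excluded from insemination-attributed
  numerators), pooled cohort totals, parthenogenesis incidence, and sperm
  morphometric summaries with an exact additivity property.
- **`synthetic_data`** — seeded generators for Hardy–Weinberg populations,
  Mendelian offspring, terminal-fusion parthenotes (genome-wide homozygous),
  genotyping noise, and egg-pair oviposition schedules with geometric
  post-insemination fertilization decay.
- **`cli_pipeline`** — a `parthenotrace` CLI tying the stages together.

Golden fixtures transcribed from the source study (a nine-locus panel, 15
parthenote genotypes, two known dams, four published maternal
reconstructions, 20 insemination-trial outcomes, sperm morphometrics and a
48-female habitat egg survey) ship inside the package; see
`src/parthenotrace/fixtures/PROVENANCE.md`.

## CLI

```sh
parthenotrace classify   --genotypes g.csv --dam 307 --out calls.tsv
parthenotrace minmothers --genotypes parthenotes.csv --out dams.tsv
parthenotrace summarize  --events events.csv --out summaries.tsv
parthenotrace simulate genotypes --seed 1 --n-dams 10 --out simdir
parthenotrace simulate eggs      --seed 1 --n-females 5 --out simdir
parthenotrace run --config config.yaml        # full pipeline bundle
```

`run` takes a YAML config (panel, input paths, dam/sire maps, groups,
tolerance, seed, output directory) and writes offspring calls, maternal
reconstructions, female summaries, cohort totals, an incidence block and a
manifest; reruns with the same config are byte-identical.

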