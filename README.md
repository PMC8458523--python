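# whalesong

Analysis toolkit for structured animal song in passive acoustic monitoring
data, built around humpback-whale-style song hierarchies (units → phrases →
themes → songs → sessions). It provides:

- **Hour categorization** — classify reviewed hours as absence, social
  calls, preliminary song (≥ 3 repeated phrases of one type), or complex
  song (≥ 2 distinct themes), plus station-month proportion summaries.
- **Singer attribution & segmentation** — 24-hour gap rule for presumed
  individual singers, SNR/theme quality filtering, session splitting at
  > 60 s silence gaps, and song delineation by complete rendition of the
  session's unique theme set.
- **Elaborateness** — session/song lengths (units), unit/phrase/song
  complexity ratios, and Pearson correlations against day of year and
  latitude.
- **Similarity** — Dice coincidence index (DCI) on phrase repertoires,
  token-level Levenshtein similarity (LSI) on theme sequences, set-median
  string selection, and labelled similarity matrices.
- **Clustering** — single-linkage (nearest neighbour) trees on 1 − s with
  multiscale-bootstrap approximately-unbiased (AU) support per division and
  Newick export.
- **Sea ice** — daily station series from gridded concentration (50 km
  radius), monthly means, 15% ice-edge crossing events, and song/ice lags.
- **Unit validation** — out-of-bag misclassification rate and confusion
  matrix of a bagged-tree ensemble on labelled acoustic feature tables.
- **Synthetic data** — a seeded generator producing song groups with
  configurable catalogue overlap and era drift, hour tables with a seasonal
  peak, sinusoidal ice fields, and Gaussian unit-feature clusters, so the
  whole pipeline is testable offline.

A transcription of the published set-median theme-sequence table
(77 singers, 44 phrase types) ships as a checksummed package fixture.

## Command line

```bash
whalesong simulate --seed 7 --out out/synthetic     # full synthetic study
whalesong table1 --method dci --out out/table1      # cluster the packaged fixture
whalesong run-all --seed 7 --out out/run            # simulate + every stage
whalesong cluster --songs songs.jsonl --method lsi --seed 1 --out out/clust
```

Every stage writes plain-text artifacts (CSV / JSONL / Newick) plus a
`*.meta.json` sidecar carrying the seed, version, and a hash of the
effective configuration. `whalesong --help` lists all stages
(`classify-hours`, `build-sequences`, `elaborateness`, `similarity`,
`cluster`, `seaice`, `validate-units`, `table1`, `run-all`).

## Interpretation choices worth knowing

- Edit distance operates on whole theme tokens, never characters.
- The multiscale bootstrap resamples *raw observations*: phrase-type
  columns of the binary repertoire matrix for DCI, each singer's song set
  for LSI. The resampling unit is recorded in output metadata.
- When only the set-median table is available, a singer's repertoire is
  proxied by the phrase-type set of the printed median sequence (flagged in
  metadata).
- Ice-edge events use strict comparisons (drop below / exceed the
  threshold); interior gaps of at most five days are linearly interpolated.
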