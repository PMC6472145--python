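# margex

Text-mining pipeline for studying how often p-values just above .05 are
*reported as marginally significant* in scientific articles.

Given plain-text article bodies with metadata (DOI, journal, year), margex:

1. **extracts** every reported p-value with a regular-expression grammar,
   capturing the verbatim match, the comparison sign, the printed number,
   and up to 200 characters of context on each side;
2. **cleans** the records through an ordered filter cascade — drop rows
   with no metadata at all, drop non-numeric values (e.g. `p = .`), drop
   journals that belong only to the general/interdisciplinary category,
   and finally keep only `.05 < p ≤ .10` (boundaries compared in exact
   decimal arithmetic) — while standardizing journal names against a
   registry, filling metadata gaps through an injectable DOI resolver, and
   optionally drawing a per-journal stratified test sample;
3. **classifies** each retained mention as reported-as-marginal by a
   case-insensitive, word-initial search for the stems `margin` and
   `approach` inside the captured context windows;
4. **aggregates** two outcome levels per group (overall / journal /
   discipline, optionally per year): the percentage of in-range p-values
   labeled marginal, and the percentage of articles with p-values that
   contain at least one marginal in-range p-value (denominator: *all*
   articles with p-values), with Wald (default) or Wilson 95% CIs;
5. **fits trends**: unweighted simple least-squares slopes of the yearly
   percentages.

A first-class **synthetic corpus generator** produces articles with known
per-mention ground truth (controllable in-range mass, marginal-phrase
probability and its yearly drift, stem-bearing decoy phrases placed inside
or outside the windows), so extraction recall/precision, classifier
agreement, and end-to-end parameter recovery are all testable offline.

## CLI

Each stage is a subcommand; `run-all` chains them from one YAML config:

```sh
margex simulate --out-dir corpus/ --seed 7         # synthetic corpus + truth
margex extract  --corpus corpus/corpus.jsonl --out records.csv
margex clean    --records records.csv --registry journals.csv \
                --out clean.csv --report filter_report.json
margex classify --records clean.csv --out labeled.csv
margex aggregate --records labeled.csv --by discipline --per-year --out stats.csv
margex trend    --stats stats.csv --out trends.csv
```

`run-all` example config:

```yaml
out_dir: out
seed: 11
grouping: discipline
simulate:
  n_articles: 200
  theta_marginal: 0.4
  theta_trend: 0.01
```

```sh
margex run-all --config run.yaml
```

Outputs land in `out_dir`: the record-level dataset (`records.csv`, one row
per extracted p-value), group statistics, trend slopes, a stratified test
sample, a manifest with per-stage filter counts, and the resolved config.
Unknown config keys are rejected.

Real corpora are read either as a directory of UTF-8 `.txt` files plus a
`metadata.csv` sidecar (`article_id,doi,journal,year`) or as a `.jsonl`
file with those fields inline.  Journal registries are CSV
(`raw_name,canonical_name,disciplines,core_only`, disciplines
semicolon-separated); a small editable registry seeded with the nine APA
discipline labels ships with the package.

## Notes on fidelity

- The original study never printed its extraction regex; the grammar here
  matches its printed examples and is flag-configurable (plural `ps`
  matching off by default, `≤`/`≥` normalization on by default).
- CI method defaults to the Wald normal approximation, which reproduces
  the published brackets; Wilson is available via `--ci-method wilson`.
- The record CSV encodes missing values as `\N` (literal `\N` strings are
  escaped), so CSV and JSONL round-trips are both lossless.
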