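# Optional local data

Files placed here are picked up by the tests, the acceptance script, and the
CLI, but nothing in this directory is required: the genome-scale checks fall
back to cobrapy's packaged copy of iJO1366.

- `iJO1366.json` — the *E. coli* K-12 MG1655 genome-scale model in
  COBRA-JSON, downloadable once from BiGG:
  `curl -o data/iJO1366.json http://bigg.ucsd.edu/static/models/iJO1366.json`
- Knockout-exclusion lists for `auxodesign design --exclude` are plain text,
  one reaction id per line, `#` comments allowed — e.g. a rich-media
  essentiality list or a model false-positive list compiled from the
  literature for the model you are using.
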