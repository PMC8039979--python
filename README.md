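# cactokey

Identification toolkit for cyst nematodes of the genus *Cactodera*. The
package bundles a 17-taxon comparative character matrix (cyst, second-stage
juvenile and egg characters) and a machine-readable dichotomous key to the
genus, and provides:

- **datamodel** — character registry, interval/categorical matrix cells with
  explicit unknowns, CSV/JSON round-trip I/O, specimen observation
  validation (`cactokey.datamodel`).
- **morphometrics** — "mean ± sd (min-max)" summary blocks and the de Man
  ratio indices (a, b, c, c′) plus L/MB, TL/H, cyst L/W and egg L/W
  (`cactokey.morphometrics`).
- **key_engine** — the dichotomous key as an acyclic decision graph
  evaluated with three-valued (yes/no/ambiguous) logic, full traversal
  traces, and a key-vs-matrix consistency audit. Transcription repairs and
  known printed-key tensions are shipped in a machine-readable errata file
  (`cactokey.key_engine`).
- **identify** — multi-access (polyclave) identification: interval-overlap
  scoring of a specimen against every taxon, ranked candidates, and
  pairwise diagnostic-character reports (`cactokey.identify`).
- **seqdiv** — pairwise divergence on pre-aligned nucleotide sequences with
  "N bp (P.PP%)" reporting and configurable gap policy (`cactokey.seqdiv`).
- **fixtures** — seeded generators for synthetic specimens (drawn inside
  published intervals) and toy alignments with exact ground-truth
  differences (`cactokey.fixtures`).

## CLI

The `cactokey` entry point groups the main operations:

```sh
cactokey matrix show                       # inspect the bundled matrix
cactokey matrix export matrix.json         # round-trip-safe export
cactokey key path "C. tianzhuensis"        # couplet trace for a taxon
cactokey key validate                      # audit all 17 taxa vs the key
cactokey identify --obs specimen.csv       # ranked candidates
cactokey compare "C. tianzhuensis" "C. cacti"   # diagnostic characters
cactokey summarize sheet.csv               # per-character summary block
cactokey divergence aln.fasta --ref seq1   # "N bp (P.PP%)" table
cactokey simulate specimens --taxon "C. rosae" --n 20 --seed 1
cactokey simulate alignment --length 500 --n-seqs 3 --diffs 5 --seed 1
```

Specimen CSVs have two columns, `character,value`, where `value` is a
number, a `lo-hi` interval, or a category token; character ids are listed
in `src/cactokey/data/cactodera_v1/registry.json`.

## Notes

- The comparative matrix stores published *ranges*; key couplets that test
  *means* are answered with the interval midpoint and flagged `proxy-mean`
  in traces. Two taxa are misrouted by their own table rows under this
  proxy; both cases are documented in
  `src/cactokey/data/cactodera_v1/key_errata.yaml` and surfaced (not
  repaired) by `cactokey key validate`.
- GenBank-derived divergence percentages and Bayesian tree topologies from
  the source study are out of scope: they require external accessions and
  external inference tools. The divergence arithmetic is validated against
  brute-force counts on constructed alignments instead.
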