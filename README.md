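# proteoannot

A proteogenomic re-annotation toolkit. It translates annotated gene models,
predicted lncRNAs and long-read transcript isoforms into candidate proteins,
validates them against peptide-spectrum-match (PSM) evidence using
reversed-decoy FDR filtering and a two-peptide rule, quantifies validated
proteins with NSAF spectral counting, calls differential expression with
fold-change thresholds, classifies NMD-targeted isoforms by the 50-nt
last-junction rule, and compares the domain composition of a gene's protein
isoforms. A synthetic-data module generates a complete toy study — genome,
gene models, isoforms, lncRNAs, true proteome, two-tissue PSM tables and
domain assignments — with truth tables so every stage is testable offline.

## Layout

| module | purpose |
| --- | --- |
| `proteoannot.coords` | the two coordinate dialects (1-based closed GFF3, 0-based half-open mRNA) and their conversions |
| `proteoannot.io_formats` | FASTA / GFF3 / PSM-and-domain TSV readers and writers |
| `proteoannot.synthetic_data` | deterministic toy-study generator with truth tables |
| `proteoannot.orf_finder` | ATG-initiated ORF extraction in 3 forward frames; lncRNA `> 100 aa` filter |
| `proteoannot.peptide_engine` | tryptic digestion (KP/RP suppression), reversed decoys, target-decoy FDR, I/L-collapsed peptide matching, two-peptide protein inference |
| `proteoannot.quantification` | NSAF, pseudocounted fold changes, DE calls, sample correlation |
| `proteoannot.nmd_classifier` | 50-nt PTC rule and NMD composition percentages |
| `proteoannot.domain_compare` | four domain-set relation categories per gene |
| `proteoannot.report` | set-overlap summaries, molecular weights, hypergeometric enrichment |
| `proteoannot.pipeline` / `proteoannot.cli` | orchestration and the `proteoannot` command |

## CLI

Every stage is a subcommand; `run-all` simulates a study and drives all of
them, writing a manifest of content hashes (two runs with the same seed are
byte-identical):

```sh
proteoannot run-all --seed 1 --n-genes 300 --out-dir out/
proteoannot simulate --seed 1 --n-genes 50 --out-dir sim/
proteoannot orfs --input sim/lncrna.fa --biotype lncrna \
    --out-fasta lnc_orfs.fa --out-table lnc_orfs.tsv
proteoannot digest --input sim/proteins_annotated.fa --out peptides.tsv
proteoannot decoy --input sim/proteins_annotated.fa --out target_decoy.fa
proteoannot match --psms sim/psms_seedling.tsv --psms sim/psms_leaf.tsv \
    --annotated sim/proteins_annotated.fa --lncrna-orfs lnc_orfs.fa \
    --isoform-orfs iso_orfs.fa --out-dir match/
proteoannot quantify --proteins match/proteins.tsv --out-dir quant/
proteoannot nmd --gff3 sim/models.gff3 --orfs iso_orfs.tsv \
    --out-calls nmd.tsv --out-summary nmd.json
proteoannot domains --domains sim/domains.tsv --validated match/proteins.tsv \
    --out-categories cats.tsv --out-counts cats.json
```

Defaults follow the study's thresholds: FDR < 0.01 at peptide and protein
level, ≥ 2 distinct peptides per protein, fold change ≥ 4 / ≤ 0.25,
NMD distance ≥ 50 nt, lncRNA ORFs > 100 aa, 2 missed cleavages.

## Conventions worth knowing

- Genomic coordinates are 1-based closed (GFF3); all mature-mRNA
  coordinates are 0-based half-open. Conversions live in one helper module.
- Peptide matching collapses I/L on both sides; isoform-level validation
  additionally requires at least one isoform-unique peptide, and shared
  peptides never contribute to isoform-level spectral counts.
- Fold changes use a 0.5 spectral-count pseudocount; reported NSAF values
  never do. NSAF sums to 1 per sample by construction.
- The `> 100 aa` lncRNA ORF filter is strict (kept at ≥ 101 aa);
  mRNA/isoform databases keep all ORFs ≥ 100 aa, multiple per transcript.
- The NMD boundary is inclusive: a stop ending exactly 50 nt upstream of
  the last junction is NMD.
- Reported percentages round half-up (1 or 2 decimals depending on the
  surface); overlap shares are integer percents.
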