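# vulnscreen

Analysis toolkit for dual high-throughput vulnerability screens: an siRNA
arm (plate normalization, robust Z-scoring, seed-median off-target
correction, exponential-power tail cutoffs, RSA gene ranking, Haystack
3'-UTR regression, verification-screen RSA and an expression filter) and a
small-molecule arm (DMSO/bortezomib control normalization, robust
grid-based 4PL dose-response fitting, normalized AUC, absolute IC50 /
relative EC50, genotype-class summaries). A synthetic-data module generates
screens with known ground truth so every stage is verifiable offline.

## Package layout

| module | role |
| --- | --- |
| `vulnscreen.io_formats` | TSV/CSV plate tables, siRNA libraries, expression tables, UTR FASTA, result reports |
| `vulnscreen.normalization` | plate-effect correction, robust Z, verification-control normalization |
| `vulnscreen.seed_correction` | seed extraction (guide positions 2–7), seed grouping, group-median correction |
| `vulnscreen.hit_calling` | exponential-power tail model and cutoffs, RSA ranking, hit selection, cross-line combination, verification, expression filter |
| `vulnscreen.haystack` | seed-complementary 3'-UTR site counting and per-gene off-target regression (BH-adjusted) |
| `vulnscreen.dose_response` | dilution design, viability normalization, robust grid 4PL, normalized AUC, IC50/EC50, class summaries, tumor-volume utility |
| `vulnscreen.synthetic_data` | ground-truth simulators for libraries, discovery/verification screens, UTR sets and dose plates |

## CLI

```sh
# simulate a discovery screen, then call hits
vulnscreen simulate --kind discovery --seed 1 --out-dir sim/
vulnscreen discover --plates sim/plates.tsv --library sim/library.tsv \
    --cell-line L1 --out hits.tsv

# verification arm
vulnscreen verify --plates verif_plates.tsv --library verif_library.tsv --out verified.tsv

# seed off-target regression
vulnscreen haystack --utrs utrs.fasta --activities activities.tsv \
    --library library.tsv --out haystack.tsv

# dose-response fitting (11-point 1:3 series, top ~38.3 uM by default)
vulnscreen drugfit --plates dose_plates.tsv --cell-line L1 --out curves.tsv
```

Plate tables are delimited text with header columns
`plate, well, role, id, signal`; roles come from the closed vocabulary
`library, non_transfected, negative_control, positive_control, dmso,
bortezomib`. Well addresses may be `A01`-style or `row,col` integers.

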