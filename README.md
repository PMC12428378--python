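# horscan

Detection and classification of **alpha-satellite higher-order repeats
(HORs)** in genome assemblies — including the large *cascading* superHOR
architectures of great-ape centromeres that classical Willard-type HOR
detectors cannot represent.

Primate centromeres are built from tandem ~171 bp alpha-satellite
*monomers*. Monomers diverged by <5% belong to one *monomer type*; an
ordered run of *n* types that is itself tandemly repeated at low inter-copy
divergence is an *n*-mer HOR. In the classical Willard-type HOR every type
occurs exactly once per unit. Cascading HORs — such as the 58-monomer
superHOR of the orangutan Y centromere, which holds only 44 distinct types
with 14 repeated internally — repeat types within the unit, producing a
multi-row aligned schematic (rows of distinct types, columns of one type).

`horscan` implements the full chain:

1. **Monomer extraction** — semi-global alignment of a 171 bp consensus
   monomer against both strands (edlib), ≥95% identity by default, greedy
   overlap tiling, exclusion of monomers overlapping assembly N-gaps,
   grouping of tandem hits into arrays.
2. **Monomer typing** — greedy static-centroid clustering at the <5%
   divergence threshold (divergence = edit distance / alignment columns),
   with a column-reconciliation pass against the provisional HOR scheme.
3. **MD / GRM diagrams** — for each monomer enumeration *l*, the MD-point
   (*l*, *p*) marks the next same-type monomer at distance *p* ≤ 90; the
   GRM table is the per-period MD-point frequency; dense horizontal MD
   line segments delimit candidate HOR arrays.
4. **HOR segmentation and classification** — an anchor monomer type cuts
   the array into copies; the *canonical* unit is the most frequent
   complete *n*-mer; every other copy is a *variant* `V<m>` named by its
   monomer count; outputs include the C/V string, per-family consensus
   sequence and mean divergence of canonical copies.
5. **Cascading layout** — greedy column assignment builds the multi-row
   scheme, classifies the family as Willard's vs. cascading, and aligns
   variant rows against the canonical rows (dashes for missing rows).
6. **Synthetic arrays** — a generator plants arrays with full ground truth
   (monomer coordinates, types, HOR structure, C/V pattern, mutation
   rates), so the entire pipeline is testable with no downloads.

## Worked example

`examples/03_hor_detection.py` plants 30 copies of a cascading 8-monomer
unit `1 2 3 4 2 3 4 5` (types 2, 3, 4 repeated) with two structural
variants — one duplicating the second half-row, one deleting a monomer —
and runs the full pipeline:

```
period: 8 monomers, type: Cascading
copies: 29 (27 canonical)
cv string: CCCCCCCCCCVCCCCCCCCCVCCCCCCCC
planted  : CCCCCCCCCCVCCCCCCCCCVCCCCCCCC (last copy is dropped at the array edge)
row scheme: [4, 4] over 5 distinct types
mean canonical divergence from consensus: 0.238%
A V copy deviates structurally from the canonical unit and is
named by its monomer count in the per-family variant table:
     row_1  row_2 row_3  n_rows
C8       4      4     -       2
V12      4      4     4       3
V7       3      4     -       2
```

The recovered C/V string equals the planted pattern (the unit after the
last anchor is dropped as a partial edge copy); the canonical unit lays
out as two rows of four monomers; the V12 variant repeats the second row,
so the canonical scheme shows a dash in the inserted row slot; the mean
divergence of canonical copies from the voted consensus recovers the
planted 0.25% per-base mutation scale.

Other examples: `01_scan_monomers.py` (extraction), `02_md_diagram.py`
(MD/GRM computation), `04_species_architectures.py` (desk-scale analogs of
the orangutan/human/chimpanzee/gorilla Y-centromere architectures).

## Command line

Each stage is independently invocable:

```sh
horscan monomers --fasta chrY.fa --out-bed monomers.bed --out-tsv monomers.tsv
horscan grm      --fasta chrY.fa --out-points md.tsv --out-freq freq.tsv
horscan run      --fasta chrY.fa --out run_dir           # full pipeline
horscan synth    --spec spec.json --out-fasta a.fa --out-truth truth
```

`horscan run` writes monomer BED/TSV, MD-points and period-frequency
tables, and a per-family directory with the copy table, C/V string,
consensus FASTA, cascade scheme, variant table and a summary JSON, plus a
manifest with the configuration and input checksum. Defaults follow the
published pipeline settings: ≥95% scan identity, <5% type threshold,
max period 90. Reruns with identical inputs are byte-identical.

Applying the pipeline to real centromeres is a plain invocation on the
assembly FASTA (e.g. a complete Y chromosome); note that the shipped
consensus monomer is a synthetic stand-in — supply your preferred
published alpha-satellite consensus with `--consensus` for real data.

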