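# mtqc

Quality assessment of mitochondrial-genome massively parallel sequencing
(MPS) data. The package computes per-position pileup statistics on a
circular reference — strand-bias ratios, deletion ratios ("false
deletion" profiling), coverage segmentation into relatively high/low
regions with homopolymer and interrupted-C-tract association — and
compares variant lists from two sequencing platforms after
canonicalizing indel representations (left alignment on the circle). A
fully deterministic simulator generates references, pileups, alignment
files and haplotype pairs with known ground truth so that every stage is
testable offline.

The revised Cambridge Reference Sequence (rCRS, NC_012920.1; 16,569 bp
with the historical placeholder at position 3107) is bundled as plain
FASTA under `src/mtqc/data/`.

## Modules

| module | purpose |
| --- | --- |
| `mtqc.reference` | circular reference loading, homopolymer runs, interrupted C-tracts (CnXCn), run-class counting |
| `mtqc.pileup` | strand-resolved per-position counts from SAM/BAM or the pileup TSV dialect |
| `mtqc.metrics` | strand-bias ratio min/max, deletion ratio, multi-sample summaries, high-DR site flagging |
| `mtqc.regions` | high/low coverage segmentation, homopolymer x region contingency, motif association, primer-site gap detection |
| `mtqc.concordance` | indel left-alignment on a circular genome, VCF/diff-table IO, cross-platform concordance buckets |
| `mtqc.simulate` | ground-truth simulators for references, pileups, SAM files and haplotype pairs |
| `mtqc.cli` | `mtqc` command: `simulate`, `pileup`, `metrics`, `regions`, `concord`, `report`, `run-all` |

## CLI quick start

```bash
cat > conf.yaml <<'EOF'
simulate:
  seed: 42
  genome_length: 16569
  n_samples: 24
  coverage_mean: 810
  coverage_sd: 664
  placeholder_position: 3107
  dips: [[2000, 2150, 0.3], [621, 622, 0.07]]
  planted_runs: [[C, 2050, 5], [G, 7000, 2]]
  dr_sites: [[800, 0.3]]
  n_discordant: 5
EOF
mtqc run-all --config conf.yaml --outdir out/
```

`out/` then holds the synthetic reference, per-sample pileup TSVs,
per-position metrics, flagged deletion-ratio sites, coverage regions,
the homopolymer contingency table, the concordance report and a combined
`report.json`. Re-running with the same seed reproduces every artifact
byte for byte; `--seed` overrides the config seed. The same pipeline
runs on real data by replacing the `simulate` section with an `inputs`
section pointing at a FASTA reference, pileup TSVs (or `mtqc pileup` on
a BAM), and optional variant lists.

Key defaults (all configurable under `analysis:`): strand-bias balance
threshold 0.5, extreme-bias threshold 0.1, deletion-ratio flag threshold
0.15 (strict), high/low coverage thresholds 810X/500X, concordance
exclusion zones 302-316 and 16180-16195, inconclusive repeat zone
514-524.

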