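# rtcrispr

Discovery, annotation and classification of reverse-transcriptase-associated
CRISPR-Cas loci, tested end to end on synthetic genomes with planted ground
truth.

Some CRISPR-Cas adaptive immune systems carry a reverse transcriptase (RT)
gene — often fused to `cas1` or to both `cas6` and `cas1` — next to the
adaptation module, allowing spacer acquisition from RNA. This package
implements the computational side of surveying such systems:

- **protein handling** — end-gap-free global identity, greedy longest-first
  dereplication at ≤85% identity, consensus building, and a local-alignment
  search with Karlin–Altschul e-values (`rtcrispr.sequence`);
- **CRISPR arrays** — repeat/spacer detection and a three-criterion
  orientation cascade: intrinsic leader signal (AT-richness + terminal repeat
  degeneracy, banded H/M/L), exact match to an oriented repeat database, and
  ≥90% identity to an already-oriented array (`rtcrispr.arrays`);
- **locus annotation** — ORF calling, cas-family annotation against a
  consensus-profile library, RT fusion-domain architecture
  (RT / RT-Cas1 / Cas6-RT-Cas1), locus extraction by bidirectional chaining
  with a strict <5 kb gap rule, and Type III effector subtype classification
  (`rtcrispr.loci`);
- **phylogeny** — neighbor-joining trees with bootstrap bipartition
  supports, support-thresholded clade delimitation with CRISPR-purity and
  phylum-based subclade splitting, consensus membership screening, per-label
  monophyly, and partition congruence between protein trees
  (`rtcrispr.phylo`);
- **synthetic benchmarks** — genome/cohort generators that plant loci,
  arrays, decoy genes, protein families with controlled identity ladders,
  and clade-structured trees, every planted element recorded in a ground
  truth ledger (`rtcrispr.synth`);
- **pipeline + CLI** — a deterministic end-to-end pipeline driven by a YAML
  config, exposed as the `rtcrispr` command (`rtcrispr.pipeline`,
  `rtcrispr.cli`).

The shipped profile library and repeat database are synthetic stand-ins
(`src/rtcrispr/data/synthetic_cas_profiles.faa`,
`synthetic_repeat_db.tsv`): random consensus sequences audited for mutual
dissimilarity. They carry no biological signal, but planted genes are derived
from them, so annotation behaves exactly like consensus-based profile search.

## Worked example

Generate a genome with one planted Type III-B/C locus whose RT is a
Cas6-RT-Cas1 fusion, then run the pipeline on it:

```bash
cat > spec.yaml <<'EOF'
length_bp: 25000
loci:
  - subtype: III-B/C
    gene_order: [cas10, cmr1, cmr3, cmr4, cmr5, cmr6, Cas6-RT-Cas1, cas2]
    fusion_class: Cas6-RT-Cas1
    array_spec:
      repeat_seq: GTTTCAGACGAACCCTTGTAGGGTTGAAGC
EOF
rtcrispr synth --spec spec.yaml --seed 11 --out synth
# wrote genome of 25000 bp with 1 loci to synth

cat > run.yaml <<'EOF'
genome_fasta: synth/genome.fasta
out_dir: out
bootstrap_n: 25
EOF
rtcrispr run --config run.yaml --seed 1
# {"n_loci": 1, "n_arrays": 1, "clades": []}
```

`out/loci.tsv` then contains the recovered locus with the correct fusion
class, subtype and gene architecture:

```text
contig            start  end    rt_tag      n_cas_genes  n_arrays  rt_linked_array  fusion_class  subtype  clade       architecture
synthetic_contig  379    11846  orf_7487_+  8            1         True             Cas6-RT-Cas1  III-B/C  unassigned  cas10-cmr1-cmr3-cmr4-cmr5-cmr6-RT-Array-cas2
```

and `out/arrays.tsv` the detected array, oriented by the intrinsic leader
criterion (band H, criterion i):

```text
contig            start  end    n_repeats  repeat_consensus                orientation  band  criterion
synthetic_contig  10885  11248  6          GTTTCAGACGAACCCTTGTAGGGTTGAAGC  forward      H     i
```

Running `rtcrispr run` again with the same config and seed reproduces every
output file byte for byte. Individual stages are also available as
subcommands (`rtcrispr detect-arrays`, `annotate`, `extract-loci`,
`clades`, `report`).

## Layout

```
src/rtcrispr/      package (sequence, arrays, loci, phylo, synth, pipeline, cli, io, profiles)
src/rtcrispr/data/ synthetic profile library + repeat database (text fixtures)
tests/             pytest suite, oracles, acceptance-criterion tests
scripts/           acceptance.py (headline metrics)
docs/methods.md    model, parameters, numerical choices, limitations
```
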