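# grnpipe

Transcriptional-regulator discovery on expression data, packaged as a tested,
reusable pipeline:

1. **GRN reconstruction** (`grnpipe.grn`) — signed gene–gene similarity
   (Spearman / Kendall / signed mutual information), a threshold scan that
   compares each candidate network's mean clustering coefficient against the
   density-matched random-graph expectation, and a sign-directed 0/1
   adjacency (positive similarity directs the edge one way, negative the
   other), plus degree-based hub ranking.
2. **Regulon inference** (`grnpipe.regulons`) — per-TF Spearman association
   against every gene, empirical p-values from permuting the TF's sample
   labels, Benjamini–Hochberg within each TF, targets split into positively
   and negatively associated sets.
3. **Coregulator identification** (`grnpipe.coregulation`) — hypergeometric
   shared-target overlap between TF regulons, BH-corrected across all pairs.
4. **Target filtering** (`grnpipe.target_filtering`) — database candidate
   union → "functional" targets (DE in studies where the TF is up) →
   "direct" targets (not DE in studies where the TF is absent; a
   direction-flip criterion is selectable).
5. **Motif elicitation** (`grnpipe.motifs`) — strand-aware 1000-nt upstream
   extraction from genome FASTA + BED, one-occurrence-per-sequence EM motif
   discovery over widths 6–20 with shift refinement and a shuffled-data
   significance check, and PWM comparison against a JASPAR-style database
   with reverse-complement awareness and an empirical column-shuffle null.
6. **Synthetic data** (`grnpipe.synthetic`) — every input above can be
   generated with recorded ground truth (planted signed TF→target effects,
   per-study DEG status, planted motif sites), so the whole pipeline is
   testable offline.
7. **Orchestration** (`grnpipe.pipeline`) — one YAML config drives all
   stages and writes a JSON manifest; outputs are byte-reproducible for a
   fixed seed.

## CLI

```sh
grnpipe simulate --out sim --seed 7                 # synthetic input bundle
grnpipe grn reconstruct --expr sim/expression.tsv --method spearman --out grn_out
grnpipe regulons infer --expr sim/expression.tsv --tfs sim/tf_list.txt \
    --n-perm 1000 --fdr 0.05 --seed 7 --out reg_out
grnpipe coreg --regulons reg_out/regulons.tsv --universe sim/tf_list.txt \
    --alpha 0.05 --out coreg_out
grnpipe targets cascade --candidates sim/candidates --deg sim/deg_tables.tsv \
    --policy any --out cascade.tsv
grnpipe motifs discover --fasta sim/promoters.fa --wmin 6 --wmax 20 \
    --nmotifs 2 --seed 7 --out motifs.meme
grnpipe motifs compare --query motifs.meme --db sim/pwm_db.pfm --out matches.tsv
grnpipe pipeline run --config config.yaml --out run_out
```

A minimal pipeline config:

```yaml
expression: sim/expression.tsv
tf_list: sim/tf_list.txt
deg_tables: sim/deg_tables.tsv
candidates: sim/candidates
promoters: sim/promoters.fa
pwm_db: sim/pwm_db.pfm
n_perm: 1000
fdr: 0.05
seed: 7
```

Stages whose inputs are omitted are skipped and recorded as such in
`manifest.json`.

## File formats

All formats are plain text: expression as TSV with a sample header row and a
group-label row, DEG tables as TSV (gene, direction, study_id, tf_status),
candidate lists as one-column TSV, promoters as FASTA, motif databases as
JASPAR-style PFM, discovered motifs as minimal MEME text, networks as edge
TSV + GraphML.

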