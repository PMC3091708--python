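# ventannot

Annotation triage for de novo transcriptomes of non-model organisms —
built around the gill-transcriptome analysis of the deep-sea
hydrothermal vent mussel *Bathymodiolus azoricus*. Given assembled
contigs and ranked protein-homology hit tables, the package:

- cleans contigs (adapter trimming, terminal poly-A/T masking, 40-bp
  effective-length gate);
- assigns reading frames by a three-tier cascade — strict homology
  (E ≤ 10⁻⁶), relaxed homology (E ≤ 10⁻²), then a codon-usage log-odds
  coding scan trained on the homology-called frames, with a
  null-calibrated score threshold and a 30-amino-acid peptide floor;
- counts GO annotations per broad category by DAG propagation with
  once-per-product deduplication;
- screens hits for bacterial origin by taxonomy lineage walks and builds
  the cumulative bacterial best-hit-rank curve (ranks 1–20) with plateau
  detection — the "bacterial fingerprint" of endosymbiont-rich tissue;
- compares two protein databases under E-value/bit-score gates and
  reports per-category shared-GO percentages;
- quantifies relative expression from qPCR Ct replicates by the
  comparative-CT (ΔΔCt) method, fold = 2^(−ΔΔCt).

A synthetic-data module generates every input with planted ground truth
(ORFs under a configurable codon-usage table, UTRs, poly-A tails,
adapter contamination, ranked hits with frames and taxids, a multi-root
ontology DAG, a rooted taxonomy), so the whole pipeline is testable
offline. See `docs/methods.md` for the model details and assumptions.

## Worked example

```python
from ventannot import (SimulationConfig, PipelineConfig, CascadeParams,
                       run_pipeline)

cfg = PipelineConfig(simulation=SimulationConfig(seed=1),
                     cascade=CascadeParams(seed=1))
result = run_pipeline(cfg, "out/")
print(result.cascade.accounting)
print({k: round(v, 3) if isinstance(v, float) else v
       for k, v in result.evaluation.items()})
```

prints (seed 1, 1,000 contigs, half of them coding):

```
{'strict': 236, 'relaxed': 45, 'scan': 209, 'unassigned': 510, 'total_translated': 490}
{'n_coding_kept': 489, 'n_noncoding_kept': 511, 'frame_recovery': 0.978,
 'noncoding_false_call_rate': 0.002, 'codon_usage_l1': 0.066,
 'bacterial_fraction_planted': 0.16, 'bacterial_fraction_recovered': 0.171,
 'plateau_value': 48, 'plateau_rank': 11, 'plateau_converged': True,
 'hit_bearing_queries': 281}
```

Reading it: of 489 kept contigs with a planted ORF, 490 contigs in all
were translated (236 strict-homology, 45 relaxed, 209 by the coding
scan, including a handful of false non-coding calls) and 97.8%
received their true frame; 0.2% of non-coding contigs were false-called
at the null-calibrated threshold; the bacterial best-hit-rank curve
converged at rank 11 to 48 of 281 hit-bearing queries (17.1%, planted
16%). Per-stage artifacts (clean FASTA, hit table, frame calls, peptide
FASTA, GO category report, rank curve, manifest) land in `out/`.

The same flow is available from the shell:

```bash
ventannot simulate --seed 1 --n-contigs 1000 --out out/
ventannot preprocess --contigs out/contigs_raw.fasta --adapters adapters.txt --out clean.fasta
ventannot frames --contigs clean.fasta --hits out/hits.tsv --out-calls calls.tsv
ventannot goanno --obo out/ontology.obo --assignments go.tsv --out go_report.tsv
ventannot taxscreen --hits out/hits.tsv --nodes out/nodes.dmp --names out/names.dmp --out curve.tsv
ventannot ddct --table ct.tsv --reference 28S --calibrator gene1 --out folds.tsv
```

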