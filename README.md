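# mitonet

Network analysis of quantitative mitochondrial proteomics under mtDNA
depletion.

When a cell loses its mitochondrial DNA (a ρ⁰ state, induced e.g. by
long-term ethidium bromide exposure), the nuclear-encoded mitochondrial
proteome reorganizes: proteins serving basal mitochondrial functions fall,
while machinery for protein expression, folding, transport and DNA repair
rises. `mitonet` implements the computational side of such a study as a
reusable, tested pipeline for systems biologists working with quantitative
organelle proteomics:

1. **Regulation classification** — each protein's linear abundance ratio
   ρ⁰/ρ⁺ is called *up* (ratio ≥ 1.5), *down* (ratio ≤ 0.67, a 1.5-fold
   decrease) or *unchanged*.
2. **Reliability tiering** — identified proteins are kept only with
   independent evidence of mitochondrial localization: presence in the
   organelle cellular-component annotation **and** in ≥ 1 reference
   catalog, or a single-hop physical / functional link to such a reference
   protein (physical evidence takes precedence; tiers are disjoint).
3. **Functional network statistics** — the reliable proteins induce a
   weighted undirected graph (STRING-style confidence scores in [0, 1],
   physical/functional channel flags); analysis runs on the largest
   connected component. Edges are *intra*-regulatory (up–up or down–down),
   *inter*-regulatory (up–down) or *other*. Per-protein link-type
   fractions and same-class vs opposite-class breadth-first shortest-path
   lengths are compared with a Mann–Whitney U test (mid-rank ties,
   tie-corrected normal approximation, exact enumeration for pooled
   n ≤ 12).
4. **Module detection** — average-linkage (UPGMA) hierarchical clustering
   with edge confidence as similarity (0 for absent pairs), cut when the
   best mean cross-pair similarity drops below τ. A cluster becomes a
   *functional module* if it is enriched both for an annotation term and
   for one regulation class (one-sided hypergeometric upper tail,
   P(X ≥ k) with X ~ Hypergeom(N, K, n), p < 0.01 each).
5. **Proteome–transcriptome concordance** — replicated microarray
   intensities are log₂-transformed, quantile-normalized and
   detection-p-filtered (p > 0.05); per-gene mRNA log₂ ratios join the
   protein log₂ ratios, and k-means (k = 5) partitions the 2-D profiles
   into up_up / down_down / up_down / down_up / unchanged concordance
   groups labeled from centroid geometry.

A seeded **synthetic-world generator** plants modules (stochastic block
model), regulation classes, reference-catalog membership, annotation terms
and concordance patterns, so the whole pipeline is testable end to end
without external databases.

## Worked example

```python
from mitonet.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(simulate_seed=1))
print(report["classification"])
print(report["reliability"]["reliable"])
print(report["links"]["intra_pct_of_regulatory"])
print(report["modules"]["n_modules"], report["modules"]["coverage"])
print(report["concordance"]["group_sizes"])
```

prints (seed 1, default synthetic world of 810 proteins):

```
{'n_total': 810, 'n_up': 144, 'n_down': 224, 'n_unchanged': 442,
 'percentages': {'up': 17.78, 'down': 27.65, 'unchanged': 54.57}}
{'count': 692, 'percent': 85.43}
69.0
14 {'up': {'covered': 77, 'total': 143, 'percent': 53.85},
    'down': {'covered': 127, 'total': 224, 'percent': 56.7}}
{'up_up': 129, 'down_down': 37, 'up_down': 33, 'down_up': 205, 'unchanged': 378}
```

Reading: of 810 quantified proteins, 692 (85.43%) carry independent
evidence of mitochondrial localization; on the major network component
69.0% of the regulatory links connect proteins of the same regulation
class, and 14 clusters pass the double enrichment rule (the 13 planted
modules, one of them split). The concordance partition shows the planted
asymmetry: the dominant group (down_up, 205 proteins) holds proteins whose
mitochondrial levels fall while their transcripts rise — the compensatory
transcription a depleted cell mounts when protein import falters.

The same chain is scriptable from the shell:

```bash
mitonet simulate --seed 1 --out world/
mitonet classify --abundance world/abundance.tsv --out classified.tsv
mitonet run --config pipeline.yaml
```

(`mitonet run` consumes a YAML `PipelineConfig`; see also the `filter`,
`network`, `modules`, `concordance` and `report` subcommands.)

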