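# barcodegap

DNA-barcode cryptic-lineage analysis for single-marker (COI) surveys:
Kimura-2-parameter distances and barcode-gap summaries, neighbor-joining
trees with bootstrap supports, haplotype collapsing and
statistical-parsimony networks, and rule-based flagging of deeply
divergent conspecific lineages — plus a seeded synthetic-study generator
so every stage can be exercised and scored against a known truth.

## The problem

DNA barcoding identifies specimens from a short standardized marker
(typically ~600 bp of mitochondrial COI).  Identification works when a
**barcode gap** separates conspecific from congeneric divergence; the
interesting failures are nominal species that harbour *deeply divergent
conspecific lineages* — candidate cryptic species.  Two rules of thumb
dominate the literature:

* the **2% cutoff** — specimens of one species separated by ≥ 2% K2P
  distance are unlikely to be conspecific;
* the **10X rule** — flag when conspecific divergence reaches 10× the
  mean intraspecific variability of the group.

This package implements the full analysis chain a barcode survey runs
around those rules, for users who want it scripted, seeded and testable
rather than spread across MEGA/DnaSP/TCS-style GUI tools.

## The statistics

**K2P distance.** With `P` and `Q` the proportions of sites differing by
a transition and a transversion,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

(gaps/ambiguities excluded; complete or pairwise deletion).  Standard
errors come from a nonparametric site bootstrap.

**Tree.** Saitou–Nei neighbor joining on the Q-criterion with
deterministic tie-breaks; Felsenstein bipartition supports from B
column-resampled pseudo-replicates; per-species monophyly via
bipartition scan.

**Haplotypes.** Exact-match collapsing; Nei's haplotype diversity
`Hd = n(1 - Σ pᵢ²)/(n - 1)`; variable and parsimony-informative sites;
base composition.

**Network.** Minimum-spanning network over haplotype mutational steps,
cut at the 95% statistical-parsimony connection limit (8 steps at
573 bp under the package's site-collision model); disconnected
subnetworks are unconfirmed candidate species.

**Delimitation.** Lineages = single-linkage clusters under the cutoff;
a species is flagged for deep conspecific divergence when it splits at
the cutoff **or** across subnetworks, with the 10X rule and
bootstrap-supported subclades reported as corroborating evidence.

## Worked example

```python
import barcodegap as bg

result = bg.simulate(bg.preset("pencilfish-like", seed=42))
dm  = bg.distance_matrix(result.alignment)
gap = bg.gap_summary(dm, result.records)
```

The preset emulates a 14-species, 110-specimen, 573-bp genus survey in
which four species hide 2–5 divergent lineages.  Running the bundled
examples prints (seed 42):

```
conspecific  min  0.00%  mean  4.36%  max 21.03%  sd 4.97%  (507 pairs)
congeneric   min 10.61%  mean 19.22%  max 38.97%  sd 5.22%  (5488 pairs)

connection limit j* = 8 steps -> 27 independent subnetworks
species split across multiple subnetworks (candidate species):
  digrammus       4 independent networks
  eques           5 independent networks
  trifasciatus    5 independent networks
  unifasciatus    3 independent networks

flagged for deep conspecific divergence: ['digrammus', 'eques', 'trifasciatus', 'unifasciatus']
```

The conspecific mean (4.4%) sits far above the < 1% typical of clean
species precisely because four species carry hidden lineages; their
haplotypes cannot be connected within the parsimony limit, every species
is nonetheless monophyletic with 100% bootstrap support on its stem, and
the report flags exactly the four seeded species — the ten clean ones
show a single lineage and a single subnetwork each.

The narrative scripts in `examples/` walk one capability each:
simulation, distances/barcode gap, tree/bootstrap/monophyly, haplotype
networks, and the end-to-end delimitation pipeline.  A thin CLI mirrors
the pipeline:

```bash
barcodegap simulate --preset pencilfish-like --seed 42 --outdir study/
barcodegap run --alignment study/alignment.fasta --metadata study/metadata.tsv \
               --bootstrap 1000 --seed 42 --outdir out/
```

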