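# mutascope

Post-variant-calling analysis of drug mutagenicity in clonal
mutation-accumulation experiments.

When cultured cell clones are exposed to a compound and daughter
subclones are whole-genome sequenced, the question is whether the
exposure left a mutational footprint: an excess mutation burden, a
distinctive mutational signature, true doublet substitutions, biased
placement across chromatin and replication context, and a propensity to
damage coding genes. `mutascope` implements the downstream analysis of
such experiments, starting from somatic variant calls:

* **Catalogs** — per-subclone de novo mutation catalogs over the
  standard channel sets (SBS96 substitutions, DBS78 doublets, ID83
  indels), after the clonality filters used for subclone data: variants
  kept at VAF > 0.2, samples with mean VAF < 0.4 flagged polyclonal and
  excluded from quantitation, parental/shared mutations subtracted.
  Duplex-sequencing burdens (mutations per Mb of informative duplex
  bases, variants at VAF < 0.01) are computed from the same module.
* **Signatures** — treatment signatures derived by background
  subtraction: controls are aggregated into a background signature
  *b*; bootstrap resampling of *b* across mutation burdens gives the
  expected cosine-similarity envelope (mean ± sd per burden); a treated
  catalog *t* carries a novel signature when
  cos(*t*, *b*) < mean(*n*) − k·sd(*n*) at its burden *n* (k = 3);
  the signature is the renormalized residual
  max(0, *t* − *n*₀·*b*) with *n*₀ the expected background count.
* **Doublet null** — a permutation test for whether observed adjacent
  double substitutions could be chance co-occurrence of independent
  substitutions: substitutions are re-placed genome-wide (uniformly or
  context-matched), adjacent placements are paired into chance
  doublets, and the observed count and DBS78 spectrum are compared with
  that null (fold enrichment, p-value, cosine).
* **Topography** — mutation-centered 2-kb profiles of G-quadruplex
  motifs (consensus G≥3N₁₋₇G≥3N₁₋₇G≥3N₁₋₇G≥3, both strands) and
  nucleosome signal; replication-timing decile distributions with a
  bootstrap of context/proximity-matched simulated mutations; and
  transcriptional / replicative strand asymmetry per substitution class
  with exact binomial tests, BH-adjusted.
* **Damage potential** — for a gene set, every possible coding and
  splice-site substitution is enumerated per SBS96 channel; a
  signature's propensity for stop-gain / missense / synonymous /
  splice-site changes is its weighted ratio normalized to a flat
  signature (a value of 2 = twice as likely as random), plus a
  flat-normalized blosum62 severity score for missense changes.
* **Synthetic studies** — a generator that emits a complete toy study
  (genome with planted G4s, nucleosome/timing/gene/replication tracks,
  parental clones and subclones, VCFs) in which every one of the above
  quantities is planted and recorded, so the whole pipeline is testable
  against ground truth.

## Worked example

A small synthetic study: one genotype, vehicle arm versus treated arm,
three subclones each, on a 500 kb genome with planted topography biases.

```python
import numpy as np
from mutascope.synthdata import StudyConfig, generate_study
from mutascope.catalogs import (build_catalog, filter_vaf, flag_polyclonal,
                                subtract_parental, pair_doublets)
from mutascope.signatures import (aggregate_background, bootstrap_envelope,
                                  detect_novel_signature, subtract_background,
                                  cosine_similarity)
from mutascope.topography import (scan_g4, profile_g4_enrichment,
                                  simulate_matched_mutations)

config = StudyConfig(
    genome_length=500_000, n_genes=40, gene_length=3000, g4_density=2e-4,
    genotypes=("WT",), n_subclones=3,
    sbs_burden={"DMSO": 500, "CX": 8000},
    dbs_burden={"DMSO": 5, "CX": 80},
    indel_burden={"DMSO": 50, "CX": 150},
    n_parental=100,
)
study = generate_study(config, seed=17)

catalogs = {}
for name, calls in study.samples.items():
    arm = ".".join(name.split(".")[:2])
    denovo = filter_vaf(subtract_parental(calls, study.parental[arm]))
    poly, mean_vaf = flag_polyclonal(denovo)
    catalogs[name] = build_catalog(denovo, study.genome, name)

controls = [catalogs[s] for s in study.arm_samples("WT", "DMSO")]
treated = [catalogs[s] for s in study.arm_samples("WT", "CX")]
background = aggregate_background(controls, "sbs")
envelope = bootstrap_envelope(background, seed=17)
det = detect_novel_signature(treated[0], background, envelope)
agg = np.sum([c.sbs96 for c in treated], axis=0)
bg_burden = np.mean([c.n_sbs for c in controls]) * len(treated)
derived = subtract_background(agg, background, bg_burden)
```

This prints, per subclone, the catalog totals and clonality check, then
the detection decision and recovery quality:

```
WT.DMSO.s1: 500 SBS, 5 DBS, 50 indels, mean VAF 0.50, polyclonal=False
...
WT.CX.s1: 8000 SBS, 80 DBS, 150 indels, mean VAF 0.50, polyclonal=False
treated vs background: cosine 0.311 < threshold 0.992 -> novel signature: True
cosine(derived signature, planted treatment signature) = 0.9998
G4 enrichment at mutation sites: 0.30 (context-matched control: 0.66)
```

Reading the numbers: treated subclones carry 16× the control
substitution burden; their profile is far from the background envelope
(cosine 0.31 against a 0.99 threshold), so a treatment signature is
declared and recovered essentially perfectly (cosine 0.9998 to the
planted truth). Mutations are depleted at G-quadruplexes (enrichment
0.30 at the mutation position) beyond what the context-matched
simulation explains (0.66, a purely compositional dip).

The same steps are available from the shell:

```
mutascope simulate --config study.json --seed 17 --out study/
mutascope catalog --vcf study/WT.CX.s1.vcf --fasta study/genome.fa \
    --sample WT.CX.s1 --parental study/WT.CX.parental.vcf --out cat/
mutascope dbs-null --variants study/WT.CX.s1.vcf --fasta study/genome.fa \
    --n-perm 1000 --seed 17 --out null.json
mutascope topo g4 --variants ... ; mutascope topo strand --variants ...
mutascope signature --catalogs cat/catalog.sbs.tsv --controls c1,c2 --out sig.json
```

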