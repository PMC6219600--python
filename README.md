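# polydart

DArTseq marker analysis of allopolyploid genome composition in Triticeae.

Allopolyploid species such as bread wheat (*Triticum aestivum*, genomes
ABD) and the polyploid *Aegilops* species combine the chromosome sets of
two or more diploid progenitors. `polydart` infers those progenitors from
genotyping-by-sequencing marker tables: dominant **SilicoDArT** markers
(presence/absence of restriction-fragment tags, scored 1/0) and codominant
**SNP** markers (scored 0/1/2). It is aimed at plant geneticists analysing
DArTseq exports for wheat relatives or any polyploid complex with a
reference-assigned marker panel, and at anyone who wants the full workflow
runnable end to end on synthetic data.

## What it computes

For a panel of diploid *analyzers* and polyploid *targets*:

1. **Call-rate filtering** — keep markers with call rate > 0.7
   (SilicoDArT) or > 0.9 (SNP).
2. **Species-specific markers** — markers present in exactly one species
   and absent in all others; per-species totals and percentages.
3. **Homoeology screening** — percentage of each diploid's markers
   assigned (via 1A–7D chromosome labels) to each bread-wheat subgenome,
   relative to the reference's own subgenome totals; species with ≥ 10%
   on any subgenome become analyzers.
4. **Retention (diploid–polyploid monomorphism)** — for analyzer set S and
   target presence set T, retention = |S ∩ T| / |S|. High retention of a
   diploid's specific markers marks it as a putative subgenome donor.
5. **Progenitor calls** — the top ploidy/2 analyzers by retention fill the
   subgenome slots; candidates within a margin (default 0.10) of the last
   slot produce an *unresolved* slot (an ancestral/extinct donor) instead
   of a forced pick. Per-chromosome retention profiles localize the signal.
6. **Clustering** — Pearson's r between raw SNP score vectors, transformed
   to d = 100(1 − r), then classical UPGMA with deterministic
   lexicographic tie-breaking; trees serialize to Newick.

A synthetic-data module (`polydart.simulate`) generates marker panels with
known ancestry — markers evolving down a species tree by loss and private
gain, polyploids as parental unions with post-merger loss — so every stage
is testable without any download. See `docs/methods.md` for the model,
parameter defaults and limitations.

## Worked example

```python
from polydart import (simulate_panel, triticeae_like_config, retention_table,
                      call_progenitors, specificity_report)

result = simulate_panel(triticeae_like_config(seed=1))
panel = result.panel
markers = result.markers.filter_call_rate(0.7)

diploids = panel.species_with_role("diploid_analyzer")
print(specificity_report(markers, panel, diploids).head(4))

table = retention_table(markers, panel, diploids,
                        panel.species_with_role("polyploid_target"))
call = call_progenitors(table.column("T01"), panel.ploidy_of("T01"),
                        margin=0.10, target="T01")
print("T01 progenitors:", call.selected)
print("truth:", result.truth.polyploids["T01"]["parents"])
```

prints

```
         total  specific  specific_pct
species
A1        8131       522          6.42
A2        8110       524          6.46
B1        8113       508          6.26
S1        8229       520          6.32
T01 progenitors: ['D1', 'U1']
truth: ['D1', 'U1']
```

Each diploid carries ~8 100 markers of which ~520 are species-specific;
the tetraploid `T01` is correctly traced to its generating parents D1 and
U1. For a polyploid descended from the *hidden* donor H (pruned from the
panel, mimicking an extinct progenitor), the second slot is reported
unresolved rather than mis-assigned:

```
X01 selected: ['U1']
X01 unresolved candidates: ['A1', 'A2', 'B1', 'D1', 'D2'] ...
```

The same pipeline runs from the shell:

```sh
polydart simulate --seed 1 --outdir sim
polydart all --silicodart sim/silicodart.csv --snp sim/snp.csv \
             --panel sim/panel.csv --outdir out
```

writing specificity/homoeology/retention CSVs, progenitor calls as JSON,
chromosome profiles and UPGMA trees in Newick under `out/`.

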