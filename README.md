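# barcodeval

Evaluation of multi-locus DNA-barcode reference libraries for species
identification, built for plot-based floristic inventories (tropical
tree plots in particular) where each specimen carries a field
identification, a plot label, and aligned sequences for some subset of
barcode loci such as *rbc*L, *mat*K, *trn*H–*psb*A and ITS.

The package answers the questions such a library is built to answer:

* **Sequence recovery** — how many specimens yielded a sequence per
  locus, and for at least one locus.
* **Tree-based resolution** — concatenate per-locus alignments into a
  partitioned supermatrix (with block-diagonal handling for loci that
  can only be aligned within families), build a Neighbor-Joining tree
  with nonparametric bootstrap, and score each species, genus and
  family by *supported monophyly*: all its sampled members (≥ 2) form
  an exclusive clade whose bipartition has bootstrap support ≥ 50%.
* **Similarity-based identification** — each sequence is queried
  against a reference database under the rule: an assignment is correct
  when the query is ≥ 95% identical to a sequence of its own species
  *and* every database sequence of the best-matching species is
  strictly more identical than every sequence of any other species.
  Both leave-one-out (every sequence serves as database and query) and
  cross-plot designs (one plot is the database, other plots supply the
  queries, filtered to shared taxa) are supported.
* **Misidentification auditing** — the algorithmic half of reciprocal
  illumination: flag every leaf whose smallest enclosing clade on the
  core-barcode tree contains no conspecific, gate the flag on bootstrap
  support, classify the conflict as family-, genus- or species-level
  from the clade's majority taxonomy, and summarise rates and level
  shares.
* **Synthetic campaigns** — a generator producing datasets with the
  statistical structure the analyses assume: nested taxonomy, an
  ultrametric taxonomy-concordant tree with a controllable barcode gap
  (intraspecific vs interspecific divergence), Jukes–Cantor sequence
  evolution, per-locus Bernoulli recovery, multi-plot allocation with
  optional extra between-plot divergence, and injectable
  misidentifications at the family/genus/species level — so the whole
  pipeline is testable without any sequence download.

## Worked example

Simulate a small three-family campaign with an 8% field-error rate and
run the full pipeline:

```python
import barcodeval as bv

sim = bv.SimConfig(
    n_families=3, genera_per_family=2, species_per_genus=2,
    samples_per_species=(2, 3),
    loci=(
        bv.LocusConfig("rbcL", 700, recovery_rate=0.95),
        bv.LocusConfig("matK", 800, recovery_rate=0.85),
        bv.LocusConfig("trnH-psbA", 500, recovery_rate=0.9, family_blocks=True),
    ),
    misid_rate=0.08, seed=7,
)
config = bv.PipelineConfig(sim=sim, bootstrap_replicates=100, seed=7,
                           outdir="example_out")
result = bv.run_pipeline(config)

rec = result.recovery
print("specimens:", rec.n_specimens)
print("any-marker recovery:", f"{rec.any_marker_percent}%")
for rep in result.resolution:
    if rep.rank == "species":
        print(f"resolution {rep.label:18s} species {rep.supported}/{rep.eligible} = {rep.rate}%")
for rep in result.loo_reports:
    print(f"LOO {rep.label:22s} species {rep.species_rate}%  genus {rep.genus_rate}%")
print("audit:", result.audit.n_flagged, "flagged of", result.audit.n_audited,
      "=", f"{result.audit.flag_rate}%", result.audit.level_counts)
print("ratios:", result.ratios)
```

which prints (abridged to the first resolution/LOO rows):

```
specimens: 29
any-marker recovery: 100.0%
resolution rbcL               species 8/10 = 80.0%
resolution rbcL+matK          species 8/10 = 80.0%
LOO rbcL                   species 73.1%  genus 67.9%
LOO rbcL+matK              species 74.1%  genus 69.0%
audit: 4 flagged of 28 = 14.3% {'family': 4}
ratios: {'individuals': 29, 'genera': 6, 'species': 12, 'I_G': 4.8, 'S_G_1dp': 2.0, 'S_G_2dp': 2.0}
```

Reading the numbers: 8 of the 10 species sampled twice or more are
recovered as supported monophyletic clades on the *rbc*L tree (80.0%);
leave-one-out identification under the ≥95%/dominance rule succeeds for
73.1% of *rbc*L queries at species level; and the audit flags 4 of 28
leaves on the core-barcode tree — the two specimens whose labels were
corrupted by the generator plus their stranded partners, all at family
level, which is exactly what a reviewer would take to the herbarium.
The I/G and S/G values are the clade-richness ratios
(individuals/genera and species/genera) that contextualise
identification success across floras.

The report bundle (`recovery.json`, `resolution.tsv`,
`assignment_loo.tsv`, `assignment_crossplot.tsv`, `shared_taxa.tsv`,
`audit_flags.tsv`, `audit_summary.json`, `intraspecific_variation.tsv`,
`ratios.json`, Newick trees, and a manifest) is written to `outdir`.
The same pipeline runs from the command line on real files:

```sh
barcodeval run --config pipeline.yaml
barcodeval simulate --config sim.yaml --out data/
barcodeval assign --meta data/specimens.tsv --locus rbcL=data/rbcL.fasta \
    --threshold 0.95 --mode loo --out loo.tsv
barcodeval resolve --meta data/specimens.tsv --locus rbcL=data/rbcL.fasta \
    --locus matK=data/matK.fasta --replicates 1000 --out resolution.tsv
barcodeval audit --meta data/specimens.tsv --locus rbcL=data/rbcL.fasta \
    --locus matK=data/matK.fasta --out flags.tsv
```

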