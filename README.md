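# barcodeaudit

Audit toolkit for DNA barcode reference libraries.

When a regional reference library of COI barcodes is assembled — hundreds
of species, a handful of sequenced specimens each — the central question is
*which species can actually be told apart by their barcodes*, and which
ones need taxonomic re-examination. `barcodeaudit` answers that question
for an aligned barcode library, reproducing the standard evaluation
procedure used for such libraries:

* **K2P divergences** — pairwise Kimura 2-parameter distances with
  pairwise deletion, `d = -½ ln((1 − 2P − Q)·√(1 − 2Q))`, where `P` and
  `Q` are the transition and transversion proportions over the sites where
  both sequences carry an unambiguous base.
* **Neighbour-joining tree** — classic Saitou–Nei agglomeration
  (deterministic tie-breaking, negative branches clamped with the deficit
  moved to the sibling edge), with outgroup or midpoint rooting and Newick
  output.
* **Species diagnosability** — a species succeeds when its barcodes form a
  monophyletic cluster and are not shared with other species; failures are
  classified into five mutually exclusive conditions (paraphyletic,
  polyphyletic, identical barcodes, overlapping barcodes,
  identical-and-overlapping).
* **Barcode gap & deep splits** — intraspecific vs congeneric
  interspecific divergence distributions; species whose specimens break
  into ≥ 2 single-linkage clusters above a 3 % divergence threshold are
  flagged as candidate cryptic species.
* **Sampling-bias regression** — OLS of per-species mean intraspecific
  divergence on the number of individuals analyzed; a non-significant
  slope indicates sampling depth did not bias the variation estimates.
* **Synthetic communities** — a seeded generator that evolves COI-like
  communities under the K2P substitution process at library-realistic
  scales, with engineered failure conditions and a ground-truth table, so
  every stage is testable without any sequence download.

## Worked example

```python
from barcodeaudit import (SimConfig, simulate_community, distance_matrix,
                          build_nj, classify_species, success_rate)

cfg = SimConfig(n_genera=15, n_species=40, seed=11,
                n_shared_haplotype_pairs=2, n_paraphyly_pairs=1)
dataset, truth = simulate_community(cfg)
tree = build_nj(distance_matrix(dataset))
assessments = classify_species(tree, dataset)
n_ok, n_total, prop = success_rate(assessments)
print(f"success: {n_ok}/{n_total} species diagnosable ({100*prop:.1f}%)")
for a in assessments:
    if not a.success:
        print(f"  {a.species:22s} {a.condition.value:18s} "
              f"involving {', '.join(a.congeners_involved)}")
```

prints

```
success: 35/40 species diagnosable (87.5%)
  Genus003 sp003         identical_shared   involving Genus003 sp016
  Genus007 sp007         paraphyletic       involving Genus007 sp026
  Genus003 sp016         identical_shared   involving Genus003 sp003
  Genus003 sp025         identical_shared   involving Genus003 sp038
  Genus003 sp038         identical_shared   involving Genus003 sp025
```

— exactly the five engineered failures: both species of each
identical-haplotype pair fail (a shared haplotype precludes diagnosis in
either direction), and the species whose cluster encloses a congener's
radiation is paraphyletic, while the 35 remaining species (including
singletons, which cannot demonstrate monophyly and are marked "untested by
replication") are diagnosable.

More narrative scripts live in `examples/`, one per capability. The same
pipeline runs from the shell:

```bash
barcode-audit run aligned.fasta metadata.tsv -o audit_out
barcode-audit simulate --genera 125 --species 400 --seed 1 -o audit_out
barcode-audit qc aligned.fasta metadata.tsv
```

`run` expects an aligned FASTA (equal-length IUPAC rows) and a TSV with
columns `specimen_id`, `genus`, `species`, `region`; it writes a bundle of
plotting-ready TSVs (QC flags, species assessments, deep splits,
divergence histogram, regression) plus a Newick tree and `summary.json`.

## Documentation

`docs/methods.md` describes the model assumptions, the operational
definitions behind the five failure conditions, the synthetic-data
generator's design and its limitations, and the package's numerical
conventions.
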