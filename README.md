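# barcodekit

Integrative species identification for northeast Atlantic sand lances
(Ammodytidae: *Ammodytes marinus*, *A. tobianus*, *Hyperoplus immaculatus*,
*H. lanceolatus*) — and, more generally, for any small group of closely
related species studied with DNA barcodes plus morphology.

Sand lances are commercially exploited and ecologically central forage fish
whose species cannot be assessed separately because they are hard to tell
apart. `barcodekit` implements the full identification workflow used to
tackle that problem:

**Molecular side**

- Kimura-2-parameter and p-distances between aligned sequences under
  *pairwise deletion*: a site is compared for a pair only when both carry an
  unambiguous base. With transition proportion *P* and transversion
  proportion *Q*,

  ```
  d_K2P = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
  ```

- Neighbour-joining (Saitou–Nei Q-criterion, Studier–Keppler updates) with
  non-parametric bootstrap support by column resampling (Felsenstein).
- Barcode-gap analysis: for each species, the excess of the
  nearest-neighbour (minimum interspecific) distance over the maximum
  intraspecific distance. A positive gap means distance-based
  identification works; overlap means it fails.
- Single-linkage OTU clustering at a distance threshold (default 2.2%, the
  seed value of BOLD's BIN clustering) with per-cluster taxonomic
  concordance reporting.
- Diagnostic-nucleotide detection: a site is diagnostic for species *s* if
  *s* is fixed for a base that no sequence of any other species carries (or
  could carry, via an IUPAC ambiguity); species without pure diagnostics
  can still be identified by their combination of states across all
  variable sites.

**Morphological side**

- Standardization of measurements to percent standard length
  (`value x 100 / SL`), per-species character summaries
  (range; mean ± SD; n).
- Multi-group discriminant function analysis: eigen-decomposition of
  W⁻¹B (pooled within-group vs between-group scatter), standardized
  coefficients, Wilks' Λ = Π 1/(1+λₖ) with Bartlett's χ², Box's M, scores,
  centroids and nearest-centroid classification.
- A rule-based identification key (genus from premaxilla protrusibility,
  prevomer hooks, dermal plicae count and pectoral-fin length in %SL;
  species from qualitative states and count ranges).

A synthetic-data module generates sequence alignments with planted
species-specific substitutions and morphology tables drawn from the
published per-species means/SDs, so the whole pipeline is testable against
known ground truth without any downloads.

## Worked example

```python
import barcodekit as bk

# A 652-site barcode-like alignment, 70 specimens, 4 species, in which two
# species are planted one substitution apart and the other two several
# percent away.
aln, truth = bk.simulate_alignment(bk.default_coi_config(seed=1))
dm = bk.distance_matrix(aln, model="k2p")
for s in bk.species_summaries(dm, aln.species_map()):
    gap = f"{s.barcode_gap:.2f}" if s.barcode_gap is not None else "no gap"
    print(f"{s.species:24s} n={s.n_specimens:2d} "
          f"max_intra={s.max_intra:.2f}% d_NN={s.nn_distance:.2f}% gap={gap}")

p = bk.single_linkage_otus(dm, threshold=2.2)
print("OTUs at 2.2%:", p.n_clusters, "sizes", sorted(len(c) for c in p.clusters))
```

prints

```
Ammodytes marinus        n=27 max_intra=0.62% d_NN=3.45% gap=2.84
Ammodytes tobianus       n= 6 max_intra=0.15% d_NN=0.15% gap=no gap
Hyperoplus immaculatus   n= 8 max_intra=0.62% d_NN=3.45% gap=2.84
Hyperoplus lanceolatus   n=29 max_intra=0.93% d_NN=0.15% gap=no gap
OTUs at 2.2%: 3 sizes [8, 27, 35]
```

*A. marinus* and *H. immaculatus* show clear barcode gaps, while
*A. tobianus* and *H. lanceolatus* overlap (their nearest-neighbour
distance, 0.15%, does not exceed their intraspecific variation) and fall
into one OTU of 35 specimens — the barcoding failure mode this toolkit is
built to expose. The nuclear fragment rescues those two:

```python
rh, _ = bk.simulate_alignment(bk.default_rhodopsin_config(seed=1))
table = bk.diagnostic_sites(rh)
for site in table.sites:
    print(site.position, "->", site.diagnostic_for)
```

```
82 -> Hyperoplus lanceolatus
433 -> Hyperoplus immaculatus
460 -> Ammodytes marinus
```

with `bk.combination_signature(table, "Ammodytes tobianus")` returning the
unique state vector `("C", "G", "A")` for the one species lacking a pure
diagnostic site.

## Command line

Every stage is also a `barcodekit` subcommand:

```sh
barcodekit sim seqs --locus coi --seed 1 --out-prefix sim_
barcodekit dist --model k2p --in sim_seqs.fasta --meta sim_meta.tsv --out dist.csv
barcodekit tree --in sim_seqs.fasta --meta sim_meta.tsv --boot 1000 --seed 42 --out tree.nwk
barcodekit gap  --in sim_seqs.fasta --meta sim_meta.tsv --out gap_summary.csv
barcodekit otu  --in sim_seqs.fasta --meta sim_meta.tsv --threshold 2.2 --out otus.csv
barcodekit run molecular --in sim_seqs.fasta --meta sim_meta.tsv --outdir reports/
barcodekit sim morph --seed 1 --out-prefix sim_
barcodekit run morphology --in sim_morph.csv --outdir reports/
```

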