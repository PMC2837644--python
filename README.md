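# fyvepx

Comparative genomics of FYVE- and PX-domain proteins.

Both the FYVE zinc finger and the phox-homology (PX) domain bind the
endosomal lipid phosphatidylinositol 3-phosphate, PtdIns(3)P, yet individual
genomes tend to favour one of the two: fungal and most metazoan genomes
encode more PX proteins, streptophytes (land plants) more FYVE, while
protists split both ways. `fyvepx` is a tested re-implementation of the full
analysis chain behind that observation, for anyone studying the taxonomic
distribution and domain architecture of phosphoinositide-binding proteins:

* **dereplication** — greedy clustering at 95 % identity (exact global
  alignment, CD-HIT-style shorter-sequence denominator) with an
  *inter-species screen* that keeps identical proteins from different
  species;
* **domain architectures** — Pfam-style hits filtered at E ≤ 0.1, same-name
  overlaps resolved, per-protein ordered domain strings and associated-domain
  sets for each anchor (FYVE or PX);
* **selectivity** — per-genome FYVE vs PX protein counts and their bias;
* **Venn partition** — for each domain co-occurring with an anchor, the set
  of eukaryotic groups (metazoa, fungi, viridiplantae, protist) it appears
  in, decomposed into group-exclusive, shared and core compartments;
* **association score** — for each associated domain type *r*,

  ```
  score(r) = A_r / N,     N = Σ_r A_r
  ```

  where *A_r* is the number of anchor proteins containing *r* (counted per
  protein, never per copy);
* **functional categories** — a shipped many-to-many mapping of associated
  domains onto fifteen COG-style functional categories;
* **binding-site classification** — location of the FYVE PtdIns(3)P pocket
  hexapeptide and assignment to one of three consensus classes:
  canonical `R-R-H-H-C-R`, the `K-R/K-H-N-C-Y` class of streptophyte
  FYVE–RCC1–DZC proteins, and the `G/S-R-H-H-C-R` class of
  DUF500-associated domains;
* **synthetic proteomes** — a generator that plants all of the above
  structure (group-specific abundance ratios, core/shared/exclusive domain
  pools with long-tailed association frequencies, FYVE–RCC1–DZC
  architectures with non-canonical sites, ≥95 %-identical near-duplicates)
  and emits a ground-truth ledger, so the whole pipeline is testable without
  any database download.

## Worked example

Simulate the default study conditions (58 completely sequenced genomes plus
one viral FYVE protein, ≈2,000 proteins) and run every stage:

```python
from fyvepx.simulate import preset_default, generate
from fyvepx.pipeline import run
from fyvepx.analysis import rank_for_plot

records, hits, lineage, ledger = generate(preset_default(seed=1))
result = run(records, hits, lineage)

print(result.n_input, result.n_retained)      # 2042 1855
print(result.multidomain_percent)             # {'FYVE': 65, 'PX': 49}
print(result.exclusivity)                     # {'FYVE': 78, 'PX': 74}
print(sorted(result.venn["FYVE"].core))       # ['Ank', 'Beach', 'PH', 'PIP5K', 'WD40']
print(sorted(result.venn["PX"].core))         # ['Nexin_C', 'PXA', 'Vps5']
print(round(result.correlation_r, 3))         # 0.987
print(rank_for_plot(result.association["FYVE"], result.venn["FYVE"]).head(3))
#   domain  count     score compartment
# 0     PH    131  0.208267        core
# 1   WD40     74  0.117647        core
# 2    Ank     57  0.090620        core
```

Reading the output: of 2,042 simulated proteins, 1,855 survive
dereplication (intra-species near-duplicates removed, cross-species
identical proteins kept). 65 % of FYVE and 49 % of PX proteins carry at
least one associated domain. 78 % of the 58 FYVE-associated domain types
and 74 % of the 85 PX-associated types occur in a single taxonomic group;
five and three domains respectively are "core" (present in all four
eukaryotic groups) and dominate the association-score ranking. The Pearson
r of 0.99 quantifies how tightly the number of FYVE–RCC1–DZC proteins
tracks the total FYVE count across streptophyte genomes.

The same run is available from the shell:

```sh
fyvepx run-all --simulate --seed 1 --out results/run1
```

which writes the full report bundle (selectivity.tsv, venn_*.json,
association_scores_*.tsv, binding_sites.tsv, summary.json, …) plus a
manifest of input hashes and parameters; reruns with the same seed are
byte-identical.

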