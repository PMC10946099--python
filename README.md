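# ethnogarden

Quantitative ethnobotany of homegarden plant inventories.

Homegardens — the small, household-managed plots beside rural dwellings —
are compact reservoirs of plant diversity and of the traditional knowledge
attached to it. Surveys of them produce a characteristic data shape: a
species inventory (taxonomy, life form, where each species occurs, what it
is used for and which part is used), informant interviews that yield
citation counts per species, and sometimes land-use composition for the
surrounding region. `ethnogarden` turns that data shape into a validated
data model plus the standard quantitative indices used to analyse it:

- **Use value** — `UV = Σᵢ Uᵢ / n`, the mean number of uses cited for a
  species across the `n` informants.
- **Relative importance** — `RI = NUC + NT`, where NUC is the species'
  use-category count divided by the inventory maximum and NT the analogous
  ratio for finer-grained use types (here: distinct category × plant-part
  pairs). RI is bounded by 2, attained exactly when one species holds both
  maxima.
- **Jaccard similarity** — `JI = c / (a + b − c) × 100` between the species
  sets of two communities sharing `c` of their `a` and `b` species.
- **Comprehensive land-use degree** — `La = 100 × Σᵢ Aᵢ Cᵢ` over land
  classes with ordinal grade `Aᵢ ∈ {1..4}` and area share `Cᵢ`; ranges
  100–400.
- **Shannon–Wiener diversity** — `H′ = −Σᵢ pᵢ ln pᵢ`.

On top of the indices sit the descriptive summaries such surveys report
(taxonomic richness, life-form spectrum, family frequencies, per-category
tallies, the 31-region Venn partition of species over the five use
categories, rankings and threshold counts) and a seeded synthetic-survey
generator that carries exact ground truth for every index, so the whole
pipeline is testable without field data.

The package ships a complete transcription of a homegarden survey from the
Laershan Plateau (Hunan, China): 152 species across the townships of Heku
(HK), Lianglin (LL) and Laershan (LES), with five fixed use categories
(edible, trade, medicine, forage, ornamental) and the published UV and RI
scores per species.

## Worked example

```python
import ethnogarden as eg

inv = eg.load_laershan_fixture()

tax = eg.taxonomic_summary(inv)
print(tax.n_species, tax.n_families, tax.n_genera)

pct = eg.life_form_spectrum(inv).percentages
print({lf.value: p for lf, p in pct.items()})

_, pairs = eg.jaccard_matrix(inv)
print({f"{p.group_a}-{p.group_b}": p.rounded for p in pairs})

print(eg.count_above_threshold(inv, "ri", 1.5).count)
print([s.split()[0] for s in eg.multifunctionality_partition(inv).all_five])
```

prints

```
152 62 123
{'herb': 56.6, 'shrub': 12.5, 'tree': 23.7, 'liana': 7.2}
{'HK-LL': 39.0, 'HK-LES': 40.7, 'LL-LES': 50.5}
8
['Artemisia', 'Mentha', 'Taraxacum']
```

That is: 152 species in 62 families (123 distinct genera by a first-token
recount of the transcribed names; the survey's own prose gives 124), a
herb-dominated life-form spectrum, the Lianglin–Laershan pair as the most
similar township pair at JI 50.5, eight species with relative importance
above 1.5, and three species — *Artemisia argyi*, *Mentha canadensis*,
*Taraxacum mongolicum* — serving all five functions.

The same reports are available from a shell:

```sh
ethnogarden summarize --out report/          # taxonomy, spectra, Venn partition
ethnogarden indices   --out report/          # JI matrix, RI table (+ UV/La with inputs)
ethnogarden simulate  --seed 7 --out synth/  # synthetic survey + ground truth
ethnogarden validate  --inventory synth/inventory.csv
```

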