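# cytonuclear

Exact enumeration and forward simulation of cytonuclear inheritance in the
*Eisenia andrei* (Ea) / *E. fetida* (Ef) earthworm complex, for researchers
studying asymmetrical interspecific hybridization, hermaphrodite mixed
mating, and the inheritance of the "M-fluorophore" — a fluorescent
biomarker of *E. andrei* coelomic fluid that unexpectedly turns up in some
*E. fetida* worms.

## The model

Each worm carries a cytonuclear genotype written `[af][AF][AF][Mm][Mm]`,
maternal allele first in each nuclear pair:

- a maternally inherited mitochondrial COI haplotype, `a` (Ea) or `f` (Ef);
- a diploid species-diagnostic 28S locus with alleles `A`/`F`;
- a diploid fluorophore locus with a dominant `M` allele: `MM`/`Mm`/`mM`
  worms are M-positive (Mp), `mm` worms M-negative (Mn).

So `aAFMm` is an M-positive hybrid from an Ea ovum and `fFFmm` a typical
M-negative Ef. Both partners of a pair are simultaneous hermaphrodites:
each ovum is self-fertilized with probability σ (default 0.5) and
cross-fertilized by partner sperm otherwise. Three biological asymmetries
shape the offspring distribution:

- **mito-nuclear incompatibility**: ova combining an `a` mitochondrion with
  a nuclear `F` allele are viable with probability *v* (default 0, hard
  exclusion);
- **asymmetrical hybridization**: cross-fertilization of `f` ova by
  `A`-bearing sperm succeeds with relative weight *h* (default 0.1), making
  Ef-derived `fFA` hybrids rare;
- **hybrid sterility**: `fFA` worms are sterile, and hybrid × hybrid pairs
  produce no offspring.

On top of the Mendelian model, the package implements the competing
hypothesis that M-positivity is not genetic at all but reflects a
*Verminephrobacter*-like bacterial symbiont transmitted vertically through
cocoons (probability `symbiont_vertical_p`) and occasionally sexually
between partners (`symbiont_sexual_p`); family likelihoods under both
mechanisms can be compared directly.

The package provides exact offspring distributions (Punnett enumeration
with the weights above), a seeded multi-generation pedigree simulator,
synthetic excitation/emission fluorescence scans with peak-based Mp/Mn
calling (excitation peak 320 nm, emission peak 380 nm), constraint
propagation of compatible M-locus genotypes through pedigrees, and
grid-search maximum likelihood for (σ, h) from class counts. A packaged
46-specimen study table and the 7-offspring proof-of-concept family ship
as fixtures.

## Worked example

The exact offspring distribution of an Ea-derived hybrid paired with a
typical Ef (σ = 0.5, h = 0.1, v = 0):

```
$ cytonuclear punnett --mother aAFMm --father fFFmm --selfing 0.5 --h 0.1 --v 0
aAFMm	0.25
aAFmm	0.25
fFAmM	0.00806451612903
fFAmm	0.00806451612903
fFFmM	0.0806451612903
fFFmm	0.403225806452
# class Ef_Mn	0.403225806452
# class Ef_Mp	0.0806451612903
# class hybrid_Ea_derived_Mn	0.25
# class hybrid_Ea_derived_Mp	0.25
# class hybrid_Ef_derived_Mn	0.00806451612903
# class hybrid_Ef_derived_Mp	0.00806451612903
# Mp mass	0.338709677419
```

Half the brood comes from the hybrid's ova (only `aA` ova survive, split
Mp/Mn), half from the Ef partner's ova, where selfing dominates (`fFFmm`),
the atypical M-positive Ef (`fFFmM`) arises from hybrid sperm, and the rare
Ef-derived hybrids (`fFAmM`/`fFAmm`) are down-weighted by h.

Comparing mechanisms on the proof-of-concept brood — seven offspring of an
atypical M-positive Ef line, five Mp and two Mn:

```
$ cytonuclear compare-mechanisms --family family.json
{
  "log_ratio": Infinity,
  "mendelian": -1.166476646775262,
  "symbiont": -Infinity
}
```

A selfing `fFFMm` mother yields Mn offspring with probability 1/4, so the
observed 5:2 split has log-likelihood log[C(7,2)·0.25²·0.75⁵] ≈ −1.17,
while a perfectly vertically transmitted symbiont from an infected mother
cannot produce Mn offspring at all: the Mendelian mechanism wins.

Other subcommands: `simulate` (seeded design → specimen TSV), `classify`
(specimen TSV → class counts), `fit` (counts + design → σ̂, ĥ),
`spectra classify` (scan CSVs → Mp/Mn), `generate` (synthetic cohort with
spectra).

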