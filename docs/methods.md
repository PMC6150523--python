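# Methods

## Inheritance model

A genotype couples one haploid, strictly maternal mitochondrial marker
(COI haplotype `a`/`f`) with two unlinked diploid nuclear loci: the
species-diagnostic 28S locus (`A`/`F`) and the fluorophore locus (`M`
dominant over `m`). Gametogenesis is fair Mendelian segregation — each
locus transmits either allele with probability 1/2, loci independent; ova
carry the parent's mitochondrion, sperm none. Parent of origin is retained
in every nuclear pair (maternal allele first), so `Mm` and `mM` are
distinct states with identical phenotypes; tabulations that should pool
them use the unordered equivalence (`Genotype.unordered_key`).

A mating of two hermaphrodites is resolved per ovum. With selfing rate σ
an ovum is fertilized by own sperm, otherwise by partner sperm. Each
fertilization event carries a weight: the product of gamete probabilities,
times the ovum viability (v for `a`-mito ova bearing a nuclear `F`, 1
otherwise), times the asymmetry weight h when an `f` ovum is
cross-fertilized by `A`-bearing sperm. Weights shift brood composition
only — the surviving mass is renormalized, so brood size is not modeled.
A pair is an equal mixture of the two mother roles (each renormalized
separately; a sterile or fully excluded role cedes its mass to the other).
Sterility rules: `fFA` worms produce no offspring in either role, hybrid ×
hybrid pairings produce none, and hybrid mothers self only when
`hybrid_selfing_enabled` is set (off by default — hybrid selfing cannot be
excluded during hybrid × parental matings, but there is no positive
evidence for it either).

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| σ `selfing_rate` | per-ovum selfing probability | 0.5 | facilitated selfing and outcrossing both routinely observed; an uninformative even split |
| h `ef_cross_success` | weight on `f`-ova × `A`-sperm crosses | 0.1 | Ef-derived hybrids occur but are rare (4 of 46 sampled descendants) |
| v `af_ovum_viability` | viability of mito-nuclear incompatible `aF` ova | 0.0 | such ova and their offspring are absent from observed broods; "less probable" is kept configurable |
| `hybrid_selfing_enabled` | hybrid mothers may self | off | no observed hybrid-selfing offspring |
| `symbiont_vertical_p` | cocoon transmission from infected mother | 1.0 | strict vertical transmission is the discriminating case against the Mendelian model |
| `symbiont_sexual_p` | partner-to-cocoon infection per pairing | 0.5 | unquantified; a neutral placeholder for sensitivity analysis, not an estimate |

All probabilities are validated to [0, 1]. Founders in simulated designs
default to infected iff `a`-mito (the symbiont hypothesis is
*E. andrei*-specific); overridable per design.

## Pedigree simulation

Offspring are i.i.d. draws from the exact mating distribution, so the
simulator agrees with the enumerator by construction; the test suite
verifies this at n = 10⁵ within three binomial standard errors per class.
Because both partners are hermaphrodites, pedigree links record *genetic*
roles: each partner mothers its own ova, and a self-fertilized offspring
has father equal to its mother. This makes the COI-conservation invariant
(offspring COI = genetic mother's COI) and downstream pedigree inference
exact. Offspring counts per cross are fixed, not Poisson; cocoon and
clutch dynamics are out of scope. IDs are
`{generation}_{cross-index}_{offspring-index}`. Body weights are drawn
from a normal with mean 0.77 g and SD 0.18 g truncated at zero by
rejection (the study population's mean ± SD; truncation bias at 4.3 SD
from zero is ~10⁻⁵ g and ignorable). Symbiont sexual transmission is
resolved once per pairing and genetic-mother cocoon, not per offspring.

The default three-cross design mirrors the study: an `aAAMM` × `fFFmm`
founder pair, then the F1 Ea-derived hybrid test-crossed to each parental
species. Simulated tables are reproducible byte-for-byte from (design,
parameters, seed); unseeded generators are rejected.

## Fluorescence spectra

M-positive scans are a Gaussian bump on a flat baseline: emission centered
at 380 nm on the 340–480 nm grid, excitation at 320 nm on 260–360 nm, grid
step 1 nm. Peak SD (15 nm), baseline (10 a.u.) and amplitude (100 a.u.)
are invented generator parameters — the recorded windows and peak
positions are the only measured anchors. M-negative scans are baseline
only. Noise is additive Gaussian, clipped at zero. The classifier calls Mp
iff the emission argmax falls in 370–380 nm, the excitation argmax in
314–320 nm, and both peaks exceed a prominence threshold of 2.0, where
prominence = (peak − median)/median — scale-invariant, so absolute-unit
calibration is irrelevant. Argmax ties break to the lower wavelength. The
synthetic generator does not emulate instrument drift, scatter peaks, or
within-window biological variation of the true peak position; a perfect
zero-noise round trip therefore validates the pipeline's plumbing, not
field performance on real fluorimetry.

## Inference

**Class counts.** Specimens are classified from (COI, unordered 28S
diplotype) into Ea / Ef / Ea-derived hybrid / Ef-derived hybrid, crossed
with Mp/Mn.

**M-locus genotypes through pedigrees.** Per specimen, the set of ordered
M diplotypes compatible with its phenotype and Mendelian transmission is
computed by arc-consistency iteration to a fixpoint: a child diplotype
must be transmissible from each parent's surviving set, and a parent
diplotype must be able to serve every child. The truth is never pruned
(sound but not complete — joint constraints across siblings are only
enforced pairwise). An emptied set is reported as an inconsistency naming
the specimen and the violated constraint.

**(σ, h) estimation.** Multinomial likelihood of class counts, with class
probabilities computed exactly from the design: crosses are mixed in
proportion to their offspring counts, and a selector referencing an
offspring class is resolved to the conditional genotype distribution of
that class among earlier crosses. Maximization is a plain grid search
(default 101 × 101 over the unit square) rather than a numerical
optimizer: the surface is cheap, can be flat or boundary-maximized (h
estimates hit 0 exactly when no Ef-derived hybrid is observed), and the
full surface is returned. A multinomial rather than per-pedigree
likelihood is used because class counts, not full pedigrees, are the
observable for most specimens. Parameter recovery at study scale
(n = 5000, truth σ = 0.5, h = 0.1) achieves median absolute error within
one grid step (0.01) over 20 seeded replicates.

**Mechanism comparison.** For a family with parent configuration and an
Mn count k of n offspring: the Mendelian likelihood is Binomial(k; n,
P(Mn)) with P(Mn) from the exact self/pair distribution; the symbiont
likelihood marginalizes cocoon infection (certain for an infected mother,
`symbiont_sexual_p` for an infected father only) with Mn iff uninfected
offspring. Impossible observations return −∞ by contract. Likelihoods and
ratios are reported, not p-values — no testing machinery is attached.

## Fixtures and synthetic cohorts

The packaged 46-specimen table transcribes per-worm class and phenotype;
individually reported codes (e.g. `fFF_158/190`, `fFA_149/194`,
`aAA_41`) are kept, while worms not individually coded carry synthetic
`_sNN` placeholder ids. M-locus diplotypes and pedigree links are
unobserved and left blank. The 7-offspring proof-of-concept family is
packaged with its selfing `fFFMm` mother. Both files are pinned by SHA-256
in the loader, so silent edits fail loudly. Cohort generation couples the
design simulator with per-specimen spectra (matching the true M status)
and weights, fully reproducible from (config, seed).

## Known limitations

- Two alleles per locus, no linkage, no sequence-level representation.
- Composition-only broods: fecundity differences between classes are not
  modeled, though the species differ in fecundity.
- The combined mechanism (host gene and symbiont cooperating) is noted but
  not modeled; it is under-specified.
- Whether founder Ea are `MM` or `Mm` is an assumption (config default
  `MM`), not an observation — phenotype cannot distinguish them.
- fFA paternal sterility is a default, not a demonstrated fact; only
  maternal sterility and pair infertility are directly supported.
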