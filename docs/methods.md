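# Methods

This note documents the models, the packaged data, the numerical choices,
and the limits of what the test suite demonstrates.

## Scope and representations

The package predicts 2D, achiral candidate structures.  Tandem mass
spectrometry cannot distinguish stereoisomers, so all SMILES are stripped of
stereochemistry on load and epimerizations are identity operations in this
representation (D-glucose and D-mannose share one molecular graph; both
records are kept because they are distinct biosynthetic entities).
Coordinates are 1-based inclusive internally (GenBank convention) and
exported 0-based half-open in BED-like output.  Atom indices in catalogs
(reactive groups, modification motifs) are 1-based in SMILES
atom-appearance order.

## Packaged knowledge base

* **50 gene classes** covering monomer biosynthesis (nucleotidyl­transferases,
  dehydratases, aminotransferases, cyclitol synthases, ...), two
  glycosyltransferase families with no monomer role, and tailoring-enzyme
  families.  A class may serve several monomers (e.g. the NDP-glucose
  synthase/dehydratase pair feeds most deoxysugars), and the union rule for
  candidate sets counts each class once.
* **20 secondary monomers** (streptidine, dihydrostreptose,
  N-methyl-L-glucosamine, 2-deoxystreptamine, kanosamine, neosamine C,
  garosamine, purpurosamine, sisosamine, actinamine, actinospectose,
  kasugamine, fortamine, streptamine, valienone,
  4-amino-4,6-dideoxy-D-glucose, mycarose, olivose, rhamnose, evernitrose)
  and **6 primary monomers** from central metabolism.  Gene-class
  assignments were curated from standard aminoglycoside/oligosaccharide
  biosynthesis literature; where a pathway is only partly characterized the
  assignment is a representative placeholder and is marked by the generic
  class names.
* **3 bond-formation families.**  The nucleotide-diphosphate activating
  group of a sugar donor (NDP/GDP/UDP/dTDP are interchangeable for 2D
  prediction) is modeled as the anomeric hydroxyl placeholder; glycosylation
  then removes H2O, which reproduces exact oligosaccharide masses
  (e.g. maltose = 2 glucose − H2O).  The three families are
  O-glycosylation (anomeric + hydroxyl; ribosylation is this rule acting on
  a pentose donor), N-glycosidic condensation (anomeric or ketone chemistry
  toward an amine, net dehydration), and amidation (carboxyl + amine).
* **49 modification rules**, each a motif SMILES plus an ordered command
  program over `add <label> <element>`, `remove <label>`,
  `connect <i> <j> <order>`, `disconnect <i> <j>`.  `remove` deletes an atom
  with its incident bonds; `connect` on an existing bond resets its order;
  labels are stable (they do not shift when atoms are removed).  Each rule
  stores the mass delta its program produces on the bare motif; the loader
  and test suite replay every program and require agreement within 1e-4 Da.
  Because a motif can embed at chemically different sites (a `CO` motif can
  map onto a ring ether as well as a hydroxyl), every *application* re-checks
  the observed mass delta and skips non-conforming sites with a logged
  reason; valence-illegal products are likewise skipped.

## The probabilistic model

BGCs are binary presence vectors *b* over the G gene classes; saccharides
are binary vectors (*g*, *m*).  The factorized likelihood uses three
parameters:

* α = P(g=1 | b=1): a detected gene is actually used by the product,
* β = P(g=1 | b=0): the *missing-gene rate* — a gene class required by the
  product although annotation did not find it,
* γ = P(m=1): marginal inclusion of a primary monomer.

The likelihood over training pairs is αᵃ(1−α)ᵇ βᶜ(1−β)ᵈ γᵉ(1−γ)ᶠ with
a…f the aggregated co-occurrence counts, giving the closed-form MLEs
α = a/(a+b), β = c/(c+d), γ = e/(e+f).  Degenerate estimates (empty
denominator, boundary 0/1) are returned with a warning rather than silently
renormalized.  Unsupported monomers admitted under the eligibility
relaxation pay the β penalty once per required gene, which is what makes a
fully gene-supported set outrank an unsupported one whenever α > β.

The default parameters are trained from a packaged 20-molecule table
(`training_pairs_synthetic.tsv`).  The underlying benchmark's gene-by-gene
data are not published in machine-readable form, so the table is a
*synthetic reconstruction*: required-gene vectors come from this package's
own catalog, the detected subset per molecule follows the published
per-cluster detection percentages, and glycosyltransferase plus tailoring
classes are added as present-but-not-required genes.  It yields
α = 0.636, β = 0.020, γ = 0.200 — a plausible regime (most detected genes
used, missing genes rare, primaries occasional) but not the original tool's
fit.  Callers can override all three parameters explicitly.

## Enumeration limits

Candidate multisets are capped at 7 monomers (the largest benchmark
molecule), multiplicity 3 per monomer (repeated glucose units occur in
glucose-rich oligosaccharides), and at most 2 primary monomers; the top 500
sets proceed to assembly.  Ties in log-probability are broken by the
lexicographic monomer-id tuple so rankings are reproducible.  The
enumeration universe is highly sensitive to these caps, so reported
denominators ("rank r of n sets") are only comparable under identical caps.

## Assembly and modification

All distinct orderings of a multiset are enumerated (identical-monomer
symmetry deduplicated) and every junction tries every compatible
(rule, donor side, donor group, acceptor group) choice; terminal monomers
consume exactly one reactive group and internal monomers two, each group at
most once.  Branching is not enumerated (the accounting layer would permit
it); an optional terminal-to-terminal cyclization attempt is off by
default.  Products are deduplicated by canonical SMILES and capped at 5,000
per set.  Mass conservation (Σ monomers − Σ leaving groups, 1e-4 Da) is
asserted for every emitted candidate.

Modification enumeration is breadth-first to depth 3 (rules compose; the
true composition semantics of tailoring cascades are unknown, so
enumerate-with-caps favors recall), iterating rules in sorted-id order with
canonical-SMILES deduplication, making the output independent of caller
rule order.  Multi-enzyme rules activate only when *all* listed gene
classes are present in the BGC.

## Spectral scoring

The scorer is intentionally simple and fully specified — it is not a
reimplementation of any published dereplication engine, and its integer
scores are not comparable to scores printed elsewhere.

* **Bridges.**  Fragmentable bonds are acyclic bonds whose cleavage leaves
  ≥ 4 heavy atoms on both sides; this selects glycosidic (C−O−C),
  N-glycosidic and amide linkers while leaving hydroxyls and methyls
  intact.  Fragments are connected-component neutral masses over all
  subsets of ≤ 2 bridge cuts, with homolytic hydrogen bookkeeping (each
  atom keeps its hydrogens) and (mass, composition) deduplication.
* **Score.**  Greedy one-to-one nearest-mass matching of experimental peaks
  to adduct-adjusted fragment m/z within 0.01 Da; intensities are ignored
  by default (``score_match(..., intensity_weighted=True)`` returns the
  matched fraction of total intensity instead).  Adducts: [M+H]+, [M−H]−, and [M+NH3]− (an ammonia adduct
  observed after deprotonation, the negative-mode analyte form of
  trestatin-class oligosaccharides); precursor tolerance 10 ppm.
* **Variable mode.**  The score is maximized over one global mass shift;
  candidate shifts are 0 and the precursor-minus-intact-mass difference
  (plus any user grid) within ±500 Da, and every fragment is offered both
  unshifted and shifted because the altered side of the molecule is
  unknown.  Shift 0 is always included, so the variable score never falls
  below the standard score.
* **Significance.**  Empirical p = (1 + #{decoys ≥ observed}) / (decoys+1),
  decoys resampling fragment masses uniformly over the theoretical
  spectrum's mass range with the fragment count preserved; 999 decoys and a
  p ≤ 10⁻³ report threshold by default (the smallest attainable p with
  999 decoys is exactly 10⁻³, so the threshold keeps only perfect-rank
  matches).  These p-values are conservative and discrete; with
  integer shared-peak scores they are *not* continuously uniform under the
  null — sparse spectra concentrate them at 1 — and the test suite checks
  the validity bound P(p ≤ t) ≤ t + 1/(decoys+1) plus approximate
  uniformity in a dense-score regime.  Positional isomers can share an
  identical fragment-mass multiset and therefore tie exactly; a search can
  rank such isomers only by their shared score.

## Synthetic fixtures

All tests run on generated data: toy catalogs reusing real sugar graphs,
protein fixtures built from seeded consensus sequences with 5 %-mutated
8-sequence alignments turned into profile HMMs, training pairs drawn from
the generative model itself, and spectra assembled from a structure's own
fragments with seeded dropout, jitter, noise peaks and optional global
shifts.  Every generator output is byte-reproducible from (spec, seed).
The fixtures deliberately omit real-data complications — homologous
cross-matching enzymes, fragmented assemblies, chimeric or multiply charged
spectra, isotope envelopes, instrument-dependent noise — so green tests
demonstrate correctness of the algorithms under the stated model, not
field performance on real genomes or LC-MS runs.  Problem sizes in the
suite and the acceptance script (toy G = 6, disaccharide/trisaccharide
assemblies, 60-candidate search pools, 999 decoys, 500 training pairs) were
chosen as the smallest sizes at which each property is non-trivially
exercised.

## Known limitations

* Gene-class ↔ monomer assignments are curated, not learned; pathways
  outside the aminoglycoside/oligosaccharide literature will not be
  detected.
* No branching backbones, no regio-/stereo-selectivity, no hybrid
  polyketide/peptide moieties.
* The fragmentation and significance models are simplified stand-ins;
  absolute scores and p-values are internally consistent but not
  comparable across tools.
* Genes outside the 10-kb window are invisible to the presence vector; the
  β parameter compensates statistically, not mechanistically.
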