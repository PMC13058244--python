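# Methods

## Scope and model of the data

The package analyses predicted two-chain coordinate models of receptor
ectodomains (ECDs) with two tandem DUF26 domains per chain, their
predicted-aligned-error (PAE) matrices and per-model ipTM/pTM scores, plus
family sequence data (nucleotide alignments for diversity statistics,
protein sequences for motif scans).  Structure prediction itself, genome
retrieval, phylogenetics, selection tests and electrostatics are upstream
or downstream of this package and are consumed or emulated, not computed.

## Screening procedure

For every candidate pair the five predicted models are ranked by the
combined confidence `0.8·ipTM + 0.2·pTM`.  This weighting is the standard
multimer ranking confidence and keeps the score on the 0–1 scale; a raw
`ipTM + pTM` sum (0–2) is available behind `combined_mode="sum"` for
pipelines that log the plain sum.  A model passes when `combined > 0.8`
and `iPAE < 6 Å`, both strict inequalities exactly as the thresholds are
conventionally printed; inclusive variants are a config flag.  Among
passing models the highest combined score is selected (ties: lower iPAE,
then lower model rank).

iPAE is the arithmetic mean of the two cross-chain blocks of the PAE
matrix (rows of chain 1 × columns of chain 2 and vice versa).  An
alternative reading — averaging only entries inside annotated DUF26
domains — is implemented behind `mode="domain"`; the chain-block mean is
the tested default because it needs no annotation and is symmetric.

Interface residues are defined by a heavy-atom distance cutoff (5.0 Å
default) rather than buried surface area: a distance contract is
deterministic, dependency-free and exactly recoverable on fixtures.  The
adaptive interface cutoff is `ceil(mean − 1·sample SD)` over the per-chain
interface counts of all confidence-passing chosen models (each model
contributes its two chain counts); the ceiling reproduces the printed
worked case mean 34, SD 5.5 → 29.  The cutoff is applied per chain
("both chains require ≥ cutoff residues"); a complex-total mode exists
behind `interface_rule="total"` because the per-chain reading, while the
natural one, is not the only possible one.

## Orientation classification

Each chain gets a domain axis: the unit vector from the DUF26-A Cα
centroid to the DUF26-B Cα centroid.  Cross-chain residue contacts are
tabulated by domain pairing (B:B, A:B/B:A, A:A).  The decision rule is:

* **Standard** — dominant B:B pairing and inter-axis angle θ < 60°;
* **Flipped** — dominant A:B pairing (any angle);
* **FlippedShifted** — dominant B:B, θ ≥ 120°, and the projection of the
  chain-centroid offset on the first chain's axis exceeds 0.5 × the mean
  domain length;
* **Unclassified** — anything else, including dominant A:A or no contacts.

The angle and shift thresholds are configurable; 60° splits the sphere
into clearly-parallel / clearly-antiparallel caps with a wide indifference
band, and 0.5 domain lengths is the smallest shift that cannot be confused
with ordinary interface slack.  Real model sets were historically
finalized with manual inspection; this rule is a formalization and is not
guaranteed to reproduce every manual call on borderline geometry.

## Geometry details

* Disulfides: Sγ–Sγ distance ≤ 2.5 Å, greedy nearest-first pairing with
  ties broken by (chain, residue index), one partner per cysteine;
  cysteines lacking Sγ fall back to Cβ with the cutoff relaxed by 2 Å.
  Bonds between sequence-adjacent cysteines are flagged vicinal.
* β-ladders: cross-chain residue pairs with main-chain N–O distance
  ≤ 3.5 Å in either direction, chained into runs where both indices
  advance by one (chain-2 index may run in either direction, covering
  parallel and antiparallel sheets); runs ≥ 3 are reported.  No angle term
  is used — adequate for fixtures and a documented simplification for
  real models.
* Kabsch RMSD: SVD of the cross-covariance with the determinant sign
  corrected so only proper rotations are used.
* pLDDT classes: very-high (90, 100], high (70, 90], low [50, 70],
  very-low [0, 50).  The conventional verbal brackets overlap at 70 and
  leave 50 and 90 unassigned; this assignment closes them upward so each
  value has exactly one class.
* File handling: first model of multi-model files, altloc 'A'/blank
  preferred, hydrogens ignored; pLDDT read from the B-factor column.

## Diversity statistics

S, k̂, π and Tajima's D use listwise site filtering: only columns free of
gaps and ambiguity codes in every row enter the statistics, so all pairs
share one denominator.  The upstream convention (trimming high-gap
columns) is the caller's business; within a statistic, complete columns
avoid pair-dependent site counts.  D uses the Tajima (1989) constants and
is reported as undefined (not zero) when S = 0; it is evaluated for any
n ≥ 2 but values at n = 2–3 carry little information.  Pairwise identity
divides matches by columns where at least one of the pair is non-gap.
Percent shares (haplotype share, region fractions, retained percent) are
rounded half-up to integers, matching how such shares are printed.

## Synthetic data: what it emulates and what it does not

* **Dimer fixtures** are Cα/N/O pseudo-chains: two rigid domains of
  3.8 Å-spaced Cα positions per chain, with `planted_contacts` consecutive
  residue pairs brought to the requested separation and their N/O atoms
  aimed so exactly those pairs satisfy the hydrogen-bond criterion.
  Contacts pair B:B for Standard/FlippedShifted and A:B for Flipped;
  axes are parallel for Standard, antiparallel otherwise; FlippedShifted
  shifts the second chain along the axis by one domain length by default —
  with antiparallel chains a B:B interface is only geometrically possible
  with such a shift, and one domain length always exceeds the classifier's
  0.5-length threshold.  The planted-contact contract (interface count per
  chain equals planted contacts; one ladder at exactly the planted length)
  is exact for separations in [4.4, 5.0] Å; the recovery grid uses 4.4,
  4.7 and 5.0 Å at domain sizes 6, 10 and 14.  These are not protein
  folds: side chains, twist, and realistic β-sheet geometry are absent, so
  passing tests demonstrate correctness of the metrics' contracts, not
  performance on real predicted structures.
* **PAE fixtures** are block-constant matrices (intra vs inter level) with
  optional Gaussian noise, clipped to the conventional 31.75 Å ceiling.
* **Coalescent alignments** follow the standard neutral Kingman process:
  exponential inter-coalescent times at rate k(k−1)/2, Poisson mutation
  count with mean (θ/2)·total branch length, each mutation on a branch
  chosen proportionally to length and a fresh site (infinite sites);
  ancestral/derived alleles are coded A/T.  If a Poisson draw exceeds the
  sequence length it is resampled, preserving infinite sites at test
  scales.  No recombination, selection or indels.  Calibration (n = 20,
  θ = 5, 2,000 replicates, 600 sites): mean pairwise differences within
  5 % of θ and mean D within ±0.2 of 0.
* **Motif planting** draws background residues from letters outside all
  planted motifs and outside {N, S, T, C}, so scanner hits are exactly the
  planted positions.
* **Retrieval emulation** plants each locus (distinct 20-mer prefixes)
  once per synthetic genome with substitutions allowed outside the prefix;
  "retrieval" extracts one best hit per genome × locus by prefix search.
  This reproduces the count contract of a genome-wide best-hit search
  (69 genomes × 40 loci → 2,760 sequences), not aligner behaviour.
* **The screening cohort** plants three classes of pairs — confidence
  passes (one clearly best model: combined ≈ 0.9, iPAE ≈ 3 Å, 6 contacts),
  confidence failures (scores ≤ 0.6, iPAE > 6 Å) and interface failures
  (pass confidence, 2 contacts) — with orientations cycled over the three
  classes and a configurable number of passing self-pairs.  The default
  mix (7/6/3) puts the adaptive cutoff (3) strictly between the planted
  contact levels, so planted pass/fail labels are recovered exactly.

## Network analysis

Self-pairs are stored as homodimer node flags, not self-loops, and are
excluded from PageRank/Walktrap adjacency — they decorate nodes in the
standard rendering and would otherwise distort the walk.  PageRank is
plain power iteration (damping 0.85, L1 tolerance 1e−9) with uniform
teleportation and uniform redistribution of dangling mass.  Walktrap
follows Pons–Latapy: t-step transition distributions (t = 8), distances
weighted by inverse degree, Ward-style merging restricted to adjacent
communities, and the returned cut maximizes Newman modularity along the
merge path (ties toward fewer communities).  Components are processed
independently and each component's cut optimized on its own subgraph.
The expression filter keeps nodes with value strictly above the threshold
(default 0: "expressed at all"); real expression cutoffs are
dataset-specific and left to the caller.

## Problem sizes

The test suite and acceptance script run at desk scale by design: dimer
fixtures of 12–28 residues per chain, cohorts of 16 pairs × 5 models,
2,000 coalescent replicates of 20 × 600 sites, 50–100 random matrices and
graphs (n ≤ 30).  These sizes make every check exhaustive or
Monte-Carlo-tight while keeping the whole suite in tens of seconds.

## Known limitations

* The distance-based interface definition is not ΔASA; counts on real
  models will differ from PISA-style interface residue numbers.
* The β-ladder detector uses distances only; on real structures an
  N–H···O angle term would be needed to suppress spurious pairings.
* The orientation rule formalizes what is ultimately a visual taxonomy;
  borderline angles near the thresholds are reported Unclassified rather
  than forced.
* Enumeration supports both family conventions (n(n−1)/2 + n self-pairs,
  e.g. 38 → 741, and n(n−1)/2 without, e.g. 40 → 780); which applies to a
  given dataset is the caller's declaration, and the two conventions give
  different denominators for retained percentages.
* Logo rendering is out of scope; `column_frequencies` emits the
  position × residue frequency table that logo tools consume.
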