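# Methods

## Structure handling

Models are heavy-atom only: crystal structures of protein–DNA complexes at
typical resolutions carry no hydrogens, so every criterion in the package
is a heavy-atom criterion and no angular hydrogen-bond term is applied.
Parsing (via gemmi) keeps the first MODEL block, resolves alternate
locations to the highest-occupancy conformer (ties broken toward the
earlier altloc letter, so one conformer is chosen deterministically) and
drops waters and non-polymer heteroatoms. Canonical heavy-atom sets for the
twenty amino acids and four deoxyribonucleotides are embedded as static
tables; a residue has a *missing side chain* when any canonical side-chain
atom is absent (glycine is never reported, unknown residue names are
skipped with a warning).

Residue numbering is author (PDB) numbering throughout, with an optional
injective per-chain `NumberingMap` to reference positions. The default is
the identity map, appropriate for deposited structures already numbered by
the reference protein (the murine Oct4 complex is).

## Superposition and side-chain grafting

`kabsch_superpose` computes the least-squares rigid transform between two
equal-length coordinate sets: centre both, take the SVD of the
cross-covariance matrix, and correct the sign of the smallest singular
direction so the rotation is proper. Inputs of fewer than three points, or
centred rank < 2 (collinear) sets, are rejected because the rotation is
then underdetermined.

Grafting copies template side-chain geometry without touching anything
else. For each target residue the backbone atoms (N, CA, C, O, plus CB
where present in both structures) of a ±2-residue window around the paired
template residue are fitted onto the target backbone and the template's
side-chain atoms the target lacks are copied under that local transform.
A *local* window fit rather than one global superposition tolerates
inter-domain motion between target and template; window size is a
parameter. Pre-existing target atoms are never moved — the round-trip
tests assert bit-level equality for them. Cross-residue-type grafts are
refused by default (an override exists and warns). Residue pairing between
chains uses biopython's global pairwise alignment with BLOSUM62 and affine
gaps (open 10, extend 1); pairings below 20% identity are refused as
unsafe templates. Tie-breaking among co-optimal alignments follows the
aligner's canonical first traceback, which is deterministic.

Grafted residues are recorded in the model's metadata so that downstream
network edges resting on modeled coordinates can be flagged provisional.

## Interface definition and contact typing

A protein residue belongs to the protein–DNA interface when the minimum
heavy-atom distance to any DNA atom is ≤ 3.6 Å. Contact classes are
distance-only:

| class         | condition                                              | cutoff |
|---------------|--------------------------------------------------------|--------|
| salt bridge   | charged-group atom (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2; Asp OD1/OD2; Glu OE1/OE2) vs phosphate oxygen | 4.0 Å |
| hydrogen bond | N/O pair, one donor-capable and one acceptor-capable   | 3.5 Å |
| nonpolar      | carbon vs carbon                                       | 4.5 Å |

Precedence is salt bridge > hydrogen bond > nonpolar. The 3.5 Å
donor–acceptor limit is the standard heavy-atom hydrogen-bond ceiling; the
4.5 Å nonpolar limit is this package's documented default since no
published distance is available for "non-polar contact". All cutoffs are
configurable (`ContactCutoffs`). The membership cutoff is independent of
the class cutoffs: a residue can be interface-listed by a 3.6 Å
carbon–oxygen approach that no class covers; it is then reported as
`unclassified_proximity`.

DNA atoms partition into phosphate (P, OP1, OP2, O5', O3'), sugar
(C1'–C5', O4') and base (everything else). O3' and O5' are assigned to the
phosphate because they belong to the phosphodiester linkage; "backbone" in
reports means phosphate + sugar. Distances are printed rounded half-up to
one decimal; all comparisons use full precision. Residues with minimum
distance in (cutoff, cutoff + 1 Å] are listed as near misses — a residue
at 4.4 Å is biologically adjacent to the interface and worth reporting
even though it fails the membership test.

For intra-protein contacts the same tables apply with one adjustment: a
salt bridge requires groups of *opposite* formal sign (basic vs acidic
side chain), since the protein–DNA rule's "any charged group vs phosphate
oxygen" has no meaning between two protein residues. Sequence-adjacent
(i, i±1) pairs are excluded from network edges by default to suppress
trivial backbone adjacencies; the networks of interest are side-chain
mediated.

## Conservation and uniqueness

Per-column statistics are reported only for columns where the reference is
not gapped; position p is the p-th non-gap reference residue. Gaps never
count as substitutions. "Highly variable" is operationalised as ≥ 1
non-gap substitution relative to the reference (no frequency threshold is
published; the parameter is exposed). A position is *unique* to the
reference protein when all orthologs carry the reference residue (no gaps)
and at least `min_paralog_subs` paralogs differ; the default demands every
non-reference paralog differ — the strict reading of a residue found in
the reference protein and in no other family member — and is relaxable.

## Phenotype normalisation and classification

Colony counts: fraction of WT = mutant replicate mean / WT replicate mean.
A mutant is **defective** when fraction < 0.5 **and** an exact one-sided
permutation test on the replicate values (all reassignments of the pooled
replicates enumerated; feasible at replicate scale) gives p ≤ 0.05;
**reduced** when significant but above threshold; **normal** otherwise.
The permutation test was chosen over a t-test because replicate colony
counts are small-n overdispersed count data; both threshold and α are
config values recorded in output metadata. With fewer than two replicates
the significance requirement is dropped and the record flagged. Note that
with three replicates per arm the smallest attainable one-sided p is
1/C(6,3) = 0.05, so significance at α = 0.05 requires complete separation
of the replicate sets — an intentionally conservative behaviour at the
published replicate scale.

Reporters: relative activity = (firefly/renilla of the construct) /
(firefly/renilla of the mock control). Stability: Oct4 band intensity is
divided by the co-expressed GFP intensity per timepoint and rescaled so
t = 0 equals 1; the half-life is ln 2 / k from a least-squares fit of
log(level) against time, reported undefined when the fitted slope is
non-negative.

Integration joins defect calls with interface membership, base/backbone
contact flags and uniqueness calls, one row per mutated position;
multi-site mutants stamp their class onto every mutated position and are
flagged `shared_evidence`; a position claimed by two different mutants is
an error. The 2×2 defective-vs-interface table is tested with a two-sided
Fisher exact test (scipy); the test suite checks its p-values against an
integer-exact hypergeometric enumeration on every 2×2 table with total
≤ 40. The POU-domain span defaults to mOct4 131–289 — no boundary is
published, and this span contains all POU-internal defective sites
(147–279) while excluding Y327 — and is config-overridable.

## Synthetic data

The generators exist so that every pipeline stage can be exercised against
known ground truth with no downloads; they are first-class, tested code.

**Idealised B-DNA.** Two antiparallel strands with exact helical
parameters (rise 3.38 Å, twist 36° per step) and canonical atom names for
every moiety; 5'-terminal nucleotides lack the phosphate. The per-moiety
radial layout (phosphates outermost ~9–10 Å, sugar ring ~6–7.5 Å, bases
inner) and the 154° inter-strand azimuthal offset (unequal grooves) are
stylised, not fibre-diffraction coordinates.

**Toy complexes.** Each planted residue is posed so that exactly one atom
pair realises the requested (class, moiety, distance): the designated
contact atom sits at the tip, distal side-chain atoms trail it (as bonded
neighbours would) and CB plus the polar backbone retreat farthest along
the pose axis with a small zig-zag that keeps backbones non-collinear for
window fits. Poses are searched deterministically over target nucleotides,
approach directions (radial, tilted, axial) and rolls, and validated
in-process: the planted pair must be the unique distance minimum and every
classified contact of the residue must carry exactly the planted label;
near-miss plants must stay out of the interface. Residue geometry is
therefore *stylised*: atom names and canonical atom sets are exact and
every consuming test (atom-set completeness, graft round trips, label
recovery) is meaningful, but rotamers and bond lengths are not chemical —
realistic folds are out of scope. Intra-protein network plants pose a
child residue off an anchor atom of an already-placed parent, validated so
that exactly the intended pair classifies and the child stays beyond every
class cutoff from all other residues and beyond the clearance from DNA.
In the paper-like preset the second- and third-generation anchors
(K215–Q211, T156–D159, V269–N273) use backbone carbonyl oxygens: a
backbone hydrogen bond is chemically legitimate and the carbonyl is the
one polar atom far enough from the parent's own crowded contact tip for a
clean pose to exist. Infeasible plants raise after the bounded candidate
search, naming the entry. Decoy residues are placed beyond a clearance
(default 5 Å, required > interface cutoff + 1).

**Alignments.** Ortholog sets vary only at planted positions; paralog sets
apply a substitution map in which every non-reference paralog differs at
fully-substituted positions (cycling the substitute set so each planted
substitute appears). Auto-generated references avoid colliding with
planted substitutes. Gap-free by construction; gap handling is tested on
hand-written alignments.

**Phenotype tables.** Counts are negative-binomial with variance
(1 + d)·mean, d = 0.2 by default — the dispersion parameter is the
fractional variance excess over Poisson, a mild overdispersion appropriate
for replicate colony counts. The default scenario is 90 mutants, 34
defective at effect fractions ≤ 0.2 of a WT mean of 100 colonies, 3
replicates. The paper-like integration scenario plants 33 defective sites
inside the POU span, one outside it at 0.45× WT, and 56 normal mutants.
That outlier sits deliberately close to the 0.5 classification threshold,
so single simulations occasionally miss it; the acceptance test asserts
that no other position is ever called defective outside the POU span and
that the outlier is recovered in a clear majority of replicate runs.

**What passing these tests shows — and does not.** Exact recovery of
planted labels shows the classifier, the moiety partition, the graft
machinery and the counting statistics implement their definitions
correctly. It does not validate the cutoffs against real crystallographic
geometry, water-mediated or π-type interactions (out of scope), or
alignment quality (alignments are inputs, never computed here). The two
structure-specific acceptance tests run the same code on the published
POU-domain complexes when the user supplies the PDB entries.

## Numerical choices

* Altloc ties: earlier letter wins. Alignment tie-breaks: the aligner's
  first traceback.
* Kabsch collinearity guard: second singular value ≤ 1e-8 × the first.
* PDB coordinates are written at the format's 3-decimal precision, so one
  write/parse round trip is exact to 1e-3 Å and subsequent round trips are
  bit-stable.
* Report distances: rounded half-up to 1 decimal; comparisons at full
  precision.
* Permutation and Fisher p-values are exact enumerations, no asymptotics.
* All generators are pure functions of (spec, seed); pipeline outputs
  contain no timestamps, so identical configs give byte-identical tables.

## Problem sizes

The default test and acceptance workloads use a 24-bp duplex with ~25
posed residues for the paper-like structural preset, 8-bp duplexes for
per-operation checks, 12-ortholog/16-paralog alignments of a 250-residue
reference, and 90-mutant tables at 3 replicates; recovery properties run
over 100 generator seeds. These sizes exercise every code path while
keeping the full suite fast on a single CPU.

## Known limitations

* Distance-only hydrogen bonds over-count relative to angle-aware
  definitions; with no hydrogens and no published geometric criteria this
  is the honest reproducible choice.
* Water-mediated contacts, π-stacking, cation–π and buried-surface area
  are not modelled.
* Grafting copies template geometry verbatim: no rotamer optimisation or
  clash relief, so a grafted side chain can clash where target and
  template disagree locally — the grafting report's local RMSD is the
  guard to inspect.
* The network builder reports whatever the (possibly grafted) coordinates
  support; interactions attributed in the literature to residues whose
  side chains were never modeled are not hard-coded and will appear only
  if the coordinates support them, flagged provisional.
* `map_alignment_to_structure` assumes the chain covers one contiguous
  reference span; chains with internal deletions need an explicit
  `NumberingMap`.
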