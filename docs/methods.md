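# Methods

## Bioactivity scale and curation

All potencies are expressed as bioactivity = log₁₀(value in nM); 1 µM maps to
exactly 3.0 and lower values mean more potent compounds. Only IC₅₀ and Kᵢ
measurements are retained; other measurement kinds, rows without a kinase id,
structure or value, non-positive values, and unknown unit tokens are rejected
and logged rather than silently coerced — a misread unit shifts a value by
three log units, so failing loudly is the safer default. Accepted units are
nM, µM (either micro sign or `u`), mM and M, case-insensitive.

Repeated measurements of one kinase–compound pair are averaged on the log
scale (the geometric mean of the raw potencies), once over the fully merged
record set; averaging after merging, rather than per source, keeps the result
independent of how the input happened to be partitioned into files. Strict
splits move *all* records of the held-out kinases (or compounds) to the test
side and verify the complementary invariant by exhaustive membership scan.

## Kinase encodings

The kinase catalog is an aligned FASTA of kinase-domain sequences (a
structure-validated alignment is consumed as input, never constructed here).
Characters are restricted to the 20 standard amino acids plus the gap symbol
`-`; the one-hot channel order is the amino acids alphabetically by
one-letter code, then gap — fixed so encodings are bit-stable across runs. In
strict mode non-standard residues (B, J, O, U, X, Z) are an error; a lenient
flag maps them to the gap channel with a warning, because silently inventing
a residue corrupts the encoding. The active-site representation selects a
fixed, configurable list of alignment columns (29 by default, the choice of
columns being a property of the alignment provider); columns are 0-based in
code and 1-based in YAML/CLI files.

## 2D descriptors

* **PCPP** — 208 physicochemical properties from an explicit, pinned name
  registry (topological and topochemical indices, Crippen LogP/MR, Lipinski
  counts, fragment counts). Descriptor sets drift between toolkit releases,
  so membership is pinned by name and asserted at import. Descriptors that
  raise or return non-finite values yield 0.0 with a logged warning: the
  regressor cannot consume NaN, and a zero in a standardized block is the
  least informative finite value.
* **MCFP** — the 167 MACCS structural keys.
* **MGFP** — hashed circular fingerprints of radius 2, 3 and 4 folded to
  256, 512 and 1024 bits and concatenated in that order (1792 bits). Bit
  collisions are accepted behaviour of the stated folding sizes.

Canonicalization re-parses the canonical isomeric SMILES so every descriptor
depends only on the canonical form, not on the input notation or atom
ordering. No salt stripping or standardization is applied beyond
canonicalization.

## 3D conformer-ensemble descriptor (3CED)

Conformers are embedded by ETKDG distance geometry with a fixed seed, at most
16 per molecule, pruned at 0.5 Å heavy-atom RMSD; force-field relaxation is
available but off by default (determinism and speed matter more at desk scale
than strained geometries). Pharmacophore sites are perceived with the
toolkit's base feature definitions; eight families are used: Donor, Acceptor,
NegIonizable, PosIonizable, ZnBinder, Aromatic, Hydrophobe, LumpedHydrophobe.

A signature is a (family combination, distance-bin assignment) slot. For
point count n ∈ {2, 3}, family combinations are multisets of size n and the
C(n,2) pairwise distances each take one of B ordered bins, giving

    dimension = Σₙ C(F+n−1, n) · B^C(n,2)

— with F = 8 and B = 3: 36·3 + 120·27 = **3348**. Bins are half-open
[0,3), [3,6), [6,9) Å; a pair at ≥ 9 Å contributes nothing. No symmetry
collapsing or triangle pruning is applied to the *space*: the enumeration is
deliberately the same one used by the established 2D/3D pharmacophore
signature factories, and the tests cross-check the dimension against that
independent implementation for several family subsets.

Counting convention: each unordered pair/triple of distinct perceived sites
increments exactly one slot. When families repeat, several site orderings are
consistent with the sorted family tuple; the lexicographically smallest bin
tuple is taken, which makes the count well defined and rotation/translation
invariant. Counts (not binary presence) are accumulated per conformer and the
3CED vector is the element-wise mean over the ensemble — an ensemble mean of
presence bits would discard multiplicity, and counts reduce to bits for the
sparse molecules where it matters.

## Model

Six variants pair a kinase branch (identifier one-hot, active-site slice, or
full alignment) with the 2D descriptor blocks and optionally 3CED. The
architecture uses five blocks:

* **Convolution** — same-padded 1-D convolutions over alignment positions,
  one filter bank per kernel size (defaults 3/5/7 × 64 channels), ReLU,
  then a dense projection to the embedding width. The identifier variant has
  a length-1 "sequence", for which convolution is vacuous; it uses a dense
  embedding of the catalog one-hot instead.
* **Input attention** — for the kinase branch, multi-head self-attention over
  positions (default 4 heads on a 128-wide embedding) followed by mean
  pooling; for flat descriptor blocks, a learned sigmoid gating vector
  (feature attention) multiplying a ReLU dense encoding. Self-attention over
  a flat vector has no sequence axis to attend over, so gating is the
  well-posed analogue.
* **Concatenation** of the branch embeddings.
* **Output attention** — sigmoid gating over the concatenated representation.
* **Output** — a dense head (256 → 64 → 1, ReLU) emitting bioactivity.

All weights are initialized from one seed; forward passes are deterministic.
The kinase branch is evaluated once per unique kinase and gathered per
record, which makes training cost nearly independent of how many records
share a kinase. The network and its gradients are implemented on a compact
reverse-mode autodiff engine over numpy arrays (`kinoprof.nn`); every
primitive is verified against central finite differences in the test suite.
Checkpoints store weights plus a JSON manifest (variant, shapes, seed) and
refuse to load against a mismatched parameter set.

## Training, cross-validation, consensus

Loss is MSE on the log₁₀(nM) scale. The optimizer is Adam (lr 1e-3 default;
the recovery experiments use 5e-3, chosen for fast convergence at batch 512
with standardized inputs). Defaults follow common practice for this kind of
model: up to 3000 epochs with early stopping at patience 100 on validation
loss and restoration of the best-epoch weights, batch size 512. Real-valued
blocks (PCPP, 3CED) are standardized per feature with statistics from the
training rows of each fold; binary fingerprints and one-hots are left as is.

Five-fold cross-validation shuffles records (kinase–compound pairs) with a
seeded partition — leakage across entities is handled by the separate strict
splits, not by fold grouping. The consensus predictor is the arithmetic mean
of the five fold models' outputs. Metrics are PCC, R², RMSE and MAE; a
constant truth (or prediction) vector leaves PCC/R² undefined and is flagged
rather than silently zeroed. Per-entity PCC tables include only entities with
strictly more than 10 records.

## Selectivity profiling

Calls are positive iff bioactivity ≤ cutoff (default 3.0 ↔ 1 µM; the
boundary counts as positive — the cutoff names a potency that qualifies).
For each kinase group, the contingency table (N_GP, N_OP, N_GN, N_ON) of
positive/negative calls inside/outside the group gives
OR = (N_GP/N_OP)/(N_GN/N_ON). Zero cells use Haldane's correction (+0.5 to
every cell) by default so profiles stay finite and rankable; a `limit` policy
returns 0/∞ instead. The predicted selectivity class is the argmax-OR group
with ties broken by name — an explicit rule, since "correctly assigned" has
no canonical definition. Compounds whose calls are single-class carry no
contrast and are skipped with a reason.

Method comparison min–max scales both score vectors (lower = more active) to
[0, 1], labels records at cutoffs of 0.1/1/5 µM converted to the log scale
(2.0 / 3.0 / ≈3.699), computes AUC threshold-free from ranks, and point
metrics at a scaled-score threshold of 0.5. Kinome-tree annotation export
writes (name, size, fill) rows with a monotone linear value→size map.

## Synthetic data generator

The generator emulates the statistical structure of a kinome profiling
dataset, not its biology: no real phylogeny, no real chemotypes. Defaults
define the study conditions: 40 kinases in 5 groups, alignment width 200
(standing in for the ~2.2k-column kinase-domain alignment at desk scale),
125 compounds → 5000 records, 40 % of compounds selective with a 2.0
log-unit group effect, per-kinase offsets of SD 0.3, a compound-level signal
of SD 0.7 (a realistic compound-to-compound potency spread) given by a fixed
sparse linear function of named physicochemical descriptors (MolLogP, TPSA,
rotatable bonds, z-scored over the sampled library), and Gaussian noise of
SD 0.3, all on the log scale around a 10 µM baseline. Group sequences share
a consensus mutated at ~30 % informative columns with group-specific gap
columns; members add 5 % substitution noise; the 29-column active-site map
samples the informative columns. The compound library is a committed fixture
of 212 synthetic drug-like structures (scaffold × substituent enumeration,
all RDKit-valid and 3D-embeddable).

What passing recovery tests shows: the pipeline can learn a planted
kinase-group × compound interaction plus additive structure from the exact
representations the model consumes, and the odds-ratio machinery recovers
planted selectivity. What it does not show: performance on real kinome data,
whose noise is assay-dependent and whose sequence–activity relationship is
far richer than the planted linear-plus-interaction form.

## Problem sizes and numerical choices

The recovery experiment uses the 5000-record simulation with a 1000-record
held-out set and five-fold cross-validation of the full-alignment + 3CED
variant at reduced widths (conv 16 channels, kernel 5, 2 heads, embedding 64,
head 256→64), 60 epochs maximum at patience 15 — sizes chosen so the full
experiment runs in minutes on one CPU while leaving clear headroom above the
0.8 PCC recovery bar. Tolerances: one-hot and signature checks are exact
integer comparisons; float comparisons use numpy defaults (rtol 1e-7) unless
a stochastic quantity warrants wider bands (AUC null ±0.05). Ties in
bin assignment and group argmax are broken lexicographically. Degenerate
inputs (empty ensembles, all-zero contingency tables, constant truth
vectors, empty train/validation sets) raise or are flagged explicitly.

## Known limitations

* The 208-descriptor registry membership is a pinned dialect; other toolkit
  versions print different descriptor sets.
* Pharmacophore perception follows the toolkit's base feature definitions;
  a different feature dictionary changes signatures (the space dimension only
  through F).
* The autodiff engine is minimal by design: CPU only, no convolution stride
  or dilation, no dropout/batch-norm.
* Odds ratios carry no significance test; profiles rank groups, they do not
  test hypotheses.
* Kinase point mutations are out of scope; the catalog is the unit of
  identity.
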