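# Methods

## Contact model

A protein residue is an *interacting* (binding-site) residue of a ligand
instance when the minimum Euclidean distance between any heavy atom of
the residue and any atom of the ligand is at most a cutoff, 4.0 Å by
default. This is a plain distance criterion: no surface complementarity,
interaction typing (H-bond vs hydrophobic) or energy model is applied.
Parsing conventions, chosen to match what a typical X-ray PDB entry
provides:

* only the first model of a multi-model file is used;
* hydrogens and deuteriums are discarded before distance evaluation;
* for altloc duplicates the highest-occupancy conformer is kept (ties:
  first in file);
* waters (HOH/WAT/DOD) are never ligands; the 20 standard amino acids are
  never ligands; every other het code is an eligible ligand. Modified
  amino acids therefore appear as het groups and are excluded from
  polymer statistics;
* insertion codes are part of residue identity.

One *binding site* is one (structure, chain, ligand instance) triple with
at least one contact. The per-ligand aggregate counts R_i (interacting
residues of type i, summed over sites; duplicate contacts of one residue
by one ligand instance count once) and N_i (all standard residues of the
site's chain, accumulated once per site). Accumulating N per site rather
than per distinct chain is deliberate: when k ligand copies bind one
chain, both R and N grow k-fold, preserving 0 ≤ R_i ≤ N_i, which a
per-chain denominator would violate. A dataset filter retains ligands
with at least `min_sites` binding sites (default 30, inclusive).

## Statistics

With N = ΣR_i the total number of interacting residues:

* composition RC_i = 100 R_i / N (sums to 100);
* propensity RP_i = 100 R_i / N_i. Types with N_i = 0 receive RP 0 and an
  `absent` flag instead of being dropped, so 20-vectors stay aligned;
* normalized propensity NP_i = 9 (RP_i − P_min)/(P_max − P_min), where
  P_min/P_max range over the 20 types. A constant RP vector maps to all
  zeros — the conservative "no preference" signal;
* preference categories: low if RP < 5, moderate if 5 ≤ RP ≤ 12, high if
  RP > 12 (both boundary values read as moderate);
* physicochemical composition PC_i = 100 P_i / N over eight classes
  (charged DEKHR; acidic DE; basic KRH; small PACGSNDTV; polar STYNQ;
  non-polar AVLIPFWMCG; aromatic FYW; aliphatic LIVAG). Classes overlap,
  so PC entries do not sum to 100, but acidic + basic = charged exactly.

The pooled "average ligand" reference (AVR) is the composition of the
element-wise sum of interacting counts across datasets.

## Ligand comparison and clustering

Three Euclidean metrics compare ligands p and q: CED over RC (20 terms),
PED over RP (20 terms, percent scale — deliberately not the 0–9 NP,
which would discard the overall contact-rate scale), and PCED over PC.
The PCED sum runs over the 8 property classes, the dimensionality the
class table actually defines. Distance matrices feed scipy's
agglomerative linkage (complete by default; average and single are
selectable). Ligands are reordered lexicographically before linkage, so
ties break deterministically by ligand id and the tree is invariant to
input order. Trees serialize to Newick with branch length = parent merge
height − child merge height, so every leaf's root distance equals the
root merge height under a monotone linkage.

## Prediction

A query position's score depends only on its residue type: raw score =
RP, digit = NP rounded half-up (floor(NP + 0.5)) to an integer 0–9.
Positions with 'X' score 0, are flagged, and are excluded from
evaluation. Binary calls are digit ≥ threshold (default 5). Evaluation
reports per-residue accuracy 100(TP+TN)/(TP+TN+FP+FN) plus sensitivity
and specificity, so stricter or more lenient readings of "accuracy" can
be reconstructed from the counts.

## Windows and enrichment

Every sequence position is the centre of one window of odd length
(default 21), termini padded with 'X'; windows are partitioned by the
central residue's label, so |interacting| + |non-interacting| equals the
sequence length. Redundancy reduction is a documented greedy rule:
process sequences in input order, retain one iff its identity to every
retained sequence is below the threshold (default 0.30), where identity
= matches / alignment length under global alignment with match 1,
mismatch 0, linear gap −1 (Biopython's PairwiseAligner).

The per-cell neighbourhood statistic is a pooled two-proportion z-test
of residue frequency at a window position, interacting vs
non-interacting sets — proportions are the quantity a two-sample logo
actually displays, which is why a z-test on proportions is used rather
than a t-test; the correction method is selectable (Bonferroni default)
over window_length × 20 tests. The 'X' padding column carries
frequencies but is never tested. Motif *discovery* is delegated:
windows export as MEME/WebLogo-ready FASTA rather than re-implementing
an EM motif finder.

## Synthetic generators

* **Toy complexes** place a 3-atom ligand at the origin and residues
  (Cα + side-chain centroid, a reduced atom model sufficient for a
  purely distance-based rule) on per-residue directions, contact
  residues at ≤ cutoff − 0.2 Å and all others at ≥ cutoff + 1.2 Å, so
  the designated contact set is recovered exactly and with margin.
  Output is standard PDB text via gemmi; identical seeds give identical
  bytes.
* **Planted datasets** draw chains with uniform residue composition
  (default; a balanced mode tiles the 20-letter alphabet for exact
  per-type totals) and label each position interacting with probability
  p_i of its type, independently. RP_i/100 is then the maximum-likelihood
  estimate of p_i with binomial error √(p_i(1−p_i)/N_i), and a digit-
  threshold call rule has the closed-form accuracy Σ w_i·(p_i if type
  called positive else 1−p_i)/Σ w_i. Every generated chain is kept as a
  site, including chains without any interacting position, so the
  degenerate all-zero-probability case still yields a dataset.
* **Planted ligand groups** build exact-count datasets (R_i = round(N_i
  p_i), no sampling noise) around group centroids that boost the contact
  probability of a signature residue set by separation/200; signature
  sets (DE, FWY, KRH, ILV, STQ, AGP) have distinct physicochemical
  classes, so groups separate in composition, propensity *and* property
  space. Per-ligand jitter is uniform with amplitude separation/(1000·√20)
  per coordinate, capping the within-group spread at separation/5 in
  propensity units. Separations above ≈ 180 would clip probabilities at
  their [0.005, 0.95] bounds and weaken the guarantee.

What the generators do **not** emulate: real backbone geometry and
side-chain rotamers, crystallographic noise and resolution limits,
correlation of contacts along the chain, homology between chains, and
non-uniform residue usage of real proteomes. Passing the planted-model
tests therefore demonstrates correctness of the statistics and
algorithms, not predictive performance on real structures.

## Numerical choices and edge cases

* Composition/propensity of an all-zero count vector is an error, not a
  NaN vector.
* A dataset with R_i > N_i is rejected as inconsistent.
* Sensitivity (specificity) is NaN when no actual positives (negatives)
  exist rather than silently 0.
* The z statistic is 0 where the pooled proportion is degenerate (0 or 1).
* Distance-matrix symmetry is validated to 1e-9 before clustering.
* Problem sizes in the test suite and acceptance script (100 toy
  complexes, 1,000 random vectors/triples, 10,000 residues per type,
  50 clustering seeds, 100 enrichment nulls) were chosen so each
  stochastic bound is comfortably resolvable (3σ binomial arguments)
  while the whole run completes in seconds.

## Known limitations

* No mmCIF input; PDB text only. No NMR ensemble averaging (first model
  only).
* The contact rule ignores interaction chemistry; a 4 Å contact may be a
  clash or a crystal artefact in real data.
* Propensity prediction is type-based only: every occurrence of a
  residue type in a query receives the same digit, so it localizes
  *regions* enriched in preferred types, not specific sites.
* The greedy identity filter is order-dependent by design (documented
  rule, reproducible), and global-alignment identity between unrelated
  random sequences is inflated by the permissive mismatch score; very
  low thresholds are aggressive.
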