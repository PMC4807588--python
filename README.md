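# ligprop

Analysis, comparison and prediction of protein–ligand binding sites from
residue preference statistics.

`ligprop` is for structural bioinformaticians who want to know *which
amino acids a ligand prefers at its binding sites* and to exploit that
preference. It extracts binding-site residues from protein–ligand
complexes, turns them into per-ligand statistics, compares and clusters
ligands by those statistics, and predicts likely ligand-interacting
residues in new sequences — no machine-learning model, just transparent
propensity scores.

## The statistics at the core

A residue belongs to a binding site when any of its heavy atoms lies
within 4 Å of any ligand atom. From all binding sites of one ligand the
package computes, per residue type *i*:

* **composition** RC_i = 100 · R_i / N, the percent share of type *i*
  among interacting residues (R_i interacting residues of type *i*, N
  interacting residues in total);
* **propensity** RP_i = 100 · R_i / N_i, the contact rate of type *i*
  (N_i = all residues of type *i* in the contributing chains), min–max
  normalized to the digit scale NP_i = 9 · (RP_i − P_min)/(P_max − P_min)
  and bucketed into low (< 5), moderate (5–12) and high (> 12) preference;
* **physicochemical-class composition** PC_i = 100 · P_i / N over eight
  (overlapping) classes: charged, acidic, basic, small, polar, non-polar,
  aromatic, aliphatic.

Ligand pairs (p, q) are compared by Euclidean distances over these
vectors — CED (composition), PED (propensity), PCED (class composition) —
and clustered agglomeratively from the resulting distance matrix.
Prediction writes a digit track: each query position gets the rounded
NP of its residue type, and digits ≥ a threshold (default 5) are called
as likely interacting.

For logo and motif work the package also builds all overlapping
21-residue windows classified by whether the central residue interacts,
reduces chain sets to a non-redundant subset, and scores per-position
residue enrichment with a two-proportion z-test (Bonferroni-corrected).

## Worked example

Scripts in `examples/` each demonstrate one capability end to end.
`examples/04_predict_binding_residues.py` estimates a propensity table
from planted training chains and scores an unseen sequence:

```
TGDGKTLCHPTRYEVCNGFQHNGERKQQWKFPWYVQIIAEHHNMQVVSYHWWFLNQRDLD
335303973438024723093232809960046049007233269447036609298595

accuracy 70.0 %  sensitivity 71.4 %  specificity 69.6 %  (TP=10 FP=14 TN=32 FN=4)
```

The digit under each residue is its ligand propensity rescaled to 0–9;
runs of high digits mark candidate interaction regions, and the report
compares the digit ≥ 5 calls with the true planted labels.

The same operations are available from the shell:

```bash
ligprop analyze --pdb-dir pdbs/ --ligand ATP --cutoff 4.0 --min-sites 30 --out atp
ligprop stats   --dataset atp.dataset.json --out atp
ligprop compare --stats-dir datasets/ --metric propensity --linkage complete --out cmp
ligprop predict --fasta query.fasta --dataset atp.dataset.json --threshold 5 --out pred
ligprop windows --dataset atp.dataset.json --length 21 --nr 0.30 --out win
ligprop fixtures toy-complex --seed 1 --out fixtures/
```

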