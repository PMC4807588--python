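"""Propensity-based prediction of ligand-interacting residues.

Estimates a propensity table from planted training chains, scores an
unseen query as a 0-9 digit track (displayed under the sequence), calls
positions with digit >= 5 and evaluates against the true labels.
"""

import numpy as np

from ligprop import (
    PlantedProfile,
    evaluate_track,
    format_track,
    make_planted_dataset,
    predict_binding,
    propensity,
    score_sequence,
)

rng = np.random.default_rng(5)
probs = rng.uniform(0.02, 0.5, size=20)

train = make_planted_dataset(
    PlantedProfile(contact_probs=probs, n_chains=300, chain_length=200, seed=1)
)
table = propensity(train)

test = make_planted_dataset(
    PlantedProfile(contact_probs=probs, n_chains=1, chain_length=60, seed=2)
)
query = test.chains[0]

track = predict_binding(score_sequence(query.sequence, table), threshold=5)
print(format_track(track))

labels = np.zeros(len(query.sequence), dtype=bool)
labels[[p - 1 for p in query.interacting_positions]] = True
report = evaluate_track(track, labels)
print(
    f"\naccuracy {report.accuracy:.1f} %  "
    f"sensitivity {report.sensitivity:.1f} %  "
    f"specificity {report.specificity:.1f} %  "
    f"(TP={report.tp} FP={report.fp} TN={report.tn} FN={report.fn})"
)
# The digit under each residue is its ligand propensity rescaled to 0-9;
# runs of high digits mark the regions most likely to contact the ligand.
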