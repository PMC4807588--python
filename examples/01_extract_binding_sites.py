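"""Extract ligand binding-site residues from protein-ligand complexes.

Builds three small synthetic ATP complexes with known contact residues,
parses them back from PDB text, applies the 4 Å heavy-atom contact rule
and aggregates everything into a per-ligand dataset.
"""

from ligprop import (
    ToyComplexSpec,
    build_dataset,
    contacts_to_table,
    extract_contacts,
    make_toy_complex,
    parse_structure,
)

models = []
for seed in (1, 2, 3):
    spec = ToyComplexSpec(
        length=25,
        contact_positions={3, 9, 15, 21},
        ligand_code="ATP",
        seed=seed,
        structure_id=f"toy{seed}",
    )
    models.append(parse_structure(make_toy_complex(spec), structure_id=spec.structure_id))

# contacts of the first complex: one row per residue within 4 Å of ATP
model = models[0]
records = extract_contacts(model, model.het_groups[0], cutoff=4.0)
print(contacts_to_table(records).to_string(index=False))

# aggregate all three structures into one ATP dataset
dataset = build_dataset(models, "ATP", cutoff=4.0)
print(
    f"\nATP dataset: {dataset.site_count} binding sites, "
    f"{int(dataset.interacting_counts.sum())} interacting residues out of "
    f"{int(dataset.total_counts.sum())} total residues"
)
# Each row above is a residue whose minimum heavy-atom distance to any ATP
# atom is <= 4 Å; the dataset counts (R_i, N_i) feed all later statistics.
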