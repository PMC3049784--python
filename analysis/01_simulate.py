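#!/usr/bin/env python
"""Generate the planted replica data set.

Simulates the 18-sample CD34+ expression experiment (3 tissues x G0/G1 x
3 replicates, 43,356 probes) and the 646-protein LC/MS table, both with
the planted overlap structure described in engraftlogic.designs, plus the
per-tissue Ki67 qRT-PCR sort-purity values and the protein->gene id map.

Writes everything under results/01_data/ and prints the planted region
counts that later stages are expected to recover.
"""

from pathlib import Path

from engraftlogic import io as elio
from engraftlogic.designs import expression_replica_design, protein_replica_design
from engraftlogic.simulate import generate_expression, generate_ki67, generate_protein_table, plant_id_map

SEED = 1
OUT = Path("results/01_data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    design = expression_replica_design()
    matrix, gene_gt = generate_expression(design, seed=SEED)
    elio.write_matrix(matrix, OUT / "expression.tsv", OUT / "samples.tsv")
    elio.write_ground_truth(gene_gt, OUT / "ground_truth_genes.tsv")

    prot_design = protein_replica_design()
    table, prot_gt = generate_protein_table(prot_design, seed=SEED + 1)
    table.feature_meta.join(table.values).rename_axis("protein_id").to_csv(
        OUT / "proteins.tsv", sep="\t"
    )
    table.samples.rename_axis("sample_id").to_csv(OUT / "protein_samples.tsv", sep="\t")
    elio.write_ground_truth(prot_gt, OUT / "ground_truth_proteins.tsv")

    ki67 = generate_ki67(0.93)
    ki67.to_csv(OUT / "ki67.tsv", sep="\t")

    id_map = plant_id_map(prot_gt, gene_gt, n_matched=10, seed=SEED + 2)
    id_map.to_csv(OUT / "id_map.tsv", sep="\t", index=False)

    print(f"expression: {matrix.values.shape[0]} probes x {matrix.values.shape[1]} samples")
    print(f"proteins:   {table.values.shape[0]} proteins x {table.values.shape[1]} samples")
    print("\nplanted gene classes:")
    print(gene_gt["label"].value_counts().to_string())
    print("\nplanted protein classes (priority 1-2 only):")
    p12 = prot_gt[prot_gt["priority"].isin([1, 2])]
    print(p12["label"].value_counts().to_string())
    print(f"\nKi67 G0/G1 reduction: {1 - ki67['G0'].iloc[0] / ki67['G1'].iloc[0]:.0%} in all tissues")
    print(f"id map: {len(id_map)} protein->gene links (10 planted DE matches)")


if __name__ == "__main__":
    main()
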