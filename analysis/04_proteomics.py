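#!/usr/bin/env python
"""Protein-level differential expression and transcript concordance.

Reads the simulated protein table from results/01_data/, calls G0-vs-G1
differential protein expression per tissue (fold >= 1.5, BH FDR < 5%,
priorities 1-2), applies the same target subtraction as the gene side,
and matches the all-priority BM DE proteins to the BM DE genes through
the id map.  Outputs under results/04_proteomics/.
"""

from pathlib import Path

import pandas as pd

from engraftlogic import io as elio
from engraftlogic.de import de_set
from engraftlogic.matrix import TISSUES
from engraftlogic.proteomics import concordance, identify_target_proteins, test_de_proteins
from engraftlogic.targets import venn

IN = Path("results/01_data")
IN_DE = Path("results/02_de")
OUT = Path("results/04_proteomics")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = elio.read_matrix(
        IN / "proteins.tsv", IN / "protein_samples.tsv", meta_columns=("priority",)
    )

    print("protein DE at fold>=1.5, FDR<5%, priorities 1-2:")
    calls = {}
    for tissue in TISSUES:
        c = test_de_proteins(table, tissue)
        calls[tissue] = c
        elio.write_calls(c, OUT / f"protein_de_{tissue}.tsv")
        print(f"  {tissue:>3}: {int(c['is_de'].sum()):3d} DE proteins")

    summary = venn(*(de_set(calls[t]) for t in TISSUES))
    elio.write_json(summary.to_dict(), OUT / "protein_venn.json")
    print(f"\ncommon DE in all three tissues: {summary.triple}")
    print(f"common DE in BM and MPB:        {summary.bm_mpb}")

    targets = identify_target_proteins(calls["BM"], calls["MPB"], calls["UCB"])
    elio.write_calls(targets, OUT / "target_proteins.tsv")
    print(f"target proteins (BM∩MPB \\ UCB): {len(targets)}")

    bm_all = test_de_proteins(table, "BM", priorities={1, 2, 3, 4})
    print(f"\nBM DE proteins at all priorities: {int(bm_all['is_de'].sum())}")
    id_map = pd.read_csv(IN / "id_map.tsv", sep="\t")
    gene_calls = elio.read_calls(IN_DE / "de_BM.tsv")
    rep = concordance(de_set(gene_calls), de_set(bm_all), id_map)
    elio.write_json({k: v for k, v in rep.items() if k != "matched_proteins"},
                    OUT / "concordance.json")
    print(f"matched to BM DE genes by ID:     {rep['n_matched']}")
    print(f"unmapped (hypothetical/putative): {rep['n_unmapped']}")


if __name__ == "__main__":
    main()
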