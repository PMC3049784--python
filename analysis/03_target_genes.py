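#!/usr/bin/env python
"""Engraftment-target inference and direction-pattern analysis.

Reads the per-tissue DE calls from results/02_de/, decomposes the three
DE sets into Venn regions, subtracts the UCB (cell-cycle) signal from the
BM∩MPB overlap to obtain the target genes, classifies their cross-tissue
direction patterns, extracts the concordant subset, and clusters the
target expression profiles (average linkage, Euclidean).  Outputs under
results/03_targets/.
"""

from pathlib import Path

from engraftlogic import io as elio
from engraftlogic.de import de_set
from engraftlogic.matrix import TISSUES
from engraftlogic.de import normalize_median
from engraftlogic.patterns import classify_patterns, concordant_subset, hcluster, linkage_to_newick, profile_matrix
from engraftlogic.targets import venn, identify_targets

IN_DATA = Path("results/01_data")
IN_DE = Path("results/02_de")
OUT = Path("results/03_targets")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    calls = {t: elio.read_calls(IN_DE / f"de_{t}.tsv") for t in TISSUES}

    summary = venn(*(de_set(calls[t]) for t in TISSUES))
    elio.write_json(summary.to_dict(), OUT / "venn.json")
    print(f"BM∩MPB common DE genes:        {summary.bm_mpb}")
    print(f"  of which also DE in UCB:     {summary.triple}")

    targets = identify_targets(calls["BM"], calls["MPB"], calls["UCB"])
    print(f"target genes (BM∩MPB \\ UCB):   {len(targets)}"
          f"  [{summary.bm_mpb} - {summary.triple} = {summary.bm_mpb - summary.triple}]")

    classes, counts = classify_patterns(targets)
    targets["pattern_class"] = classes
    elio.write_calls(targets, OUT / "targets.tsv")
    elio.write_json(counts, OUT / "pattern_counts.json")
    print("\ndirection patterns of the targets:")
    for k, n in counts.items():
        print(f"  {k:>13}: {n}")
    conc = concordant_subset(classes)
    print(f"concordant (same direction in BM and MPB): {len(conc)}"
          f"  [{counts['UP_G0_BOTH']} + {counts['UP_G1_BOTH']}]")
    print(f"aberrant patterns:                         {len(targets) - len(conc)}")

    matrix = elio.read_matrix(IN_DATA / "expression.tsv", IN_DATA / "samples.tsv")
    linkage, leaves = hcluster(profile_matrix(normalize_median(matrix), targets.index))
    (OUT / "targets_tree.nwk").write_text(linkage_to_newick(linkage, leaves) + "\n")
    print(f"\nwrote average-linkage tree over {len(leaves)} targets to {OUT/'targets_tree.nwk'}")


if __name__ == "__main__":
    main()
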