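"""Label-free protein differential expression and transcript concordance.

Protein fold change is defined as the largest-to-smallest group-mean
intensity ratio (so it is always >= 1), thresholded at 1.5-fold on the
linear scale, with significance controlled at FDR < 5% by
Benjamini-Hochberg over the tested protein set.  Only proteins whose
identification quality rank (priority 1-4) falls in the requested subset
are tested; priorities 1-2 — the high-confidence identifications — are
the default.  The engraftment-target subtraction and the
transcript-protein ID-matching concordance sit on top.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from engraftlogic.matrix import ExpressionMatrix
from engraftlogic.de import welch_pvalues
from engraftlogic.targets import identify_targets


def test_de_proteins(
    table: ExpressionMatrix,
    tissue: str,
    fold_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    priorities: frozenset[int] | set[int] = frozenset({1, 2}),
) -> pd.DataFrame:
    """Call G0-vs-G1 differential protein expression for one tissue.

    ``table.feature_meta`` must carry a ``priority`` column.  Returns one
    row per tested protein: tissue, fold_change (max/min group mean,
    >= 1), direction, p_value (Welch t on log2 intensities), q_value (BH)
    and is_de (fold_change >= ``fold_threshold`` AND q_value <
    ``fdr_threshold``).
    """
    if table.feature_meta is None or "priority" not in table.feature_meta:
        raise ValueError("protein table lacks priority metadata")
    priorities = set(priorities)
    if not priorities <= {1, 2, 3, 4}:
        raise ValueError(f"priorities must be a subset of 1..4, got {sorted(priorities)}")
    keep = table.feature_meta.index[table.feature_meta["priority"].isin(priorities)]
    if len(keep) == 0:
        raise ValueError(f"no proteins left after priority filter {sorted(priorities)}")
    g0_cols = table.group_columns(tissue, "G0")
    g1_cols = table.group_columns(tissue, "G1")
    if len(g0_cols) < 2 or len(g1_cols) < 2:
        raise ValueError(
            f"tissue {tissue!r} needs >=2 replicates per phase "
            f"(found G0={len(g0_cols)}, G1={len(g1_cols)})"
        )
    g0 = table.values.loc[keep, g0_cols].to_numpy()
    g1 = table.values.loc[keep, g1_cols].to_numpy()
    m0, m1 = g0.mean(axis=1), g1.mean(axis=1)
    fold = np.maximum(m0, m1) / np.minimum(m0, m1)
    p = welch_pvalues(np.log2(g0), np.log2(g1))
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "tissue": tissue,
            "fold_change": fold,
            "direction": np.where(m0 > m1, "up_G0", "up_G1"),
            "p_value": p,
            "q_value": q,
            "is_de": (fold >= fold_threshold) & (q < fdr_threshold),
            "priority": table.feature_meta.loc[keep, "priority"],
        },
        index=pd.Index(keep, name="protein_id"),
    )


def identify_target_proteins(
    calls_bm: pd.DataFrame, calls_mpb: pd.DataFrame, calls_ucb: pd.DataFrame
) -> pd.DataFrame:
    """Protein analog of the gene-level target subtraction: (BM∩MPB)\\UCB."""
    return identify_targets(calls_bm, calls_mpb, calls_ucb)


def concordance(
    gene_set, protein_set, id_map: pd.DataFrame
) -> dict:
    """Transcript-protein agreement by ID matching.

    ``id_map`` is a partial protein->gene mapping (columns protein_id,
    gene_id); proteins absent from it are counted as unmapped — the
    expected case for hypothetical/putative identifications.  Returns a
    report dict with the matched proteins (mapped gene is in
    ``gene_set``), their count, and the unmapped-protein count.
    """
    genes = set(gene_set)
    proteins = set(protein_set)
    mapping = dict(zip(id_map["protein_id"], id_map["gene_id"]))
    matched = sorted(p for p in proteins if mapping.get(p) in genes)
    unmapped = sorted(p for p in proteins if p not in mapping)
    return {
        "n_proteins": len(proteins),
        "n_matched": len(matched),
        "matched_proteins": matched,
        "n_unmapped": len(unmapped),
    }
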