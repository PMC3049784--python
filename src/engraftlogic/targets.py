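"""Cross-tissue set subtraction: the engraftment-target inference step.

The comparative logic rests on three observations about CD34+ cells:
engraftment of BM and MPB cells is restricted to the quiescent G0
fraction; UCB cells engraft regardless of phase; hence genes whose
G0-vs-G1 differential expression is shared by BM and MPB but absent from
UCB are candidates for controlling engraftment rather than cell-cycle
progression.  Operationally: targets = (DE_BM ∩ DE_MPB) \\ DE_UCB.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class VennSummary:
    """Disjoint-region decomposition of the three DE sets."""

    bm_only: int
    mpb_only: int
    ucb_only: int
    bm_mpb_only: int
    bm_ucb_only: int
    mpb_ucb_only: int
    triple: int

    @property
    def bm_total(self) -> int:
        return self.bm_only + self.bm_mpb_only + self.bm_ucb_only + self.triple

    @property
    def mpb_total(self) -> int:
        return self.mpb_only + self.bm_mpb_only + self.mpb_ucb_only + self.triple

    @property
    def ucb_total(self) -> int:
        return self.ucb_only + self.bm_ucb_only + self.mpb_ucb_only + self.triple

    @property
    def bm_mpb(self) -> int:
        """|BM ∩ MPB| including the triple overlap."""
        return self.bm_mpb_only + self.triple

    @property
    def union(self) -> int:
        return (
            self.bm_only + self.mpb_only + self.ucb_only + self.bm_mpb_only
            + self.bm_ucb_only + self.mpb_ucb_only + self.triple
        )

    def to_dict(self) -> dict[str, int]:
        return {
            "BM_only": self.bm_only,
            "MPB_only": self.mpb_only,
            "UCB_only": self.ucb_only,
            "BM_MPB_only": self.bm_mpb_only,
            "BM_UCB_only": self.bm_ucb_only,
            "MPB_UCB_only": self.mpb_ucb_only,
            "BM_MPB_UCB": self.triple,
            "BM_total": self.bm_total,
            "MPB_total": self.mpb_total,
            "UCB_total": self.ucb_total,
            "BM_MPB": self.bm_mpb,
        }


def _as_set(s, name: str) -> set:
    items = list(s)
    out = set(items)
    if len(out) != len(items):
        raise ValueError(f"duplicate feature ids in {name} DE set")
    return out


def venn(de_bm, de_mpb, de_ucb) -> VennSummary:
    """Exact disjoint-region decomposition of three DE feature sets."""
    bm = _as_set(de_bm, "BM")
    mpb = _as_set(de_mpb, "MPB")
    ucb = _as_set(de_ucb, "UCB")
    triple = bm & mpb & ucb
    return VennSummary(
        bm_only=len(bm - mpb - ucb),
        mpb_only=len(mpb - bm - ucb),
        ucb_only=len(ucb - bm - mpb),
        bm_mpb_only=len((bm & mpb) - ucb),
        bm_ucb_only=len((bm & ucb) - mpb),
        mpb_ucb_only=len((mpb & ucb) - bm),
        triple=len(triple),
    )


def identify_targets(
    calls_bm: pd.DataFrame,
    calls_mpb: pd.DataFrame,
    calls_ucb: pd.DataFrame,
    direction_aware: bool = False,
) -> pd.DataFrame:
    """Return (BM∩MPB)\\UCB with per-tissue fold changes attached.

    Inputs are per-tissue DE call tables (from :func:`engraftlogic.de.test_de`
    or its protein analog) over a common feature universe.  Subtraction is
    membership-based: a feature DE in UCB in any direction is removed.
    With ``direction_aware=True`` (sensitivity variant) a UCB call only
    removes a feature when its UCB direction matches its BM direction.

    The result satisfies |targets| = |BM∩MPB| - |BM∩MPB∩UCB| exactly
    (membership semantics; the identity is the disjoint-region one).
    """
    from engraftlogic.de import de_set

    bm = de_set(calls_bm)
    mpb = de_set(calls_mpb)
    ucb = de_set(calls_ucb)
    _as_set(calls_bm.index, "BM"), _as_set(calls_mpb.index, "MPB")
    common = bm & mpb
    if direction_aware:
        ucb_dir = calls_ucb["direction"]
        bm_dir = calls_bm["direction"]
        removed = {f for f in common & ucb if ucb_dir.get(f) == bm_dir.get(f)}
    else:
        removed = common & ucb
    kept = sorted(common - removed)
    out = pd.DataFrame(
        {
            "fc_BM": calls_bm.loc[kept, "fold_change"],
            "fc_MPB": calls_mpb.loc[kept, "fold_change"],
            "fc_UCB": calls_ucb["fold_change"].reindex(kept),
            "direction_BM": calls_bm.loc[kept, "direction"],
            "direction_MPB": calls_mpb.loc[kept, "direction"],
        },
        index=pd.Index(kept, name="feature_id"),
    )
    out.attrs["provenance"] = "targets = (BM DE ∩ MPB DE) \\ UCB DE"
    return out


def ki67_gate(
    ki67_g0: float, ki67_g1: float, min_reduction: float = 0.90
) -> tuple[bool, float]:
    """Sort-purity QC gate on relative Ki67 expression.

    A clean G0 sort must show Ki67 at least ``min_reduction`` (default
    90%) lower in G0 than in G1 cells; the bound is inclusive, and purer
    sorts (larger reductions) always pass.  Returns (passed, reduction).
    """
    if ki67_g0 <= 0 or ki67_g1 <= 0:
        raise ValueError("Ki67 expression values must be positive")
    reduction = 1.0 - ki67_g0 / ki67_g1
    return reduction >= min_reduction, reduction
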