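"""Shipped planted designs replicating the study's printed overlap structure.

The expression design plants, over 43,356 features, per-tissue G0-vs-G1 DE
totals of 10,256 (BM), 1,705 (MPB) and 2,685 (UCB) with the printed
direction splits (BM 4522 up-G0 / 5734 up-G1; MPB 840/865; UCB 1432/1253),
a BM∩MPB overlap of 643 containing a 159-gene triple overlap, and the four
direction-pattern classes 132/207/54/91 inside the 484-gene target region.
The BM∩UCB-only and MPB∩UCB-only regions are set to zero (no printed
counts constrain them); single-tissue counts absorb the remainder, and the
triple overlap is split 80 up-G0 / 79 up-G1 so every per-tissue direction
margin is met exactly.

The protein design plants, over 646 proteins, priority-1&2 DE totals of
25 (BM), 12 (MPB) and 22 (UCB) with a triple overlap of 7 and BM∩MPB of
11 (hence 4 target proteins), plus 37 further BM-only DE proteins at
priorities 3/4 so that the all-priority BM DE count is 62.
"""

from __future__ import annotations

from engraftlogic.simulate import PlantedDesign, RegionSpec, UP_G0, UP_G1


def expression_replica_design(
    effect_size: float = 2.0,
    noise_sd: float = 0.1,
    replicates_per_group: int = 3,
    n_features: int = 43356,
) -> PlantedDesign:
    """Expression design reproducing the printed Venn and pattern counts."""
    regions = (
        # target region: DE in BM and MPB, unchanged in UCB
        RegionSpec((("BM", UP_G0), ("MPB", UP_G0)), 132),
        RegionSpec((("BM", UP_G1), ("MPB", UP_G1)), 207),
        RegionSpec((("BM", UP_G0), ("MPB", UP_G1)), 54),
        RegionSpec((("BM", UP_G1), ("MPB", UP_G0)), 91),
        # cell-cycle region: DE in all three tissues
        RegionSpec((("BM", UP_G0), ("MPB", UP_G0), ("UCB", UP_G0)), 80),
        RegionSpec((("BM", UP_G1), ("MPB", UP_G1), ("UCB", UP_G1)), 79),
        # tissue-specific remainders completing the printed margins
        RegionSpec((("BM", UP_G0),), 4256),
        RegionSpec((("BM", UP_G1),), 5357),
        RegionSpec((("MPB", UP_G0),), 537),
        RegionSpec((("MPB", UP_G1),), 525),
        RegionSpec((("UCB", UP_G0),), 1352),
        RegionSpec((("UCB", UP_G1),), 1174),
    )
    return PlantedDesign(
        n_features=n_features,
        regions=regions,
        effect_size=effect_size,
        noise_sd=noise_sd,
        replicates_per_group=replicates_per_group,
        feature_prefix="G",
    )


def protein_replica_design(
    effect_size: float = 1.0,
    noise_sd: float = 0.1,
    replicates_per_group: int = 4,
    n_features: int = 646,
) -> PlantedDesign:
    """Protein design reproducing the printed priority-1&2 DE structure."""
    regions = (
        # 4 target proteins (BM∩MPB, not UCB), priorities 1-2
        RegionSpec((("BM", UP_G0), ("MPB", UP_G0)), 2, priority=1),
        RegionSpec((("BM", UP_G1), ("MPB", UP_G1)), 2, priority=2),
        # 7 proteins DE in all three tissues
        RegionSpec((("BM", UP_G0), ("MPB", UP_G0), ("UCB", UP_G0)), 4, priority=1),
        RegionSpec((("BM", UP_G1), ("MPB", UP_G1), ("UCB", UP_G1)), 3, priority=2),
        # single-tissue remainders at priorities 1-2
        RegionSpec((("BM", UP_G0),), 7, priority=1),
        RegionSpec((("BM", UP_G1),), 7, priority=2),
        RegionSpec((("MPB", UP_G0),), 1, priority=1),
        RegionSpec((("UCB", UP_G0),), 8, priority=1),
        RegionSpec((("UCB", UP_G1),), 7, priority=2),
        # additional BM-only DE proteins at low identification quality,
        # bringing the all-priority BM DE total to 62
        RegionSpec((("BM", UP_G0),), 19, priority=3),
        RegionSpec((("BM", UP_G1),), 18, priority=4),
    )
    return PlantedDesign(
        n_features=n_features,
        regions=regions,
        effect_size=effect_size,
        noise_sd=noise_sd,
        replicates_per_group=replicates_per_group,
        baseline_log2_mean=20.0,
        baseline_log2_sd=2.0,
        feature_prefix="P",
    )
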