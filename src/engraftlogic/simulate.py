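"""Planted-truth simulator for expression and protein tables.

The generator plants a known differential-expression structure: each
feature belongs to exactly one region of the three-set Venn over the
tissues in which it is differentially expressed between G0 and G1, with a
signed log2 effect per tissue (positive = higher in G0).  Membership is
assigned deterministically from the design, so Venn region sizes are exact
by construction; only the replicate noise is random.

Intensities follow a log-normal model: Normal noise on the log2 scale
added to a per-feature baseline and the phase-specific half-effect, then
exponentiated — the standard intensity model for microarray and label-free
LC/MS data, and one that keeps every value strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from engraftlogic.matrix import ExpressionMatrix, TISSUES, PHASES

UP_G0 = 1
UP_G1 = -1


@dataclass(frozen=True)
class RegionSpec:
    """One disjoint Venn region with a fixed direction pattern.

    ``directions`` maps tissue -> +1 (up in G0) or -1 (up in G1) and its
    keys define the tissues in which the features of this region are DE.
    ``priority`` is only meaningful for protein tables (identification
    quality rank 1-4); expression generation ignores it.
    """

    directions: tuple[tuple[str, int], ...]
    count: int
    priority: int | None = None

    def __post_init__(self):
        dirs = dict(self.directions)
        if not dirs:
            raise ValueError("region must name at least one tissue")
        bad = set(dirs) - set(TISSUES)
        if bad:
            raise ValueError(f"unknown tissue(s) in region: {sorted(bad)}")
        if any(d not in (UP_G0, UP_G1) for d in dirs.values()):
            raise ValueError("directions must be +1 (up_G0) or -1 (up_G1)")
        if self.count < 0:
            raise ValueError(f"negative region count: {self.count}")
        if self.priority is not None and self.priority not in (1, 2, 3, 4):
            raise ValueError(f"priority must be in 1..4, got {self.priority}")

    @property
    def tissues(self) -> frozenset[str]:
        return frozenset(dict(self.directions))

    def label(self) -> str:
        dirs = dict(self.directions)
        t = self.tissues
        if t == {"BM", "MPB", "UCB"}:
            return "cell_cycle"
        if t == {"BM", "MPB"}:
            if dirs["BM"] == UP_G0 and dirs["MPB"] == UP_G0:
                return "engraftment_G0"
            if dirs["BM"] == UP_G1 and dirs["MPB"] == UP_G1:
                return "engraftment_G1"
            if dirs["BM"] == UP_G0:
                return "discordant:BM_G0_MPB_G1"
            return "discordant:BM_G1_MPB_G0"
        if len(t) == 1:
            (tissue,) = t
            word = "up_G0" if dirs[tissue] == UP_G0 else "up_G1"
            return f"tissue_specific:{tissue},{word}"
        return "other:" + "+".join(sorted(t))


@dataclass(frozen=True)
class PlantedDesign:
    """Full specification of a planted data set.

    ``effect_size`` is the planted |log2 fold change| of DE features
    (dimensionless, log2 scale); ``noise_sd`` the replicate noise SD on
    the log2 scale; baselines are drawn once per feature from
    Normal(baseline_log2_mean, baseline_log2_sd).
    """

    n_features: int
    regions: tuple[RegionSpec, ...] = ()
    effect_size: float = 2.0
    noise_sd: float = 0.1
    replicates_per_group: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    feature_prefix: str = "G"
    null_priority_weights: tuple[float, float, float, float] = (0.2, 0.3, 0.3, 0.2)

    def __post_init__(self):
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")
        total = sum(r.count for r in self.regions)
        if total > self.n_features:
            offender = max(self.regions, key=lambda r: r.count)
            raise ValueError(
                f"planted region counts sum to {total} > n_features="
                f"{self.n_features} (largest region: "
                f"{dict(offender.directions)} with {offender.count})"
            )

    @property
    def n_planted(self) -> int:
        return sum(r.count for r in self.regions)


def _feature_ids(design: PlantedDesign) -> list[str]:
    width = len(str(design.n_features))
    return [f"{design.feature_prefix}{i:0{width}d}" for i in range(design.n_features)]


def build_ground_truth(design: PlantedDesign) -> pd.DataFrame:
    """Assign every feature its class label and signed per-tissue log2 effect.

    Deterministic: features are assigned to regions in design order, nulls
    last.  Returns a DataFrame indexed by feature id with columns
    ``label``, ``effect_BM``, ``effect_MPB``, ``effect_UCB`` (and
    ``priority`` when any region declares one).
    """
    ids = _feature_ids(design)
    labels = []
    effects = {t: [] for t in TISSUES}
    priorities = []
    for region in design.regions:
        dirs = dict(region.directions)
        for _ in range(region.count):
            labels.append(region.label())
            for t in TISSUES:
                effects[t].append(dirs.get(t, 0) * design.effect_size)
            priorities.append(region.priority)
    n_null = design.n_features - len(labels)
    labels.extend(["null"] * n_null)
    for t in TISSUES:
        effects[t].extend([0.0] * n_null)
    priorities.extend([None] * n_null)
    gt = pd.DataFrame(
        {
            "label": labels,
            "effect_BM": effects["BM"],
            "effect_MPB": effects["MPB"],
            "effect_UCB": effects["UCB"],
        },
        index=pd.Index(ids, name="feature_id"),
    )
    if any(p is not None for p in priorities):
        gt["priority"] = priorities
    return gt


def _sample_sheet(design: PlantedDesign, prefix: str = "S") -> pd.DataFrame:
    rows = []
    for tissue in TISSUES:
        for phase in PHASES:
            for rep in range(1, design.replicates_per_group + 1):
                rows.append(
                    {
                        "sample_id": f"{prefix}_{tissue}_{phase}_{rep}",
                        "tissue": tissue,
                        "phase": phase,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _simulate_intensities(
    design: PlantedDesign, gt: pd.DataFrame, samples: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    baseline = rng.normal(
        design.baseline_log2_mean, design.baseline_log2_sd, size=design.n_features
    )
    effect = gt[[f"effect_{t}" for t in TISSUES]].to_numpy()  # features x 3
    tissue_idx = np.array([TISSUES.index(t) for t in samples["tissue"]])
    phase_sign = np.array([1.0 if p == "G0" else -1.0 for p in samples["phase"]])
    # log2 intensity = baseline + sign * effect/2 + noise
    log2 = (
        baseline[:, None]
        + effect[:, tissue_idx] * (phase_sign[None, :] / 2.0)
        + rng.normal(0.0, design.noise_sd, size=(design.n_features, len(samples)))
    )
    return pd.DataFrame(
        np.exp2(log2), index=gt.index, columns=samples.index.copy()
    )


def generate_expression(
    design: PlantedDesign, seed: int
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a probe x sample intensity matrix with planted DE structure.

    Emulates the 18-sample study design (3 tissues x 2 phases x replicates).
    Returns the matrix (with sample sheet) and the ground-truth table.
    """
    gt = build_ground_truth(design)
    if "priority" in gt.columns:
        gt = gt.drop(columns="priority")
    samples = _sample_sheet(design)
    rng = np.random.default_rng(seed)
    values = _simulate_intensities(design, gt, samples, rng)
    return ExpressionMatrix(values=values, samples=samples).validate(), gt


def generate_ki67(
    reduction_fraction: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-tissue relative Ki67 expression for sorted G0 and G1 fractions.

    Ki67 marks proliferating cells, so a clean G0 sort shows strongly
    reduced Ki67: the G0 value is ``(1 - reduction_fraction)`` times the
    G1 value.  Optional multiplicative log-normal noise perturbs both
    phases.  Returns a DataFrame indexed by tissue with columns G0, G1.
    """
    if not 0.0 <= reduction_fraction <= 1.0:
        raise ValueError("reduction_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = {}
    for tissue in TISSUES:
        g1 = 1.0
        g0 = (1.0 - reduction_fraction) * g1
        if noise_sd > 0:
            g0 *= float(np.exp2(rng.normal(0, noise_sd)))
            g1 *= float(np.exp2(rng.normal(0, noise_sd)))
        rows[tissue] = {"G0": g0, "G1": g1}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("tissue")


def generate_protein_table(
    design: PlantedDesign, seed: int
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a protein x sample intensity table with priority ranks.

    Same intensity model as :func:`generate_expression`; every protein
    additionally carries an identification-quality priority (1-4).  DE
    regions take their declared priority; null proteins are assigned
    priorities deterministically in proportion to
    ``design.null_priority_weights``.
    """
    gt = build_ground_truth(design)
    if "priority" not in gt.columns:
        gt["priority"] = None
    missing_de = gt.index[(gt["label"] != "null") & gt["priority"].isna()]
    if len(missing_de):
        raise ValueError(
            f"protein region lacks a priority rank (first feature: {missing_de[0]!r})"
        )
    # deterministic proportional fill for nulls
    null_idx = gt.index[gt["label"] == "null"]
    w = np.asarray(design.null_priority_weights, dtype=float)
    w = w / w.sum()
    counts = np.floor(w * len(null_idx)).astype(int)
    counts[0] += len(null_idx) - counts.sum()
    fill = np.repeat([1, 2, 3, 4], counts)
    gt.loc[null_idx, "priority"] = fill
    gt["priority"] = gt["priority"].astype(int)

    samples = _sample_sheet(design, prefix="P")
    rng = np.random.default_rng(seed)
    values = _simulate_intensities(design, gt, samples, rng)
    meta = gt[["priority"]].copy()
    mat = ExpressionMatrix(values=values, samples=samples, feature_meta=meta)
    return mat.validate(), gt


def plant_id_map(
    protein_gt: pd.DataFrame,
    gene_gt: pd.DataFrame,
    n_matched: int,
    tissue: str = "BM",
    n_null_mapped: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Construct a partial protein -> gene id map with a known match count.

    Exactly ``n_matched`` of the proteins DE in ``tissue`` are mapped to
    distinct genes DE in the same tissue; ``n_null_mapped`` null proteins
    are mapped to null genes; all remaining proteins stay unmapped
    (mimicking hypothetical/putative identifications without an array id).
    Returns a DataFrame with columns protein_id, gene_id.
    """
    de_prot = protein_gt.index[protein_gt[f"effect_{tissue}"] != 0]
    de_gene = gene_gt.index[gene_gt[f"effect_{tissue}"] != 0]
    if n_matched > min(len(de_prot), len(de_gene)):
        raise ValueError(
            f"cannot plant {n_matched} matches: only {len(de_prot)} DE proteins "
            f"and {len(de_gene)} DE genes in {tissue}"
        )
    rng = np.random.default_rng(seed)
    matched_prot = list(de_prot[:n_matched])
    matched_gene = list(rng.choice(de_gene, size=n_matched, replace=False))
    null_prot = protein_gt.index[protein_gt["label"] == "null"]
    null_gene = gene_gt.index[gene_gt["label"] == "null"]
    k = min(n_null_mapped, len(null_prot), len(null_gene))
    pairs = list(zip(matched_prot, matched_gene)) + list(
        zip(null_prot[:k], rng.choice(null_gene, size=k, replace=False))
    )
    return pd.DataFrame(pairs, columns=["protein_id", "gene_id"])
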