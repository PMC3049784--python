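"""End-to-end orchestration of the simulate -> DE -> subtract -> classify
-> proteomics -> concordance pipeline, with a single seed governing all
randomness and a JSON run report aggregating every summary count."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import engraftlogic
from engraftlogic import io as elio
from engraftlogic.simulate import generate_expression, generate_protein_table, generate_ki67, plant_id_map
from engraftlogic.designs import expression_replica_design, protein_replica_design
from engraftlogic.de import normalize_median, test_de, de_set
from engraftlogic.targets import venn, identify_targets, ki67_gate
from engraftlogic.patterns import (
    classify_patterns,
    concordant_subset,
    profile_matrix,
    hcluster,
    linkage_to_newick,
)
from engraftlogic.proteomics import test_de_proteins, identify_target_proteins, concordance
from engraftlogic.matrix import TISSUES

log = logging.getLogger("engraftlogic")


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    seed: int = 0
    out_dir: str = "results/run"
    # expression design
    effect_size: float = 2.0
    noise_sd: float = 0.1
    replicates_per_group: int = 3
    n_features: int = 43356
    # thresholds
    fc_threshold: float = 2.0
    p_threshold: float = 0.01
    protein_fold_threshold: float = 1.5
    fdr_threshold: float = 0.05
    priorities: tuple[int, ...] = (1, 2)
    # QC
    ki67_reduction: float = 0.93
    ki67_min_reduction: float = 0.90
    qc_abort_on_fail: bool = True
    # proteomics design
    protein_effect_size: float = 1.0
    protein_noise_sd: float = 0.1
    protein_replicates: int = 4
    n_proteins: int = 646
    concordance_matches: int = 10
    concordance_tissue: str = "BM"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "priorities" in raw:
            raw["priorities"] = tuple(raw["priorities"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> "RunConfig":
        if not (self.fc_threshold >= 1 and self.protein_fold_threshold >= 1):
            raise ValueError("fold thresholds must be >= 1")
        if not (0 < self.p_threshold <= 1 and 0 < self.fdr_threshold <= 1):
            raise ValueError("p/FDR thresholds must be in (0, 1]")
        if not set(self.priorities) <= {1, 2, 3, 4}:
            raise ValueError("priorities must be within 1..4")
        if not 0 <= self.ki67_min_reduction <= 1:
            raise ValueError("ki67_min_reduction must be in [0, 1]")
        return self


class QCError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis on a planted data set; return the report.

    Stages, in order: simulate expression + Ki67 + proteins; Ki67 sort-
    purity QC; median normalization; per-tissue G0-vs-G1 DE; three-set
    Venn; target subtraction; direction-pattern classification;
    concordant subset; hierarchical clustering of targets; per-tissue
    protein DE (priority filter); protein target subtraction;
    transcript-protein concordance.  All stage outputs and the aggregated
    RunReport are written under ``config.out_dir``; the run is fully
    deterministic given ``config.seed``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("simulate: seed=%d, %d features, %d proteins",
             config.seed, config.n_features, config.n_proteins)
    design = expression_replica_design(
        effect_size=config.effect_size,
        noise_sd=config.noise_sd,
        replicates_per_group=config.replicates_per_group,
        n_features=config.n_features,
    )
    matrix, gene_gt = generate_expression(design, seed=config.seed)
    prot_design = protein_replica_design(
        effect_size=config.protein_effect_size,
        noise_sd=config.protein_noise_sd,
        replicates_per_group=config.protein_replicates,
        n_features=config.n_proteins,
    )
    prot_table, prot_gt = generate_protein_table(prot_design, seed=config.seed + 1)
    ki67 = generate_ki67(config.ki67_reduction)

    elio.write_matrix(matrix, out / "expression.tsv", out / "samples.tsv")
    elio.write_ground_truth(gene_gt, out / "ground_truth_genes.tsv")
    elio.write_ground_truth(prot_gt, out / "ground_truth_proteins.tsv")

    # QC gate: sort purity via Ki67 reduction in every tissue
    qc = {}
    for tissue in TISSUES:
        passed, reduction = ki67_gate(
            ki67.loc[tissue, "G0"], ki67.loc[tissue, "G1"], config.ki67_min_reduction
        )
        qc[tissue] = {"passed": bool(passed), "reduction": round(float(reduction), 6)}
    if config.qc_abort_on_fail and not all(v["passed"] for v in qc.values()):
        failed = [t for t, v in qc.items() if not v["passed"]]
        raise QCError(f"Ki67 sort-purity QC failed for tissue(s): {failed}")

    log.info("normalize + per-tissue DE at fc>=%g, p<%g", config.fc_threshold, config.p_threshold)
    norm = normalize_median(matrix)
    calls = {}
    de_counts = {}
    for tissue in TISSUES:
        c = test_de(norm, tissue, config.fc_threshold, config.p_threshold)
        calls[tissue] = c
        de = c[c["is_de"]]
        de_counts[tissue] = {
            "total": int(len(de)),
            "up_G0": int((de["direction"] == "up_G0").sum()),
            "up_G1": int((de["direction"] == "up_G1").sum()),
        }
        elio.write_calls(c, out / f"de_{tissue}.tsv")

    summary = venn(*(de_set(calls[t]) for t in TISSUES))
    targets = identify_targets(calls["BM"], calls["MPB"], calls["UCB"])
    classes, class_counts = classify_patterns(targets)
    concordant = concordant_subset(classes)
    aberrant = len(targets) - len(concordant)

    assert len(targets) == summary.bm_mpb - summary.triple
    assert sum(class_counts.values()) == len(targets)
    assert len(concordant) == class_counts["UP_G0_BOTH"] + class_counts["UP_G1_BOTH"]

    targets_out = targets.copy()
    targets_out["pattern_class"] = classes
    elio.write_calls(targets_out, out / "targets.tsv")
    elio.write_json(summary.to_dict(), out / "venn.json")

    newick = None
    if len(targets) >= 2:
        linkage, leaves = hcluster(profile_matrix(norm, targets.index))
        newick = linkage_to_newick(linkage, leaves)
        (out / "targets_tree.nwk").write_text(newick + "\n")

    log.info("protein DE at fold>=%g, FDR<%g, priorities=%s",
             config.protein_fold_threshold, config.fdr_threshold, config.priorities)
    pcalls = {}
    protein_de_counts = {}
    for tissue in TISSUES:
        pc = test_de_proteins(
            prot_table,
            tissue,
            config.protein_fold_threshold,
            config.fdr_threshold,
            set(config.priorities),
        )
        pcalls[tissue] = pc
        protein_de_counts[tissue] = int(pc["is_de"].sum())
        elio.write_calls(pc, out / f"protein_de_{tissue}.tsv")
    psummary = venn(*(de_set(pcalls[t]) for t in TISSUES))
    ptargets = identify_target_proteins(pcalls["BM"], pcalls["MPB"], pcalls["UCB"])
    elio.write_calls(ptargets, out / "target_proteins.tsv")

    # concordance uses the all-priority BM protein DE set, by ID matching
    t = config.concordance_tissue
    bm_all = test_de_proteins(
        prot_table, t, config.protein_fold_threshold, config.fdr_threshold, {1, 2, 3, 4}
    )
    id_map = plant_id_map(
        prot_gt, gene_gt, config.concordance_matches, tissue=t,
        seed=config.seed + 2,
    )
    id_map.to_csv(out / "id_map.tsv", sep="\t", index=False)
    conc = concordance(de_set(calls[t]), de_set(bm_all), id_map)
    conc_report = {k: v for k, v in conc.items() if k != "matched_proteins"}

    report = {
        "version": engraftlogic.__version__,
        "config": dataclasses.asdict(config) | {"priorities": list(config.priorities)},
        "qc_ki67": qc,
        "de_counts": de_counts,
        "venn": summary.to_dict(),
        "n_targets": int(len(targets)),
        "pattern_counts": class_counts,
        "n_concordant": len(concordant),
        "n_aberrant": int(aberrant),
        "protein_de_counts": protein_de_counts,
        "protein_venn": psummary.to_dict(),
        "n_target_proteins": int(len(ptargets)),
        "protein_de_all_priorities": {t: int(bm_all["is_de"].sum())},
        "concordance": conc_report,
    }
    elio.write_json(report, out / "report.json")
    log.info("report written to %s", out / "report.json")
    return report
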