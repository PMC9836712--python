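"""End-to-end barcode delimitation pipeline and its JSON summary.

Chains: input reading -> alignment statistics -> K2P distances -> barcode
gaps -> NJ tree (optional bootstrap) -> ABGD + PTP + K/theta -> consensus
and morphology concordance. Every stage writes its own TSV into the output
directory; ``summary.json`` holds only numbers recomputable from those
stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__, abgd as abgd_mod, consensus as cons_mod
from . import gap as gap_mod, ktheta as ktheta_mod
from . import ptp as ptp_mod, seqio, stats as stats_mod
from .distances import k2p_matrix, group_distance_summary
from .model import Partition
from .nj import BootstrapConfig, bootstrap_support, midpoint_root, nj as build_nj

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    fasta: str
    metadata: str
    outdir: str
    tree: str | None = None
    external_partitions: tuple[str, ...] = ()
    seed: int = 0
    min_sites: int = 100  # n_compared floor for real barcodes
    saturation_policy: str = "drop_pair"
    run_nj: bool = True
    bootstrap_replicates: int = 0  # 0 disables the bootstrap stage
    run_abgd: bool = True
    run_ptp: bool = True
    run_ktheta: bool = True
    abgd: abgd_mod.AbgdConfig = field(default_factory=abgd_mod.AbgdConfig)
    ptp_restarts: int = 10
    ktheta_threshold: float = 4.0
    ktheta_theta_rule: str = "max"
    consensus_rule: str = "strict"

    def validate(self) -> None:
        for p in (self.fasta, self.metadata, self.tree, *self.external_partitions):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if (self.run_ptp or self.run_ktheta) and self.tree is None and not self.run_nj:
            raise ValueError(
                "PTP / K-theta need a rooted tree: provide --tree or enable NJ"
            )


def _clean(x):
    if isinstance(x, float) and not math.isfinite(x):
        return None
    if isinstance(x, dict):
        return {k: _clean(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_clean(v) for v in x]
    return x


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns (and writes) the JSON summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    alignment = seqio.read_metadata(config.metadata, seqio.read_fasta(config.fasta))
    labels = alignment.require_labels()

    site = stats_mod.classify_sites(alignment)
    comp = stats_mod.sequence_summary(alignment)
    stats_mod.write_reports(alignment, outdir)

    matrix = k2p_matrix(alignment, min_sites=config.min_sites)
    matrix.write_tsv(outdir / "k2p_matrix.tsv", outdir / "pairs.tsv")
    usable = matrix.apply_saturation_policy(config.saturation_policy)  # type: ignore[arg-type]
    summary_grp = group_distance_summary(matrix, labels)
    summary_grp.within.to_csv(outdir / "within_species.tsv", sep="\t", index=False)
    summary_grp.between.to_csv(outdir / "between_species.tsv", sep="\t", index=False)

    gaps = gap_mod.gap_report(matrix, labels)
    gap_mod.records_to_frame(gaps).to_csv(outdir / "gap_report.tsv", sep="\t", index=False)
    gap_mod.gap_points(matrix, labels).to_csv(outdir / "gap_points.tsv", sep="\t", index=False)
    tenx = gap_mod.ten_x_test(matrix, labels)

    tree = None
    if config.tree is not None:
        tree = seqio.read_tree(config.tree)
        seqio.require_branch_lengths(tree, "tree-based delimitation")
    elif config.run_nj or config.run_ptp or config.run_ktheta:
        if config.bootstrap_replicates > 0:
            nj_aln = alignment.subset(usable.ids) if len(usable) < len(matrix) else alignment
            tree = bootstrap_support(
                nj_aln,
                BootstrapConfig(replicates=config.bootstrap_replicates,
                                seed=config.seed),
            )
        else:
            tree = build_nj(usable)
        seqio.write_tree(tree, outdir / "nj_tree.nwk")
    rooted = midpoint_root(tree) if tree is not None and not tree.is_rooted else tree
    tree_ids = (
        sorted(lf.taxon.label for lf in rooted.leaf_node_iter())
        if rooted is not None else None
    )

    partitions: list[Partition] = []
    per_method: dict[str, int] = {}
    if config.run_abgd:
        res = abgd_mod.abgd_partition(usable, config.abgd)
        seqio.write_partition(res.partition, outdir / "abgd_partition.tsv")
        partitions.append(res.partition)
        per_method["abgd"] = res.n_groups
    if config.run_ptp:
        model, part = ptp_mod.ptp_ml(
            rooted, ptp_mod.PtpSearchConfig(restarts=config.ptp_restarts,
                                            seed=config.seed),
        )
        seqio.write_partition(part, outdir / "ptp_partition.tsv")
        (outdir / "ptp_model.json").write_text(json.dumps({
            "lambda_speciation": model.lambda_speciation,
            "lambda_within": model.lambda_within,
            "log_likelihood": model.log_likelihood,
            "n_species": model.n_species,
            "species_subtrees": [sorted(s) for s in model.species_subtrees],
        }, indent=1))
        partitions.append(part)
        per_method["ptp"] = model.n_species
    if config.run_ktheta:
        kt_matrix = usable.submatrix(tree_ids) if tree_ids != usable.ids else usable
        results: list[ktheta_mod.KThetaResult] = []
        part = ktheta_mod.ktheta_delimit(
            rooted, kt_matrix, theta_rule=config.ktheta_theta_rule,  # type: ignore[arg-type]
            threshold=config.ktheta_threshold, results=results,
        )
        seqio.write_partition(part, outdir / "ktheta_partition.tsv")
        ktheta_mod.ktheta_report(results).to_csv(
            outdir / "ktheta_report.tsv", sep="\t", index=False)
        partitions.append(part)
        per_method["ktheta"] = part.n_otus
    for path in config.external_partitions:
        ext = seqio.read_partition(path)
        partitions.append(ext)
        per_method[ext.method_name] = ext.n_otus

    consensus = concordance = agreement = None
    if partitions:
        common = set.intersection(*(p.samples for p in partitions))
        trimmed = [
            Partition({s: o for s, o in p.assignment.items() if s in common},
                      method_name=p.method_name)
            for p in partitions
        ]
        consensus = cons_mod.consensus_partition(trimmed, rule=config.consensus_rule)  # type: ignore[arg-type]
        seqio.write_partition(consensus, outdir / "consensus_partition.tsv")
        agreement = cons_mod.agreement_table(trimmed)
        agreement.to_csv(outdir / "agreement.tsv", sep="\t", index=False)
        records = cons_mod.compare_to_morphology(consensus, labels)
        concordance = cons_mod.concordance_frame(records)
        concordance.to_csv(outdir / "concordance.tsv", sep="\t", index=False)

    cfg_dict = asdict(config)
    for path_field in ("fasta", "metadata", "tree", "external_partitions", "outdir"):
        cfg_dict.pop(path_field, None)  # hash analysis parameters, not paths
    summary = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "n_samples": len(alignment),
        "n_columns": alignment.length,
        "n_species_labels": len(set(labels.values())),
        "site_classification": {
            "n_sites": site.n_sites, "conserved": site.conserved,
            "variable": site.variable,
            "parsimony_informative": site.parsimony_informative,
            "singleton": site.singleton,
        },
        "composition": {
            "at_content": comp.at_content, "gc_content": comp.gc_content,
            "mean_length": comp.mean_length, "min_length": comp.min_length,
            "max_length": comp.max_length, "ts_tv_ratio": comp.ts_tv_ratio,
        },
        "distances": {
            "within_mean": summary_grp.overall_within_mean,
            "between_mean": summary_grp.overall_between_mean,
            "between_within_ratio": summary_grp.ratio,
            "n_undefined_pairs": matrix.n_undefined_pairs,
        },
        "ten_x": {
            "mean_intra": tenx.mean_intra, "mean_inter": tenx.mean_inter,
            "ratio": tenx.ratio, "passes_10x": tenx.passes_10x,
        },
        "intra_fraction_below_2pct": gap_mod.intra_fraction_below(matrix, labels),
        "species_with_gap": sum(1 for g in gaps if g.gap_present),
        "per_method_n_otus": per_method,
        "consensus_n_otus": consensus.n_otus if consensus is not None else None,
        "concordance_status_counts": (
            concordance["status"].value_counts().to_dict()
            if concordance is not None else None
        ),
    }
    summary = _clean(summary)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
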