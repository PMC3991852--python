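"""One-shot orchestration of the full cell-size scaling analysis.

Stage order: simulate-or-load -> radius normalization -> per-feature
correlation (genes, metabolites) -> correlation density and abundance
strata -> gene-set scaling profiles with KS tests -> lipid-class summary ->
network connectivity null (negative and positive sets) -> genotype/size
overlap -> surface-area-to-volume expectation curve.

Every stage writes its result table into the run directory; a flat JSON
summary records the headline quantities plus full parameter provenance.
A stage failure leaves partial outputs in place together with a
``FAILED.txt`` marker naming the stage.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import pandas as pd

from . import io, netconn, setscaling, simulate, sizecorr
from .config import dump_config, validate_config
from .datatypes import SampleTable, ValidationError
from .genotype import genotype_effect_genes, overlap_stats

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _json_safe(obj: Any) -> Any:
    """Recursively convert to JSON-serializable values; non-finite floats
    become strings so the summary stays machine-readable."""
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else repr(f)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _setup_run_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("cellscale").addHandler(handler)
    return handler


def run_pipeline(
    config: Optional[Dict[str, Any]] = None,
    out_dir: str = "cellscale_run",
    seed: Optional[int] = None,
) -> Dict[str, Any]:
    """Run the full analysis; returns the summary mapping.

    ``config`` is validated (defaults filled); ``seed`` overrides the
    config seed.  In ``simulate`` mode every input artifact is generated
    and written alongside the results so the run can be replayed from the
    echoed configuration.
    """
    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out)
    stage = "setup"
    try:
        summary: Dict[str, Any] = {"parameters": cfg}
        dump_config(cfg, out / "config_echo.yaml")
        rng_seed = cfg["seed"]
        sim = cfg["simulate"]

        stage = "inputs"
        if cfg["mode"] == "simulate":
            samples = simulate.generate_design(
                n_replicates=sim["n_replicates"],
                group_radii=sim["group_radii"],
                radius_cv=sim["radius_cv"],
                seed=rng_seed,
            )
            gene_matrix, gene_truth = simulate.generate_matrix(
                samples,
                n_positive=sim["n_genes_positive"],
                n_negative=sim["n_genes_negative"],
                n_null=sim["n_genes_null"],
                slope_positive=sim["slope_positive"],
                slope_negative=sim["slope_negative"],
                noise_sd=sim["noise_sd"],
                n_genotype_shifted=sim["n_genotype_shifted"],
                genotype_log2fc=sim["genotype_log2fc"],
                kind="gene",
                seed=rng_seed,
            )
            met_matrix, met_truth = simulate.generate_matrix(
                samples,
                n_positive=sim["n_metabolites_positive"],
                n_negative=sim["n_metabolites_negative"],
                n_null=sim["n_metabolites_null"],
                slope_positive=sim["slope_positive"],
                slope_negative=sim["slope_negative"],
                noise_sd=sim["noise_sd"],
                n_genotype_shifted=0,
                kind="metabolite",
                seed=rng_seed,
            )
            gene_sets = simulate.generate_annotations(
                gene_truth,
                overlap_fraction=sim["set_overlap_fraction"],
                seed=rng_seed,
            )
            lipid_map = simulate.generate_lipid_classes(met_truth, seed=rng_seed)
            network = simulate.generate_network(
                gene_truth,
                p_within_module=sim["network_p_within"],
                p_background=sim["network_p_background"],
                seed=rng_seed,
            )
            io.write_sample_table(samples, out / "sample_table.tsv")
            io.write_feature_matrix(gene_matrix, out / "gene_matrix.tsv")
            io.write_feature_matrix(met_matrix, out / "metabolite_matrix.tsv")
            io.write_gene_sets(gene_sets, out / "gene_sets.gmt")
            io.write_lipid_classes(lipid_map, out / "lipid_classes.tsv")
            io.write_network(network, out / "network.tsv")
            gene_truth.features.to_csv(
                out / "truth_genes.tsv", sep="\t", index=False, float_format="%.6g"
            )
            met_truth.features.to_csv(
                out / "truth_metabolites.tsv", sep="\t", index=False, float_format="%.6g"
            )
        else:
            paths = cfg["inputs"]
            samples = io.read_sample_table(paths["sample_table"])
            gene_matrix = io.read_feature_matrix(paths["gene_matrix"], "gene", samples)
            met_matrix = (
                io.read_feature_matrix(paths["metabolite_matrix"], "metabolite", samples)
                if paths["metabolite_matrix"]
                else None
            )
            gene_sets = io.read_gene_sets(paths["gene_sets"]) if paths["gene_sets"] else None
            lipid_map = (
                io.read_lipid_classes(paths["lipid_classes"])
                if paths["lipid_classes"]
                else None
            )
            network = io.read_network(paths["network"]) if paths["network"] else None

        stage = "normalize"
        samples = sizecorr.normalize_radius(samples, reference=("control", "pre"))
        io.write_sample_table(samples, out / "sample_table_normalized.tsv")

        stage = "correlate"
        corr_cfg = cfg["correlation"]
        gene_table = sizecorr.build_correlation_table(
            gene_matrix,
            samples,
            ci_level=corr_cfg["ci_level"],
            log2_transform=corr_cfg["log2_transform"],
            pseudocount=corr_cfg["pseudocount_gene"],
        )
        io.write_table(gene_table, out / "correlation_genes.tsv")
        met_table = None
        if met_matrix is not None:
            met_table = sizecorr.build_correlation_table(
                met_matrix,
                samples,
                ci_level=corr_cfg["ci_level"],
                log2_transform=corr_cfg["log2_transform"],
                pseudocount=corr_cfg["pseudocount_metabolite"],
            )
            io.write_table(met_table, out / "correlation_metabolites.tsv")

        stage = "density"
        edges, counts, median_r = sizecorr.correlation_density(
            gene_table["r"], bin_width=corr_cfg["bin_width"]
        )
        io.write_table(
            pd.DataFrame(
                {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
            ),
            out / "correlation_density_genes.tsv",
        )
        summary["gene_median_r"] = median_r
        if met_table is not None:
            _, _, met_median = sizecorr.correlation_density(met_table["r"])
            summary["metabolite_median_r"] = met_median

        stage = "strata"
        strata = sizecorr.abundance_stratified_summary(
            gene_table, n_strata=corr_cfg["n_strata"]
        )
        io.write_table(strata, out / "abundance_strata_genes.tsv")

        stage = "set_profiles"
        summary["sets"] = {}
        if gene_sets is not None and len(gene_sets):
            set_cfg = cfg["sets"]
            profiles = setscaling.set_scaling_profile(
                gene_table,
                gene_sets,
                background=set_cfg["background"],
                bin_width=set_cfg["bin_width"],
                statistic_mode=set_cfg["statistic_mode"],
                min_set_size=set_cfg["min_set_size"],
                exclude_set_from_background=set_cfg["exclude_set_from_background"],
            )
            io.write_table(
                setscaling.profiles_long_frame(profiles), out / "set_profiles.tsv"
            )
            io.write_table(
                setscaling.profiles_summary_frame(profiles), out / "set_summary.tsv"
            )
            for pr in profiles:
                summary["sets"][pr.set_name] = {
                    "n": pr.n_members_measured,
                    "median": pr.median_stat,
                    "ks_D": pr.ks_D,
                    "ks_p": pr.ks_p,
                    "ks_p_adj": pr.ks_p_adj,
                }

        stage = "lipid_classes"
        if met_table is not None and lipid_map:
            lipids = setscaling.lipid_class_summary(
                met_table, lipid_map, min_class_size=cfg["lipids"]["min_class_size"]
            )
            io.write_table(lipids, out / "lipid_class_summary.tsv")
            summary["lipid_classes"] = {
                row["lipid_class"]: {
                    "n": int(row["n"]),
                    "median_r": row["median_r"],
                    "mean_log2_fc": row["mean_log2_fc"],
                }
                for _, row in lipids.iterrows()
            }
            if len(lipids):
                summary["top_lipid_class"] = str(lipids.iloc[0]["lipid_class"])

        stage = "network"
        summary["connectivity"] = {}
        if network is not None:
            net_cfg = cfg["network"]
            measured = set(gene_table["feature_id"].astype(str))
            if net_cfg["universe"] == "measured_features":
                universe = sorted(set(network.nodes) & measured)
            else:
                universe = sorted(network.nodes)
            for direction in ("negative", "positive"):
                genes = netconn.select_significant(
                    gene_table, direction, alpha=net_cfg["alpha"]
                )
                if not genes:
                    summary["connectivity"][direction] = None
                    continue
                result = netconn.connectivity_enrichment(
                    network,
                    genes,
                    n_iterations=net_cfg["n_iterations"],
                    universe=universe,
                    seed=cfg["seed"],
                    gene_set=f"{direction}_correlating",
                )
                io.write_table(result, out / f"connectivity_{direction}.tsv")
                summary["connectivity"][direction] = {
                    "set_size": result.set_size,
                    "observed_edges_per_gene": result.observed_edges_per_gene,
                    "null_mean_edges_per_gene": result.null_mean_edges_per_gene,
                    "enrichment_ratio": result.enrichment_ratio,
                    "empirical_p": result.empirical_p,
                }

        stage = "overlap"
        summary["overlap"] = {}
        ov_cfg = cfg["overlap"]
        genotype_set, genotype_table = genotype_effect_genes(
            gene_matrix,
            samples,
            timepoint=ov_cfg["timepoint"],
            fc_threshold=ov_cfg["fc_threshold"],
            alpha=ov_cfg["alpha"],
            pseudocount=corr_cfg["pseudocount_gene"],
        )
        io.write_table(genotype_table, out / "genotype_effect_genes.tsv")
        overlap_rows = []
        for direction in ("positive", "negative"):
            size_set = netconn.select_significant(
                gene_table, direction, alpha=cfg["network"]["alpha"]
            )
            if not size_set:
                summary["overlap"][direction] = None
                continue
            res = overlap_stats(
                genotype_set,
                size_set,
                name_a="genotype_effect",
                name_b=f"{direction}_correlating",
            )
            overlap_rows.append(res.as_row())
            summary["overlap"][direction] = {
                "n_genotype": res.size_a,
                "n_size": res.size_b,
                "n_shared": res.n_shared,
                "pct_of_size_set": res.pct_of_b,
                "pct_rounded": res.pct_of_b_rounded,
            }
        if overlap_rows:
            io.write_table(pd.concat(overlap_rows, ignore_index=True), out / "overlap.tsv")

        stage = "geometry"
        sv = setscaling.surface_volume_expectation(samples.radii)
        io.write_table(
            pd.DataFrame(
                {
                    "sample_id": samples.sample_ids,
                    "relative_radius": samples.radii,
                    "expected_surface_per_volume": sv,
                }
            ),
            out / "surface_volume_expectation.tsv",
        )

        stage = "summary"
        safe = _json_safe(summary)
        (out / "summary.json").write_text(
            json.dumps(safe, sort_keys=True, indent=2) + "\n", encoding="utf-8"
        )
        return safe
    except Exception as err:  # noqa: BLE001 - stage name is part of the contract
        (out / "FAILED.txt").write_text(f"stage: {stage}\ncause: {err}\n", encoding="utf-8")
        raise PipelineError(stage, err) from err
    finally:
        logging.getLogger("cellscale").removeHandler(handler)
        handler.close()
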