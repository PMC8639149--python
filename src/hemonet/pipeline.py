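"""End-to-end pipeline runner.

Orchestrates preprocess -> embedding -> network -> range scan -> models
over either a monitoring/clinical CSV pair or a synthetic cohort, writing
every stage artifact plus a machine-readable summary of the decisions
made along the way (k_min, selected k and d, walk length t*, cluster
count, selected MAP ranges, model comparison).  Fully deterministic for a
given configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .embedding import pairwise_euclidean, select_embedding
from .models import (
    Covariate,
    ModelSpec,
    NaturalSpline,
    Poly,
    fit_logistic,
    likelihood_ratio_test,
    loocv_error,
)
from .network import cluster_network, contract_clusters, knn_adjacency
from .preprocess import (
    FilterRules,
    cdf_featurize,
    downsample_q1_to_q5,
    filter_artifacts,
    summarize_averages,
)
from .range_scan import (
    assortativity_scan,
    build_range_matrix,
    lasso_last_standing,
    refit_single_range,
)
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger("hemonet")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; defaults mirror the reference study."""

    monitoring_path: str | None = None
    clinical_path: str | None = None
    synthetic: SyntheticConfig | None = None
    filter_rules: FilterRules = field(default_factory=FilterRules)
    n_cdf_bins: int = 100
    d_max: int = 8
    n_k_candidates: int = 5
    t_range: tuple = (1, 100)
    range_center: float = 90.0
    range_steps: int = 25
    range_fixed_low: float = 76.0
    range_upper_sweep: tuple = (91.0, 130.0)
    seed: int = 0
    out_dir: str = "hemonet_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "filter_rules" in raw and raw["filter_rules"] is not None:
            raw["filter_rules"] = FilterRules(**raw["filter_rules"])
        for key in ("t_range", "range_upper_sweep"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        cohort, clinical, _ = generate_cohort(
            dataclasses.replace(config.synthetic, seed=config.seed)
        )
        return cohort, clinical
    if config.monitoring_path is None or config.clinical_path is None:
        raise ValueError("need either a synthetic config or monitoring+clinical paths")
    return hio.read_monitoring(config.monitoring_path), hio.read_clinical(
        config.clinical_path
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write artifacts under ``config.out_dir``.

    Returns the summary dict (also written as ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # ---------------- preprocess
    logger.info("stage: preprocess")
    cohort, clinical = _load_inputs(config)
    cohort = [filter_artifacts(s, config.filter_rules) for s in cohort]
    cohort = [downsample_q1_to_q5(s) if s.sampling == "Q1" else s for s in cohort]
    hio.write_monitoring(cohort, out / "monitoring_q5.csv")
    features = cdf_featurize(cohort, config.n_cdf_bins)
    hio.write_features(features, out / "features.csv")
    averages = summarize_averages(cohort)
    clinical = clinical.drop(columns=["amap_mmHg", "ahr_bpm"], errors="ignore").merge(
        averages, on="patient_id"
    )
    hio.write_clinical(clinical, out / "clinical.csv")

    # ---------------- embedding
    logger.info("stage: embedding")
    D = pairwise_euclidean(features)
    pd.DataFrame(D, index=features.patient_ids, columns=features.patient_ids).to_csv(
        out / "distances.csv"
    )
    solution = select_embedding(
        D, ids=features.patient_ids, d_max=config.d_max,
        n_k_candidates=config.n_k_candidates,
    )
    pd.DataFrame(
        solution.coords, index=solution.ids,
        columns=[f"dim{j + 1}" for j in range(solution.coords.shape[1])],
    ).to_csv(out / "coords.csv", index_label="patient_id")
    diag_rows = [
        {"dimension": dim, "birth": b, "death": d}
        for dim, dg in solution.diagrams_input.items()
        for b, d in dg.pairs
    ]
    pd.DataFrame(diag_rows).to_csv(out / "diagrams_geodesic.csv", index=False)
    (out / "embedding_selection.json").write_text(
        json.dumps(
            {
                "k_min": solution.k_min,
                "k": solution.k,
                "selected_d": solution.selected_d,
                "elbow_d": solution.elbow_d,
                "rv_by_d": {str(k): v for k, v in solution.rv_by_d.items()},
                "wd0_by_d": {str(k): v for k, v in solution.wd0_by_d.items()},
                "wd1_by_d": {str(k): v for k, v in solution.wd1_by_d.items()},
                "candidate_scores": {str(k): v for k, v in solution.candidate_scores.items()},
            },
            indent=2,
        )
    )

    # ---------------- network
    logger.info("stage: network")
    network = knn_adjacency(solution.selected_coords, ids=solution.ids)
    cluster_network(network, range(config.t_range[0], config.t_range[1] + 1))
    attributes = clinical.set_index("patient_id")
    contract_clusters(network, attributes)
    relabel = {u: network.ids[u] for u in network.graph.nodes}
    nx.write_graphml(nx.relabel_nodes(network.graph, relabel), out / "network.graphml")
    pd.DataFrame(
        {"patient_id": list(network.cluster_labels), "cluster": list(network.cluster_labels.values())}
    ).to_csv(out / "clusters.csv", index=False)

    # ---------------- range scan
    logger.info("stage: range scan")
    clinical_idx = clinical.set_index("patient_id").loc[[s.patient_id for s in cohort]]
    improved_known = clinical_idx["improved"].notna().to_numpy()
    scan_results = {}
    for mode in ("symmetric", "asymmetric"):
        scan = build_range_matrix(
            cohort, mode=mode, center=config.range_center, n_steps=config.range_steps,
            fixed_low=config.range_fixed_low, upper_sweep=config.range_upper_sweep,
        )
        assortativity_scan(network, scan)
        minutes_cc = scan.minutes_outside.loc[improved_known]
        y = clinical_idx.loc[improved_known, "improved"].to_numpy(float)
        label, path, lam = lasso_last_standing(minutes_cc, y)
        refit = refit_single_range(minutes_cc[label].to_numpy(), y)
        scan.minutes_outside.to_csv(out / f"minutes_outside_{mode}.csv")
        path.to_csv(out / f"lasso_path_{mode}.csv")
        scan_results[mode] = {
            "selected_range": label,
            "lambda": lam,
            "ar_argmax": max(
                (k for k, v in scan.ar_by_range.items() if v is not None),
                key=lambda k: scan.ar_by_range[k],
                default=None,
            ),
            "refit_coef": float(refit.params.loc["minutes_out", "coef"]),
            "refit_p": float(refit.params.loc["minutes_out", "p"]),
        }

    # ---------------- models
    logger.info("stage: models")
    cc = clinical_idx.loc[improved_known].reset_index()
    specs = {
        "null": ModelSpec("improved", ()),
        "linear": ModelSpec("improved", (Poly("amap_mmHg", 1),)),
        "quadratic": ModelSpec("improved", (Poly("amap_mmHg", 2),)),
        "cubic": ModelSpec("improved", (Poly("amap_mmHg", 3),)),
        "ns2": ModelSpec("improved", (NaturalSpline("amap_mmHg", 2),)),
        "ns3": ModelSpec("improved", (NaturalSpline("amap_mmHg", 3),)),
    }
    fits = {name: fit_logistic(s, cc) for name, s in specs.items()}
    comparisons = {
        "linear_vs_null": likelihood_ratio_test(fits["null"], fits["linear"]),
        "quadratic_vs_linear": likelihood_ratio_test(fits["linear"], fits["quadratic"]),
        "cubic_vs_quadratic": likelihood_ratio_test(fits["quadratic"], fits["cubic"]),
    }
    model_table = {
        name: {
            "aic": fit.aic,
            "deviance": fit.deviance,
            "n_params": fit.n_params,
            "loocv_error": loocv_error(specs[name], cc),
        }
        for name, fit in fits.items()
    }

    summary.update(
        {
            "n_patients": len(cohort),
            "n_outcome_known": int(improved_known.sum()),
            "k_min": solution.k_min,
            "k_selected": solution.k,
            "d_selected": solution.selected_d,
            "network_k": network.k_used,
            "t_selected": network.t_used,
            "n_clusters": network.n_clusters,
            "modularity_q": network.modularity_q,
            "range_scan": scan_results,
            "model_comparison": comparisons,
            "model_table": model_table,
        }
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
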