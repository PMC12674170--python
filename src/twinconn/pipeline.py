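"""End-to-end orchestration: configuration, stage sequencing, JSON report.

Stages run in dependency order — edge construction / cohort loading,
G-score adjustment and twin correlations, cross-twin LOGOCV prediction,
consensus edges, co-twin fingerprinting, difference models (whole-brain
and per network), and the closing correlation comparisons.  Everything is
deterministic given the configured seeds, and the report carries enough
provenance (config echo, seeds, version) to reproduce every number.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .atlas import NetworkAtlas, canonical_atlas, read_atlas, scaled_atlas
from .cohort import Cohort, save_ground_truth
from .consensus import (
    consensus_edge_table,
    network_tally,
    node_strength,
    tally_edge_selection,
    threshold_consensus,
    top_k_nodes,
)
from .corrstats import compare_independent_correlations
from .cross_twin import run_logocv_bootstrap
from .diff_predict import (
    network_specific_prediction,
    pair_differences,
    run_kfold_diff_prediction,
)
from .fingerprint import identification_accuracy
from .gscore import adjust_cohort, falconer_h2, twin_pair_correlation
from .simulate import generate_study_cohort

logger = logging.getLogger(__name__)

DEFAULT_STAGES = (
    "gscore", "cross_twin", "consensus", "fingerprint", "diff_predict", "corrstats",
)


@dataclass
class AnalysisConfig:
    """Everything a full run needs; YAML round-trippable."""

    cohort_dir: str | None = None          # saved cohort (roster + edges)
    atlas_path: str | None = None
    output_dir: str = "twinconn_output"
    stages: tuple = DEFAULT_STAGES
    # synthetic-cohort fallback when no cohort_dir is given
    simulate: dict = field(default_factory=dict)
    seed: int = 0
    # cross-twin engine
    B: int = 1000
    perms_per_model: int = 100
    alpha_screen: float = 0.05
    component_grid_max: int = 100
    inner_folds: int = 5
    # consensus
    consensus_fraction: float = 0.5
    top_k: int = 5
    # difference models
    k_folds: int = 10
    top_m: int = 400
    n_perm: int = 5000
    networks: tuple | None = None          # None -> all atlas networks
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        if self.networks is not None:
            out["networks"] = list(self.networks)
        return out


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_inputs(config: AnalysisConfig) -> tuple[Cohort, NetworkAtlas, dict | None]:
    truth = None
    if config.cohort_dir is not None:
        cohort = Cohort.load(config.cohort_dir)
    else:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        syn = generate_study_cohort(**sim_kwargs)
        cohort = syn.cohort
        truth = syn.ground_truth()
    if config.atlas_path is not None:
        atlas = read_atlas(config.atlas_path)
    elif cohort.node_count == 268:
        atlas = canonical_atlas()
    else:
        atlas = scaled_atlas(cohort.node_count)
    if atlas.node_count != cohort.node_count:
        raise ValueError(
            f"atlas has {atlas.node_count} nodes, cohort {cohort.node_count}"
        )
    return cohort, atlas, truth


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the enabled stages and write the JSON report.

    Returns the report dict; partial results are flushed to
    ``<output_dir>/report.json`` even when a later stage fails.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "twinconn_version": __version__,
            "seed": config.seed,
            "config": config.as_dict(),
        }
    }
    stages = set(config.stages)
    if "consensus" in stages and "cross_twin" not in stages:
        raise StageError(
            "consensus", ValueError("requires the cross_twin stage to be enabled")
        )
    if "fingerprint" in stages and "cross_twin" not in stages:
        logger.info("fingerprint will use whole-brain edges only (no cross_twin)")

    def _flush() -> None:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)

    try:
        cohort, atlas, truth = _load_inputs(config)
        cohort = adjust_cohort(cohort)
        if truth is not None:
            save_ground_truth(out_dir / "ground_truth.json", truth)
        zygosities = [
            z for z in ("MZ", "DZ") if (cohort.roster["zygosity"] == z).any()
        ]
        report["provenance"]["n_pairs"] = {
            z: int((cohort.roster["zygosity"] == z).sum()) // 2 for z in zygosities
        }

        if "gscore" in stages:
            t0 = time.time()
            block: dict = {}
            for z in zygosities:
                r, p = twin_pair_correlation(cohort, z, double_entry=True)
                block[z] = {"r": r, "p": p}
            if set(zygosities) == {"MZ", "DZ"}:
                est = falconer_h2(block["MZ"]["r"], block["DZ"]["r"])
                block["falconer_h2"] = est.h2
            report["gscore"] = block
            logger.info("gscore stage done in %.1fs", time.time() - t0)

        cross_results = {}
        if "cross_twin" in stages:
            for z in zygosities:
                t0 = time.time()
                res = run_logocv_bootstrap(
                    cohort, z, B=config.B,
                    perms_per_model=config.perms_per_model,
                    alpha_screen=config.alpha_screen,
                    component_grid_max=config.component_grid_max,
                    inner_folds=config.inner_folds,
                    seed=config.seed,
                )
                cross_results[z] = res
                np.savetxt(
                    out_dir / f"cross_twin_r_{z}.tsv", res.per_iteration_r,
                    header="per_iteration_r", comments="",
                )
                logger.info(
                    "cross_twin %s: mean r=%.3f p=%.4g (%.1fs)",
                    z, res.mean_r, res.p_perm, time.time() - t0,
                )
            report["cross_twin"] = {z: r.as_dict() for z, r in cross_results.items()}

        consensus_edges: dict = {}
        if "consensus" in stages:
            block = {}
            for z, res in cross_results.items():
                cons = tally_edge_selection(res.selections, cohort.n_edges)
                kept = threshold_consensus(cons, config.consensus_fraction)
                consensus_edges[z] = kept
                strengths = node_strength(kept, cohort.node_count)
                table = top_k_nodes(strengths, config.top_k, atlas)
                tally = network_tally(kept, atlas)
                consensus_edge_table(kept, cons, atlas).to_csv(
                    out_dir / f"consensus_edges_{z}.csv", index=False
                )
                block[z] = {
                    "n_consensus_edges": int(kept.size),
                    "top_nodes": table.to_dict(orient="records"),
                    "network_tally": tally.to_dict(),
                }
            report["consensus"] = block

        if "fingerprint" in stages:
            block = {}
            for z in zygosities:
                entry = {
                    "whole_brain": identification_accuracy(cohort, z).as_dict()
                }
                mask = consensus_edges.get(z)
                if mask is not None and mask.size >= 2:
                    entry["intelligence_related"] = identification_accuracy(
                        cohort, z, edge_mask=mask
                    ).as_dict()
                block[z] = entry
            report["fingerprint"] = block

        diff_results: dict = {}
        if "diff_predict" in stages:
            block = {}
            for z in zygosities:
                diffs = pair_differences(cohort, z)
                whole = run_kfold_diff_prediction(
                    diffs, k=config.k_folds, top_m=config.top_m,
                    n_perm=config.n_perm, seed=config.seed,
                    component_grid_max=config.component_grid_max,
                    inner_folds=config.inner_folds,
                )
                nets = (
                    list(config.networks)
                    if config.networks is not None
                    else atlas.networks
                )
                per_net = {}
                for net in nets:
                    per_net[net] = network_specific_prediction(
                        diffs, atlas, net, k=config.k_folds,
                        top_m=config.top_m, n_perm=config.n_perm,
                        seed=config.seed,
                        component_grid_max=config.component_grid_max,
                        inner_folds=config.inner_folds,
                    )
                diff_results[z] = {"whole_brain": whole, "networks": per_net}
                block[z] = {
                    "whole_brain": whole.as_dict(),
                    "networks": {n: r.as_dict() for n, r in per_net.items()},
                }
            report["diff_predict"] = block

        if "corrstats" in stages:
            block = {}
            if len(cross_results) == 2:
                mz, dz = cross_results["MZ"], cross_results["DZ"]
                # correlations across individuals -> per-individual counts
                block["cross_twin_MZ_vs_DZ"] = compare_independent_correlations(
                    mz.mean_r, 2 * mz.n_pairs, dz.mean_r, 2 * dz.n_pairs
                ).as_dict()
            if len(diff_results) == 2:
                wmz = diff_results["MZ"]["whole_brain"]
                wdz = diff_results["DZ"]["whole_brain"]
                # correlations across pairs -> per-pair counts
                block["diff_whole_brain_MZ_vs_DZ"] = (
                    compare_independent_correlations(
                        wmz.r, wmz.observed.size, wdz.r, wdz.observed.size
                    ).as_dict()
                )
                for net in diff_results["MZ"]["networks"]:
                    nmz = diff_results["MZ"]["networks"][net]
                    ndz = diff_results["DZ"]["networks"][net]
                    block[f"diff_{net}_MZ_vs_DZ"] = (
                        compare_independent_correlations(
                            nmz.r, nmz.observed.size, ndz.r, ndz.observed.size
                        ).as_dict()
                    )
            report["corrstats"] = block

        if config.make_plots and cross_results:
            from .plotting import plot_bootstrap_distributions

            for z, res in cross_results.items():
                plot_bootstrap_distributions(
                    res, out_dir / f"cross_twin_{z}.png"
                )
    except StageError:
        _flush()
        raise
    except Exception as exc:
        _flush()
        stage = _current_stage(report)
        raise StageError(stage, exc) from exc

    _flush()
    with open(out_dir / "summary.txt", "w") as fh:
        fh.write(render_summary(report))
    return report


def _current_stage(report: dict) -> str:
    done = [k for k in report if k != "provenance"]
    order = ["inputs", *DEFAULT_STAGES]
    return order[len(done) + 1] if len(done) + 1 < len(order) else order[-1]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def render_summary(report: dict) -> str:
    """Human-readable digest of a report."""
    lines = [f"twinconn {report['provenance']['twinconn_version']} analysis report"]
    if "gscore" in report:
        g = report["gscore"]
        for z in ("MZ", "DZ"):
            if z in g:
                lines.append(
                    f"  twin G correlation {z}: r={g[z]['r']:.3f} (p={g[z]['p']:.2g})"
                )
        if "falconer_h2" in g:
            lines.append(f"  Falconer h2 = {g['falconer_h2']:.3f}")
    if "cross_twin" in report:
        for z, r in report["cross_twin"].items():
            lines.append(
                f"  cross-twin prediction {z}: mean r={r['mean_r']:.3f} "
                f"p_perm={r['p_perm']:.4g} (B={r['n_iterations']})"
            )
    if "consensus" in report:
        for z, c in report["consensus"].items():
            lines.append(f"  consensus edges {z}: {c['n_consensus_edges']}")
    if "fingerprint" in report:
        for z, f in report["fingerprint"].items():
            for kind, d in f.items():
                lines.append(
                    f"  identification {z} ({kind}): {d['accuracy_percent']:.1f}%"
                )
    if "diff_predict" in report:
        for z, d in report["diff_predict"].items():
            wb = d["whole_brain"]
            lines.append(
                f"  dG prediction {z} (whole brain): r={wb['r']:.3f} "
                f"p_perm={wb['p_perm']:.4g}"
            )
    return "\n".join(lines) + "\n"
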