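"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` executes the standard sequence — read (or simulate) →
QC filter → diversity tables → reduction → AMOVA / pairwise R_ST /
SAMOVA → Nei + PCoA + Sammon MDS → Mantel geography test → haplogroup
batch prediction → MSN / MJ networks — writing one artifact file per
stage plus a consolidated JSON summary. Stages can be toggled; every
stochastic stage takes its seed from the config and logs it. Rerunning
an identical config reproduces all numeric outputs exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import diversity, network, ordination, structure
from .cohort import Cohort, qc_filter_biallelic, reduce_for_rst
from .haplogroup import HaplogroupFrequencyModel, batch_predict
from .io import read_cohort, write_cohort
from .panel import PPY23
from .simulate import SimConfig, simulate_cohort, truth_labels, write_truth

log = logging.getLogger("ystrkit.pipeline")

_ALL_STAGES = ("diversity", "structure", "ordination", "haplogroup", "network")


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, thresholds, seeds and toggles for one pipeline run."""

    output_dir: str
    input_path: str | None = None  # cohort CSV; mutually exclusive with simulation
    simulation: SimConfig | None = None
    stages: tuple[str, ...] = _ALL_STAGES
    permutations: int = 200
    seed: int = 0
    min_score: float = 40.0
    min_prob: float = 0.95
    samova_k: int | None = None  # default: number of regions
    haplogroup_model_path: str | None = None  # required for file input + haplogroup stage
    haplogroup_subset: tuple[str, ...] | None = None
    mj_top_haplogroups: int = 3

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path / simulation must be set")
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.permutations < 0:
            raise ValueError("permutations must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "simulation" in d and d["simulation"] is not None:
            d["simulation"] = SimConfig.from_dict(d["simulation"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns (and writes) the summary dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}
    t0 = time.time()

    # --- input -------------------------------------------------------------
    truth = None
    if config.simulation is not None:
        log.info("simulating cohort: n=%d seed=%d", config.simulation.n_samples, config.simulation.seed)
        cohort, truth = simulate_cohort(config.simulation)
        write_cohort(cohort, out / "cohort.csv")
        write_truth(truth, out / "truth.csv")
    else:
        log.info("reading cohort from %s", config.input_path)
        cohort = read_cohort(config.input_path, PPY23)
    summary["n_input"] = len(cohort)

    filtered, discarded = qc_filter_biallelic(cohort)
    log.info("QC filter: %d retained, %d discarded", len(filtered), len(discarded))
    summary["n_retained"] = len(filtered)
    summary["discarded_biallelic"] = discarded

    reduced = reduce_for_rst(filtered)
    summary["n_reduced"] = len(reduced)

    # --- diversity ---------------------------------------------------------
    if "diversity" in config.stages:
        _stage_log("diversity")
        fs = diversity.forensic_summary(filtered)
        (out / "forensic_summary.json").write_text(json.dumps(fs.to_dict(), indent=1))
        diversity.locus_gd_table(filtered).to_csv(out / "locus_gd.csv")
        table, flagged = diversity.per_population_gd_table(filtered)
        table.to_csv(out / "population_locus_gd.csv")
        summary["forensic"] = fs.to_dict()
        summary["gd_flagged_populations"] = flagged

    # --- structure ---------------------------------------------------------
    if "structure" in config.stages:
        _stage_log("structure")
        grouping = {s.population: s.region for s in reduced.samples}
        res = structure.amova(
            reduced, grouping=grouping, permutations=config.permutations, seed=config.seed
        )
        (out / "amova.json").write_text(json.dumps(res.to_dict(), indent=1))
        summary["amova"] = res.to_dict()

        rst, pvals = structure.pairwise_rst(reduced, permutations=0)
        rst.to_csv(out / "pairwise_rst.csv")
        summary["mean_pairwise_rst"] = float(rst.condensed().mean())

        k = config.samova_k or len({s.region for s in reduced.samples})
        if 2 <= k < len(reduced.populations):
            best_grouping, best = structure.samova_search(reduced, k=k, seed=config.seed)
            (out / "samova.json").write_text(
                json.dumps({"grouping": best_grouping, "result": best.to_dict()}, indent=1)
            )
            summary["samova_phi_ct"] = best.phi_ct

    # --- ordination + geography -------------------------------------------
    if "ordination" in config.stages:
        _stage_log("ordination")
        nei = structure.nei_distance(filtered)
        nei.to_csv(out / "nei_distance.csv")
        pc = ordination.pcoa(nei, k=2)
        _write_coords(pc, out / "pcoa.csv")
        summary["pcoa_explained"] = list(pc.explained[:2])

        rst, _ = structure.pairwise_rst(reduced, permutations=0)
        locations = {}
        for s in reduced.samples:
            locations.setdefault(s.population, (s.lat, s.lon))
        geo = ordination.geographic_distance_matrix(
            {p: locations[p] for p in rst.labels}
        )
        mds_input = structure.clamp_negative(rst)
        vals = mds_input.values.copy()
        iu = vals[vals > 0]
        floor = iu.min() / 10 if iu.size else 1e-6
        vals[vals <= 0] = floor  # Sammon needs positive dissimilarities
        import numpy as np

        for i in range(len(vals)):
            vals[i, i] = 0.0
        mds = ordination.sammon_mds(
            type(mds_input)(mds_input.labels, (vals + vals.T) / 2), k=2
        )
        _write_coords(mds, out / "mds.csv")
        summary["mds_stress"] = mds.stress

        test = ordination.mantel_test(
            geo, rst.reorder(geo.labels), permutations=config.permutations, seed=config.seed
        )
        summary["geo_genetic"] = {
            "correlation": test.correlation,
            "r_squared": test.r_squared,
            "p_value": test.p_value,
            "permutations": test.permutations,
        }
        (out / "geo_genetic.json").write_text(json.dumps(summary["geo_genetic"], indent=1))

    # --- haplogroups --------------------------------------------------------
    model = None
    if "haplogroup" in config.stages:
        _stage_log("haplogroup")
        if config.haplogroup_model_path:
            model = HaplogroupFrequencyModel.from_json(config.haplogroup_model_path)
        elif truth is not None:
            model = HaplogroupFrequencyModel.from_labeled_cohort(
                filtered, truth_labels(truth)
            )
        if model is None:
            log.warning("haplogroup stage skipped: no model available for file input")
        else:
            calls, props = batch_predict(
                filtered,
                model,
                min_score=config.min_score,
                min_prob=config.min_prob,
                sample_ids=config.haplogroup_subset,
            )
            calls.to_csv(out / "haplogroup_calls.csv", index=False)
            props.to_csv(out / "haplogroup_proportions.csv")
            summary["haplogroup"] = {
                "n_assigned": int((calls["best"] != "UNASSIGNED").sum()),
                "n_total": len(calls),
            }

    # --- networks -----------------------------------------------------------
    if "network" in config.stages:
        _stage_log("network")
        msn = network.collapse_and_msn(filtered)
        msn.write_graphml(out / "msn.graphml")
        summary["msn"] = {"n_haplotypes": msn.n_observed, "n_edges": msn.graph.number_of_edges()}
        if truth is not None:
            weights = network.locus_weights_from_variance(reduced)
            labels = truth_labels(truth)
            reduced_ids = {s.sample_id for s in reduced.samples}
            counts: dict[str, int] = {}
            for sid in reduced_ids:
                counts[labels[sid]] = counts.get(labels[sid], 0) + 1
            top = sorted(counts, key=counts.get, reverse=True)[: config.mj_top_haplogroups]
            summary["mj_networks"] = {}
            for hg in top:
                ids = [sid for sid in reduced_ids if labels[sid] == hg]
                sub = reduced.subset(ids)
                try:
                    mj = network.mj_network(sub, weights=weights)
                except ValueError as exc:
                    log.warning("MJ network for %s skipped: %s", hg, exc)
                    continue
                mj.write_graphml(out / f"mj_{hg}.graphml")
                summary["mj_networks"][hg] = {
                    "n_observed": mj.n_observed,
                    "n_medians": mj.n_medians,
                }

    summary["elapsed_s"] = round(time.time() - t0, 3)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log.info("pipeline finished in %.1fs", summary["elapsed_s"])
    return summary


def _stage_log(name: str) -> None:
    log.info("stage: %s", name)


def _write_coords(res, path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        k = res.coordinates.shape[1]
        w.writerow(["label"] + [f"dim{i + 1}" for i in range(k)])
        for label, row in zip(res.labels, res.coordinates):
            w.writerow([label] + [repr(float(v)) for v in row])
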