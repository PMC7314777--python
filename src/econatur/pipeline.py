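"""End-to-end orchestration: inputs -> every test and model -> bundle.

A run takes either a generator configuration (synthetic world) or
user-supplied CSV/newick inputs, executes the enabled stages and
writes one results file per analysis family plus a ``manifest.json``
with versions, per-stage seeds and runtimes.  Every stochastic stage
receives a seed derived from the master seed by hashing the stage
name, so toggling one stage never shifts another stage's stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    RegionSet,
    TaxonTable,
    ValidationError,
    load_region_set,
    load_taxon_table,
    summarize_counts,
    write_region_set,
    write_taxon_table,
)
from .flows import flow_null_test, flow_results_frame, observed_flows, recipient_map_from_regions
from .phylo import graft_missing_taxa, prune, read_newick
from .regional import (
    fit_latitude_model,
    region_count_medians,
    regional_summaries,
    summaries_frame,
)
from .resampling import (
    category_tests,
    continent_origin_test,
    pd_ses_test,
    resample_count_test,
)
from .stats import (
    fit_pairwise_use_glm,
    fit_pgls,
    fit_use_count_model,
    siegel_regression,
)
from .synthetic_data import (
    GeneratorConfig,
    sample_published_tips,
    simulate_flora,
    simulate_phylogeny,
    simulate_regions,
)

__all__ = ["RunConfig", "run_pipeline", "load_run_config", "stage_seed"]

log = logging.getLogger("econatur")

ALL_STAGES = (
    "counts",
    "categories",
    "use_models",
    "pairwise",
    "origins",
    "flows",
    "regional",
    "pd",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    master_seed: int
    outdir: str
    generator: GeneratorConfig | None = None
    taxa_path: str | None = None
    regions_path: str | None = None
    membership_path: str | None = None
    tree_path: str | None = None
    n_iter: int = 999
    stages: dict = field(default_factory=dict)  # stage -> bool (default on)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def load_run_config(path, outdir: str | None = None) -> RunConfig:
    """Read a YAML run configuration (key/value schema, see README)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen = None
    if "generator" in raw:
        gcfg = dict(raw["generator"] or {})
        gcfg.setdefault("seed", raw.get("seed", 0))
        gen = GeneratorConfig(**gcfg)
    return RunConfig(
        master_seed=int(raw.get("seed", 0)),
        outdir=outdir or raw.get("out", "econatur_run"),
        generator=gen,
        taxa_path=raw.get("taxa"),
        regions_path=raw.get("regions"),
        membership_path=raw.get("region_taxa"),
        tree_path=raw.get("tree"),
        n_iter=int(raw.get("n_iter", 999)),
        stages=dict(raw.get("stages", {})),
    )


def _resampling_frame(results: dict, key_name: str) -> pd.DataFrame:
    recs = []
    for key, res in results.items():
        rec = {key_name: key}
        rec.update(res.to_dict())
        recs.append(rec)
    return pd.DataFrame.from_records(recs)


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; returns the in-memory results."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "econatur_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "master_seed": config.master_seed,
        "n_iter": config.n_iter,
        "stage_seeds": {},
        "stages": {},
    }
    results: dict = {}

    def run_stage(name, fn):
        if not config.enabled(name) and name in ALL_STAGES:
            manifest["stages"][name] = "skipped"
            log.info("stage=%s event=skipped", name)
            return None
        t = time.time()
        log.info("stage=%s event=start", name)
        try:
            value = fn()
        except Exception as e:
            manifest["stages"][name] = f"FAILED: {e}"
            _write_json(out / "manifest.json", manifest)
            (out / "FAILED").write_text(f"stage {name}: {e}\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        dt = time.time() - t
        manifest["stages"][name] = "ok"
        manifest.setdefault("runtimes_s", {})[name] = round(dt, 3)
        log.info("stage=%s event=done elapsed=%.2fs", name, dt)
        return value

    # ---- inputs -----------------------------------------------------------
    def load_inputs():
        if config.generator is not None:
            g = config.generator
            tree_seed = stage_seed(config.master_seed, "tree")
            flora_seed = stage_seed(config.master_seed, "flora")
            region_seed = stage_seed(config.master_seed, "regions")
            manifest["stage_seeds"].update(
                {"tree": tree_seed, "flora": flora_seed, "regions": region_seed}
            )
            full_tree = simulate_phylogeny(g, seed=tree_seed)
            table = simulate_flora(full_tree, g, seed=flora_seed)
            regions = simulate_regions(table, g, seed=region_seed)
            published = sample_published_tips(full_tree, g, seed=tree_seed)
            analysis_tree, unplaced = graft_missing_taxa(published, table)
            write_taxon_table(table, out / "taxa.csv")
            write_region_set(regions, out / "regions.csv", out / "region_taxa.csv")
            published.write_newick(out / "tree.nwk")
            analysis_tree.write_newick(out / "tree_grafted.nwk")
            pd.DataFrame({"taxon_id": unplaced}).to_csv(
                out / "unplaced.csv", index=False, lineterminator="\n"
            )
        else:
            if not config.taxa_path:
                raise ValidationError("no generator and no taxa path given")
            table = load_taxon_table(config.taxa_path)
            regions = (
                load_region_set(config.regions_path, config.membership_path)
                if config.regions_path
                else None
            )
            analysis_tree = None
            unplaced = []
            if config.tree_path:
                tree = read_newick(config.tree_path)
                analysis_tree, unplaced = graft_missing_taxa(tree, table)
        return table, regions, analysis_tree

    table, regions, analysis_tree = run_stage("inputs", load_inputs)
    n_iter = config.n_iter

    # ---- counts -----------------------------------------------------------
    def stage_counts():
        summary = summarize_counts(table)
        _write_json(out / "counts_summary.json", summary.to_dict())
        return summary

    results["counts"] = run_stage("counts", stage_counts)

    # ---- category tests ---------------------------------------------------
    def stage_categories():
        seed = stage_seed(config.master_seed, "categories")
        manifest["stage_seeds"]["categories"] = seed
        frames = []
        res_all = category_tests(table, False, n_iter=n_iter, seed=seed)
        res_single = category_tests(table, True, n_iter=n_iter, seed=seed + 1)
        for label, res in (("all", res_all), ("single_use", res_single)):
            df = _resampling_frame(res, "category")
            df.insert(0, "subset", label)
            frames.append(df)
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(out / "category_tests.csv", index=False, lineterminator="\n")
        return {"all": res_all, "single_use": res_single}

    results["categories"] = run_stage("categories", stage_categories)

    # ---- number-of-uses models -------------------------------------------
    def stage_use_models():
        res: dict = {}
        glm = fit_use_count_model(table)
        glm.to_frame().to_csv(
            out / "use_count_glm.csv", index=False, lineterminator="\n"
        )
        res["use_count_glm"] = glm
        nat_econ = [t for t in table if t.naturalized and t.economic]
        if len(nat_econ) >= 3:
            x = [t.n_uses for t in nat_econ]
            y = [np.log10(t.n_regions) for t in nat_econ]
            try:
                res["regions_siegel"] = siegel_regression(x, y)
            except ValidationError:
                res["regions_siegel"] = None
            if analysis_tree is not None:
                labels = set(analysis_tree.tip_labels())
                sub = [t for t in nat_econ if t.taxon_id in labels]
                if len(sub) >= 5:
                    subtree = prune(analysis_tree, [t.taxon_id for t in sub])
                    order = subtree.tip_labels()
                    info = {t.taxon_id: t for t in sub}
                    yv = np.array([np.log10(info[l].n_regions) for l in order])
                    Xv = np.column_stack(
                        [np.ones(len(order)), [info[l].n_uses for l in order]]
                    )
                    res["regions_pgls"] = fit_pgls(
                        yv, Xv, subtree, order, names=["intercept", "n_uses"]
                    )
        _write_json(
            out / "use_models.json",
            {
                k: (
                    v
                    if isinstance(v, (dict, type(None)))
                    else {
                        "coefficients": v.coefficients,
                        "p_values": v.p_values,
                        "stat_kind": v.stat_kind,
                    }
                )
                for k, v in res.items()
            },
        )
        return res

    results["use_models"] = run_stage("use_models", stage_use_models)

    # ---- pairwise-use model ----------------------------------------------
    def stage_pairwise():
        res = fit_pairwise_use_glm(table)
        res.to_frame().to_csv(
            out / "pairwise_glm.csv", index=False, lineterminator="\n"
        )
        _write_json(
            out / "pairwise_net_effects.json",
            {
                "net_effects": res.extras["net_effects"],
                "dropped_pairs": res.extras["dropped_pairs"],
            },
        )
        return res

    results["pairwise"] = run_stage("pairwise", stage_pairwise)

    # ---- continental origins ---------------------------------------------
    def stage_origins():
        seed = stage_seed(config.master_seed, "origins")
        manifest["stage_seeds"]["origins"] = seed
        if config.generator is not None:
            richness = config.generator.richness_vector() * config.generator.n_taxa
        else:
            counts = {}
            for t in table:
                for c in t.native_continents:
                    counts[c] = counts.get(c, 0) + 1
            from .core import CONTINENTS

            richness = np.array(
                [max(counts.get(c, 0), 1e-9) for c in CONTINENTS]
            )
        frames = []
        out_res = {}
        for label, single in (("all", False), ("single_native", True)):
            r = continent_origin_test(
                table, richness, single, n_iter=n_iter, seed=seed + single
            )
            df = _resampling_frame(r, "continent")
            df.insert(0, "subset", label)
            frames.append(df)
            out_res[label] = r
        pd.concat(frames, ignore_index=True).to_csv(
            out / "origin_tests.csv", index=False, lineterminator="\n"
        )
        return out_res

    results["origins"] = run_stage("origins", stage_origins)

    # ---- flows ------------------------------------------------------------
    def stage_flows():
        if regions is None:
            raise ValidationError("flows stage requires a region set")
        seed = stage_seed(config.master_seed, "flows")
        manifest["stage_seeds"]["flows"] = seed
        rmap = recipient_map_from_regions(regions)
        matrix, excluded = observed_flows(table, rmap)
        matrix.to_csv(out / "flow_matrix.csv", lineterminator="\n")
        res = flow_null_test(table, rmap, n_iter=n_iter, seed=seed)
        flow_results_frame(res).to_csv(
            out / "flow_classification.csv", index=False, lineterminator="\n"
        )
        return {"matrix": matrix, "tests": res, "excluded": excluded}

    results["flows"] = run_stage("flows", stage_flows)

    # ---- regional ---------------------------------------------------------
    def stage_regional():
        if regions is None:
            raise ValidationError("regional stage requires a region set")
        summaries, aggregates = regional_summaries(regions, table)
        summaries_frame(summaries).to_csv(
            out / "regional_summaries.csv", index=False, lineterminator="\n"
        )
        model = fit_latitude_model(summaries)
        model.to_frame().to_csv(
            out / "latitude_model.csv", index=False, lineterminator="\n"
        )
        medians = region_count_medians(table)
        _write_json(
            out / "regional_aggregates.json",
            {**aggregates, **medians},
        )
        return {"summaries": summaries, "aggregates": aggregates,
                "latitude_model": model, "medians": medians}

    results["regional"] = run_stage("regional", stage_regional)

    # ---- phylogenetic diversity ------------------------------------------
    def stage_pd():
        if analysis_tree is None:
            raise ValidationError("pd stage requires a tree")
        seed = stage_seed(config.master_seed, "pd")
        manifest["stage_seeds"]["pd"] = seed
        labels = set(analysis_tree.tip_labels())
        econ = {t.taxon_id for t in table if t.economic} & labels
        nat = {t.taxon_id for t in table if t.naturalized} & labels
        econ_flags = {
            lab: lab in econ for lab in analysis_tree.tip_labels()
        }
        tests = {}
        if econ:
            tests["economic"] = pd_ses_test(
                analysis_tree, econ, n_iter=n_iter, seed=seed
            )
        if nat:
            tests["naturalized"] = pd_ses_test(
                analysis_tree, nat, n_iter=n_iter, seed=seed + 1
            )
            tests["naturalized_use_constrained"] = pd_ses_test(
                analysis_tree, nat, constrain_on=econ_flags,
                n_iter=n_iter, seed=seed + 2,
            )
        _resampling_frame(tests, "test").to_csv(
            out / "pd_tests.csv", index=False, lineterminator="\n"
        )
        return tests

    results["pd"] = run_stage("pd", stage_pd)

    manifest["total_runtime_s"] = round(time.time() - t0, 3)
    _write_json(out / "manifest.json", manifest)
    return results


def global_enrichment_test(
    table: TaxonTable, n_iter: int = 9999, seed: int = 0
):
    """Naturalization enrichment of economic taxa within a full flora.

    Pool = all taxa, flag = naturalized, sample size = number of
    economic taxa, observed = number of naturalized economic taxa.
    """
    flags = np.array([t.naturalized for t in table], dtype=bool)
    n_econ = sum(1 for t in table if t.economic)
    observed = sum(1 for t in table if t.economic and t.naturalized)
    return resample_count_test(flags, n_econ, observed, n_iter=n_iter, seed=seed)
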