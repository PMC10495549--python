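"""End-to-end analysis pipeline: genotypes in, report bundle out.

Runs the full host-associated-differentiation analysis in order — I/O and
filtering, diversity and differentiation statistics, clone correction,
DAPC clustering, migrant detection and (optionally) ABC-RF scenario
comparison — writing TSV/JSON outputs plus a manifest recording the seed,
every defaulted analysis constant, and per-stage row counts.  All stages
are pure functions of (input, config, seed), so a rerun with the same seed
reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geno_io import (
    GenotypeDataset,
    filter_complete,
    read_genotypes,
    subset_min_n,
    write_genotypes,
    write_metadata,
)
from .haplotypes import write_network
from . import abc_rf, assignment, dapc, mlg, popstats, simulate

log = logging.getLogger("broompop")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Analysis constants; defaults follow the study design."""

    input_path: str | None = None  # GenAlEx CSV; None -> synthetic fixture
    meta_path: str | None = None
    fixture: simulate.FixtureConfig | None = None
    min_n: int = 10
    rarefaction_n: int = 50
    n_boot: int = 999
    mantel_permutations: int = 1000
    k_range: tuple[int, int] = (2, 7)
    dapc_k: int | None = None  # cluster count used downstream; default k_range max
    membership_threshold: float = 0.9
    collapse_threshold: float | None = None  # None -> largest-gap heuristic
    migrant_n_sim: int = 10_000
    migrant_alpha: float = 0.01
    abc_enabled: bool = True
    abc_n_per_scenario: int = 10_000
    abc_n_trees: int = 1000
    abc_n_replicates: int = 10
    abc_sample_size: int = 25

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fixture = raw.pop("fixture", None)
        cfg = PipelineConfig(**raw)
        if fixture is not None:
            cfg.fixture = simulate.FixtureConfig(**fixture)
        if "k_range" in raw:
            cfg.k_range = tuple(raw["k_range"])
        return cfg


def _stage(name: str, manifest: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            manifest["stages"][name] = {"status": "running"}
            log.info("stage %s started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest["stages"][name].update(
                seconds=round(dt, 3), status="failed" if exc else "ok"
            )
            if exc:
                log.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed") from exc
            log.info("stage %s finished in %.2fs", name, dt)
            return False

    return _Timer()


def run_pipeline(cfg: PipelineConfig, seed: int, outdir: str | Path) -> dict:
    """Execute every stage and write the report bundle under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(seed)
    stage_seeds = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["fixture", "stats", "mlg", "dapc", "migrants", "abc"], root_ss.spawn(6)
        )
    }
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": _config_dict(cfg),
        "stages": {},
        "decisions": {},
    }

    # -- stage: input -------------------------------------------------------
    truth = None
    with _stage("input", manifest):
        if cfg.input_path:
            ds = read_genotypes(cfg.input_path, meta_path=cfg.meta_path)
        else:
            fx = simulate.make_study_fixture(cfg.fixture, stage_seeds["fixture"])
            ds, truth = fx.dataset, fx.truth
            write_genotypes(ds, out / "fixture_genotypes.csv")
            write_metadata(ds, out / "fixture_metadata.csv")
            truth.to_csv(out / "fixture_truth.tsv", sep="\t", index=False)
        manifest["stages"]["input"]["n_individuals"] = ds.n_individuals
        manifest["stages"]["input"]["n_loci"] = ds.n_loci
        manifest["stages"]["input"]["n_populations"] = len(ds.population_ids)

    complete = filter_complete(ds)
    working = subset_min_n(complete, cfg.min_n)
    hosts = working.host_of_population

    # -- stage: popstats ----------------------------------------------------
    with _stage("popstats", manifest):
        rng = stage_seeds["stats"]
        div = popstats.diversity_by_population(working)
        div.table.to_csv(out / "diversity_by_population.tsv", sep="\t")
        fst = popstats.wc_fstats(working, n_boot=cfg.n_boot, seed=rng)
        jd = popstats.jost_d(working, n_boot=min(cfg.n_boot, 199), seed=rng, groups=hosts)
        host_counts = pd.Series([hosts[p] for p in working.population_ids]).value_counts()
        main_hosts = list(host_counts[host_counts >= 2].index[:3])
        amova_res = None
        if len(main_hosts) >= 2:
            sub_idx = [
                i for i, s in enumerate(working.samples) if s.host_crop in main_hosts
            ]
            amova_ds = working.take(sub_idx)
            amova_res = popstats.amova_nested(
                amova_ds, amova_ds.host_of_population, n_boot=cfg.n_boot, seed=rng
            )
            amova_res.table.to_csv(out / "amova.tsv", sep="\t")
        mantel_rows = []
        for h in main_hosts:
            plist = [p for p in working.population_ids if hosts[p] == h]
            if len(plist) < 3:
                continue
            coords = {}
            for p in plist:
                s = next(s for s in working.samples if s.population_id == p)
                coords[p] = (s.latitude, s.longitude)
            if any(v[0] is None for v in coords.values()):
                continue
            geo = popstats.great_circle_matrix(coords)
            idx = np.concatenate([working.populations[p] for p in plist])
            gen = popstats.pairwise_theta(working.take(idx))
            r, p_val = popstats.mantel_test(
                gen, geo, n_perm=cfg.mantel_permutations, seed=rng
            )
            mantel_rows.append({"host_crop": h, "mantel_r": r, "p_value": p_val})
        pd.DataFrame(mantel_rows).to_csv(out / "mantel.tsv", sep="\t", index=False)
        summary = {
            "theta": fst.theta,
            "theta_ci": fst.theta_ci,
            "f_is": fst.f_is,
            "f_is_ci": fst.f_is_ci,
            "jost_d": jd["D"],
            "jost_d_ci": jd["ci_95"],
            "jost_d_per_host": jd["per_stratum"],
        }
        if amova_res is not None:
            summary["amova_phi_ct"] = amova_res.phi_ct
            summary["amova_phi_sc"] = amova_res.phi_sc
            summary["amova_phi_st"] = amova_res.phi_st
        (out / "popstats_summary.json").write_text(json.dumps(summary, indent=2))

    # -- stage: mlg ---------------------------------------------------------
    with _stage("mlg", manifest):
        dist = mlg.bruvo_distance(complete)
        table = mlg.collapse_mlgs(complete, dist, cfg.collapse_threshold)
        manifest["decisions"]["collapse_threshold"] = table.threshold
        table.individuals.to_csv(out / "mlg_assignments.tsv", sep="\t", index=False)
        mlg.genotypic_diversity(table, cfg.rarefaction_n, by="population_id").to_csv(
            out / "mlg_diversity_by_population.tsv", sep="\t"
        )
        mlg.genotypic_diversity(table, cfg.rarefaction_n, by="host_crop").to_csv(
            out / "mlg_diversity_by_host.tsv", sep="\t"
        )
        per_mlg, tally = mlg.classify_sharing(table)
        per_mlg.assign(hosts=per_mlg["hosts"].map(",".join)).to_csv(
            out / "mlg_classes.tsv", sep="\t", index=False
        )
        tally.to_csv(out / "mlg_sharing_by_host.tsv", sep="\t")
        try:
            net = mlg.msn_graph(complete, table)
            write_network(net, out / "mlg_msn_edges.tsv")
        except ValueError:
            log.warning("no non-singleton MLGs; network skipped")

    # -- stage: dapc --------------------------------------------------------
    with _stage("dapc", manifest):
        rng = stage_seeds["dapc"]
        k_lo, k_hi = cfg.k_range
        k_hi = min(k_hi, working.n_individuals - 1)
        bic, assign = dapc.find_clusters(working, k_max=k_hi, seed=rng)
        bic.to_csv(out / "dapc_bic.tsv", sep="\t", header=True)
        k_use = cfg.dapc_k or k_hi
        labels = assign[k_use]
        grid = [g for g in (10, 20, 40, 80) if g < working.n_individuals]
        best_npca, ascores = dapc.optimize_ascore(working, labels, grid, seed=rng)
        manifest["decisions"]["dapc_n_pca"] = best_npca
        model = dapc.fit_dapc(working, labels, n_pca=best_npca)
        model.memberships.to_csv(out / "dapc_memberships.tsv", sep="\t")
        pop_of = {s.individual_id: s.population_id for s in working.samples}
        per_ind, patterns = dapc.categorize_individuals(
            model, cfg.membership_threshold, population_of=pop_of
        )
        per_ind.to_csv(out / "dapc_individuals.tsv", sep="\t")
        patterns.to_csv(out / "dapc_population_patterns.tsv", sep="\t")
        host_of_ind = {s.individual_id: s.host_crop for s in working.samples}
        contingency = pd.crosstab(
            per_ind["cluster"], pd.Series(host_of_ind, name="host_crop")
        )
        contingency.to_csv(out / "dapc_cluster_by_host.tsv", sep="\t")
        manifest["stages"]["dapc"]["k_used"] = int(k_use)
        manifest["stages"]["dapc"]["admixed_fraction"] = float(
            (per_ind["status"] == "admixed").mean()
        )

    # -- stage: migrants ----------------------------------------------------
    with _stage("migrants", manifest):
        res = assignment.detect_migrants(
            working,
            n_sim=cfg.migrant_n_sim,
            alpha=cfg.migrant_alpha,
            seed=stage_seeds["migrants"],
            min_ref=cfg.min_n,
        )
        res.per_individual.to_csv(out / "migrants_by_individual.tsv", sep="\t", index=False)
        res.per_population.to_csv(out / "migrants_by_population.tsv", sep="\t")
        manifest["stages"]["migrants"]["mean_migration_rate"] = float(
            res.per_population["migration_rate"].mean()
        )

    # -- stage: abc ---------------------------------------------------------
    if cfg.abc_enabled:
        with _stage("abc", manifest):
            rng = stage_seeds["abc"]
            abc_seed = int(rng.integers(2**31 - 1))
            host_counts = pd.Series(
                [hosts[p] for p in working.population_ids]
            ).value_counts()
            demes3 = list(host_counts.index[:3])
            if len(demes3) < 3:
                raise ValueError("ABC needs at least 3 host clusters in the data")
            mapping = {
                p: hosts[p] for p in working.population_ids if hosts[p] in demes3
            }
            observed = abc_rf.compute_sumstats(working, demes=mapping)
            sizes = {d: cfg.abc_sample_size for d in demes3}
            # observed statistics are computed on everything available; the
            # training sample sizes are fixed per deme for comparability
            scen6 = simulate.build_six_scenarios(demes3, sizes)
            loci = working.loci
            ts = abc_rf.build_training_set(
                scen6,
                n_per_scenario=cfg.abc_n_per_scenario,
                sample_sizes=sizes,
                loci=loci,
                seed=abc_seed,
            )
            ts.write_tsv(out / "abc_training.tsv")
            rf_res = abc_rf.choose_scenario(
                ts,
                observed,
                n_trees=cfg.abc_n_trees,
                n_replicates=cfg.abc_n_replicates,
                seed=abc_seed + 1,
            )
            ghost = simulate.build_ghost_scenario(demes3, sizes)
            ts_ghost = abc_rf.build_training_set(
                [ghost],
                n_per_scenario=max(cfg.abc_n_per_scenario, 2),
                sample_sizes=sizes,
                loci=loci,
                seed=abc_seed + 2,
            )
            est = abc_rf.estimate_params(
                ts_ghost,
                observed,
                n_trees=cfg.abc_n_trees,
                seed=abc_seed + 3,
                parameters=[c for c in ts_ghost.params.columns if c.startswith("t_")],
            )
            est.table.to_csv(out / "abc_param_estimates.tsv", sep="\t")
            check = abc_rf.prior_scenario_check(
                ghost,
                observed,
                n_sim=min(2000, max(cfg.abc_n_per_scenario, 2)),
                seed=abc_seed + 4,
                sample_sizes=sizes,
                loci=loci,
            )
            check.to_csv(out / "abc_prior_check.tsv", sep="\t")
            abc_summary = {
                "votes": rf_res.votes.to_dict(),
                "selected": rf_res.selected,
                "posterior": rf_res.posterior,
                "global_error": rf_res.global_error,
                "local_error": rf_res.local_error,
                "stat_manifest": ts.stat_names,
            }
            (out / "abc_summary.json").write_text(json.dumps(abc_summary, indent=2))
            manifest["decisions"]["abc_stat_manifest"] = ts.stat_names

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if cfg.fixture is not None:
        d["fixture"] = dataclasses.asdict(cfg.fixture)
    return d
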