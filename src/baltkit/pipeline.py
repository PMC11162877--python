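"""Configuration-driven orchestration of the full synthetic-study pipeline.

A single YAML/JSON config drives: frequency simulation on a population
tree -> modern diploid panel -> ancient pileups -> pseudo-haploid calls
-> site filtering -> the toggled analyses (f3, pairwise mismatch,
projection PCA, ROH, continuity LRT, sexing, insertion genotyping).
Every stage writes TSV/JSON under the output directory plus a combined
``report.json``; outputs are deterministic (byte-identical) for a fixed
config, and site counts are logged after each filter so the funnel from
simulated to analysed SNPs is auditable.
"""

from __future__ import annotations

import copy
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import geno, pca, reads, roh, simdata, stats
from .continuity import build_continuity_input, fit_continuity
from .core import Dataset

__all__ = ["ConfigError", "default_config", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


_ANALYSES = ("f3", "mismatch", "pca", "roh", "continuity", "sexdet", "insgeno")

_DEFAULTS = {
    "filters": {"max_missing": 0.1, "min_maf": 0.01, "transversions_only": True},
    "ld_prune": {"enabled": True, "window_snps": 200, "step_snps": 25,
                 "r2_max": 0.4},
    "block_size_bp": 5e6,
    "pca": {"k": 4, "shrink": False},
    "roh": {"planted_segments": []},
    "sexdet": {"sexes": {"ancient_F": "female", "ancient_M": "male"},
               "autosomal_depth": 1.0, "cv": 0.05},
    "insgeno": {"carriers": {"carrier_ind": True, "noncarrier_ind": False},
                "n_reads": 20, "read_length": 60, "min_overhang": 10,
                "max_overhang_mismatches": 1},
}


def default_config() -> dict:
    """A small, fully runnable demo configuration."""
    return {
        "seed": 1,
        "simulation": {
            "tree": {
                "branches": [
                    ["root", "Outgroup", 0.15],
                    ["root", "domestic", 0.02],
                    ["domestic", "anc1", 0.02],
                    ["domestic", "BreedY", 0.06],
                    ["anc1", "BreedZ", 0.06],
                    ["anc1", "anc2", 0.03],
                    ["anc2", "Ancient", 0.02],
                    ["anc2", "BreedX", 0.04],
                ],
                "outgroup": "Outgroup",
            },
            "n_snps": 4000,
            "n_per_pop": {"Outgroup": 6, "BreedX": 15, "BreedY": 15,
                          "BreedZ": 15},
            "ancient": {
                "population": "Ancient", "n_individuals": 4,
                "mean_depth": 2.0, "damage_rate": 0.1,
                "error_rate": 0.001, "missing_rate": 0.05,
            },
        },
        "analyses": {a: a in ("f3", "mismatch", "pca", "sexdet", "insgeno",
                              "continuity")
                     for a in _ANALYSES},
    }


def _merge_defaults(cfg: dict, defaults: dict) -> dict:
    out = copy.deepcopy(defaults)
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = {**out[key], **val}
        else:
            out[key] = val
    return out


def validate_config(config: dict) -> dict:
    """Check, normalize and default-fill a pipeline configuration.

    Unknown top-level keys are rejected; a master ``seed`` is mandatory
    (per-stage seeds are derived from it deterministically and recorded
    in the normalized config); obviously invalid numbers are reported
    together rather than one at a time.
    """
    errors = []
    known = {"seed", "out_dir", "simulation", "filters", "ld_prune",
             "block_size_bp", "pca", "roh", "sexdet", "insgeno", "analyses",
             "continuity"}
    for key in config:
        if key not in known:
            errors.append(f"unknown key {key!r}")
    if "seed" not in config:
        errors.append("missing master 'seed' (stage: global)")
    if "simulation" not in config:
        errors.append("missing 'simulation' section")
    cfg = _merge_defaults(config, _DEFAULTS)
    cfg.setdefault("analyses", {})
    for a in _ANALYSES:
        cfg["analyses"].setdefault(a, False)
    unknown_an = set(cfg["analyses"]) - set(_ANALYSES)
    if unknown_an:
        errors.append(f"unknown analyses: {sorted(unknown_an)}")
    filt = cfg["filters"]
    for key in ("max_missing", "min_maf"):
        v = filt.get(key)
        if not isinstance(v, (int, float)) or not (0 <= v <= 1):
            errors.append(f"filters.{key} must lie in [0, 1], got {v!r}")
    if cfg.get("block_size_bp", 0) <= 0:
        errors.append("block_size_bp must be positive")
    sim = cfg.get("simulation") or {}
    if "simulation" in config:
        if "tree" not in sim:
            errors.append("simulation.tree is required")
        if sim.get("n_snps", 0) < 1:
            errors.append("simulation.n_snps must be >= 1")
    if errors:
        raise ConfigError(errors)
    # derive per-stage seeds from the master seed
    master = int(config["seed"])
    ss = np.random.SeedSequence(master)
    stage_names = ("frequencies", "diploids", "pileup", "pseudohaploid",
                   "mismatch", "pca", "sexdet", "insgeno", "roh")
    children = ss.spawn(len(stage_names))
    cfg["stage_seeds"] = {name: int(child.generate_state(1)[0] % (2**31))
                          for name, child in zip(stage_names, children)}
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: dict, out_dir=None, log=None) -> dict:
    """Execute the configured synthetic study and return the report dict.

    Writes per-stage TSV/JSON files plus ``report.json`` and an
    ``events.jsonl`` stage log under ``out_dir``. Stage failures abort
    with partial outputs preserved and a machine-readable error record
    in ``events.jsonl``.
    """
    cfg = validate_config(config)
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "baltkit_out"))
    out.mkdir(parents=True, exist_ok=True)
    events_path = out / "events.jsonl"
    events = open(events_path, "w")
    log = log if log is not None else sys.stderr

    def event(stage, **info):
        rec = {"stage": stage, **info}
        events.write(json.dumps(rec, sort_keys=True) + "\n")
        print(f"[baltkit] {stage}: {info}", file=log)

    report: dict = {"seed": cfg["seed"], "stage_seeds": cfg["stage_seeds"],
                    "site_counts": {}}
    seeds = cfg["stage_seeds"]
    try:
        # --- simulation -------------------------------------------------
        sim = cfg["simulation"]
        tree = simdata.PopulationTreeSpec(
            branches=[tuple(b) for b in sim["tree"]["branches"]],
            outgroup=sim["tree"]["outgroup"],
            admixture_edges=[tuple(e) for e in sim["tree"].get("admixture_edges", [])],
        )
        freqs = simdata.simulate_frequencies(tree, int(sim["n_snps"]),
                                             seed=seeds["frequencies"])
        report["site_counts"]["ascertained"] = int(len(freqs))
        event("simulate_frequencies", n_snps_requested=int(sim["n_snps"]),
              n_snps_ascertained=int(len(freqs)))
        modern, variants = simdata.sample_diploids(
            freqs, sim["n_per_pop"], seed=seeds["diploids"])
        report["truth"] = {
            "populations": sorted(sim["n_per_pop"]),
            "tree_branches": [list(b) for b in tree.branches],
            "n_modern": int(modern.n_individuals),
        }
        geno.write_eigenstrat(out / "modern", variants, modern)

        anc_cfg = sim.get("ancient")
        ancient_calls = None
        if anc_cfg:
            anc_pop = anc_cfg["population"]
            anc_freq = freqs[[anc_pop]]
            anc_geno, _ = simdata.sample_diploids(
                anc_freq, {anc_pop: int(anc_cfg["n_individuals"])},
                seed=seeds["diploids"] + 1, variants=variants)
            spec = simdata.AncientSamplingSpec(
                mean_depth=float(anc_cfg.get("mean_depth", 1.0)),
                damage_rate=float(anc_cfg.get("damage_rate", 0.0)),
                error_rate=float(anc_cfg.get("error_rate", 0.0)),
                missing_rate=float(anc_cfg.get("missing_rate", 0.0)))
            pileup = simdata.simulate_ancient_pileup(anc_geno, variants, spec,
                                                     seed=seeds["pileup"])
            geno.write_pileup_tsv(out / "ancient_pileup.tsv", pileup, variants)
            ancient_calls = geno.pseudo_haploidize_pileup(
                pileup, variants, seed=seeds["pseudohaploid"])
            ancient_calls.populations[:] = "AncientGroup"
            event("ancient_sampling", n_individuals=int(anc_cfg["n_individuals"]),
                  mean_depth=spec.mean_depth)

        # --- filtering --------------------------------------------------
        site_keep = np.ones(variants.n_sites, dtype=bool)
        if cfg["filters"]["transversions_only"]:
            site_keep &= ~geno.mask_transitions(variants)
        modern_f = modern.subset_sites(site_keep)
        variants_f = variants.subset(site_keep)
        report["site_counts"]["after_transversion_mask"] = int(site_keep.sum())
        modern_f, variants_f, kept = geno.filter_sites(
            modern_f, variants_f, cfg["filters"]["max_missing"],
            cfg["filters"]["min_maf"])
        if ancient_calls is not None:
            ancient_calls = ancient_calls.subset_sites(site_keep).subset_sites(kept)
        report["site_counts"]["after_site_filters"] = int(variants_f.n_sites)
        event("filter_sites", kept=int(variants_f.n_sites))

        blocks = stats.make_blocks(variants_f, cfg["block_size_bp"])
        toggles = cfg["analyses"]

        # --- f3 ---------------------------------------------------------
        if toggles["f3"] and ancient_calls is not None:
            freq_mod, nobs_mod = stats.group_allele_freqs(modern_f)
            freq_anc, nobs_anc = stats.group_allele_freqs(
                ancient_calls, {"AncientGroup": range(ancient_calls.n_individuals)})
            freq_all = pd.concat([freq_mod, freq_anc], axis=1)
            rows = []
            for popx in sorted(set(modern_f.populations) - {tree.outgroup}):
                est = stats.f3_outgroup(tree.outgroup, "AncientGroup", popx,
                                        freq_all, blocks)
                rows.append({"outgroup": tree.outgroup, "pop_a": "AncientGroup",
                             "pop_b": popx, **est.to_dict()})
            f3_df = pd.DataFrame(rows)
            _write_tsv(f3_df, out / "f3.tsv")
            report["f3"] = f3_df.to_dict(orient="records")
            event("f3", n_statistics=len(rows))

        # --- pairwise mismatch -------------------------------------------
        if toggles["mismatch"]:
            rows = []
            groups = {p: modern_f.pop_indices(p)
                      for p in sorted(set(modern_f.populations))}
            for pop, idx in groups.items():
                if len(idx) < 2:
                    continue
                est = stats.pairwise_mismatch(
                    modern_f.subset_individuals(idx), variants_f, blocks,
                    transversions_only=cfg["filters"]["transversions_only"],
                    seed=seeds["mismatch"])
                rows.append({"group": pop, **est.to_dict()})
            if ancient_calls is not None and ancient_calls.n_individuals >= 2:
                est = stats.pairwise_mismatch(
                    ancient_calls, variants_f, blocks,
                    transversions_only=cfg["filters"]["transversions_only"])
                rows.append({"group": "AncientGroup", **est.to_dict()})
            mm_df = pd.DataFrame(rows)
            _write_tsv(mm_df, out / "mismatch.tsv")
            report["mismatch"] = mm_df.to_dict(orient="records")
            event("mismatch", n_groups=len(rows))

        # --- PCA ----------------------------------------------------------
        if toggles["pca"]:
            non_out = modern_f.populations != tree.outgroup
            panel = modern_f.subset_individuals(non_out)
            panel, pvariants, pkeep = geno.filter_sites(
                panel, variants_f, cfg["filters"]["max_missing"],
                cfg["filters"]["min_maf"])
            if cfg["ld_prune"]["enabled"]:
                lp = cfg["ld_prune"]
                mask = geno.ld_prune(panel, pvariants, lp["window_snps"],
                                     lp["step_snps"], lp["r2_max"])
                panel = panel.subset_sites(mask)
                pvariants = pvariants.subset(mask)
            report["site_counts"]["pca_panel"] = int(pvariants.n_sites)
            k = int(cfg["pca"]["k"])
            model, scores = pca.fit_pca(panel, pvariants, k)
            score_df = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(k)])
            score_df.insert(0, "population", panel.populations)
            score_df.insert(0, "individual", panel.individuals)
            score_df.insert(2, "kind", "reference")
            if ancient_calls is not None:
                anc_sub = ancient_calls.subset_sites(pkeep)
                if cfg["ld_prune"]["enabled"]:
                    anc_sub = anc_sub.subset_sites(mask)
                proj = pca.project_lsq(anc_sub, model,
                                       shrink=bool(cfg["pca"]["shrink"]))
                proj_df = pd.DataFrame(proj,
                                       columns=[f"PC{i+1}" for i in range(k)])
                proj_df.insert(0, "population", anc_sub.populations)
                proj_df.insert(0, "individual", anc_sub.individuals)
                proj_df.insert(2, "kind", "projected")
                score_df = pd.concat([score_df, proj_df], ignore_index=True)
            _write_tsv(score_df, out / "pca_scores.tsv")
            report["pca"] = {"pct_variance": [float(v) for v in model.pct_variance]}
            event("pca", k=k, n_sites=int(pvariants.n_sites))

        # --- ROH -----------------------------------------------------------
        if toggles["roh"]:
            roh_geno = modern_f
            planted = cfg["roh"]["planted_segments"]
            truth_segments = {}
            if planted:
                seg_map: dict = {}
                for ind, chrom, start, end in planted:
                    seg_map.setdefault(ind, []).append((str(chrom), int(start),
                                                        int(end)))
                roh_geno, truth = simdata.plant_roh(
                    modern_f, variants_f, seg_map, _refit_freqs(modern_f),
                    seed=seeds["roh"])
                truth_segments = truth.roh_segments
            segments = roh.call_roh(roh_geno, variants_f, roh.RohParams())
            seg_df = pd.DataFrame(
                [{"individual": s.individual, "chrom": s.chrom,
                  "start": s.start, "end": s.end, "n_snps": s.n_snps,
                  "kb_length": s.kb_length} for s in segments])
            _write_tsv(seg_df, out / "roh_segments.tsv")
            report["roh"] = {"n_segments": len(segments),
                             "planted": {k: [list(t) for t in v]
                                         for k, v in truth_segments.items()}}
            event("roh", n_segments=len(segments))

        # --- continuity -----------------------------------------------------
        if toggles["continuity"] and ancient_calls is not None:
            out_idx = modern_f.pop_indices(tree.outgroup)
            if len(out_idx):
                out_row = modern_f.dosages[out_idx[0]]
                calls = {}
                for s in range(variants_f.n_sites):
                    dose = out_row[s]
                    if dose == 0:
                        calls[s] = (variants_f.allele0[s], variants_f.allele0[s])
                    elif dose == 2:
                        calls[s] = (variants_f.allele1[s], variants_f.allele1[s])
                variants_pol = geno.polarize_by_outgroup(variants_f, calls)
                target = cfg.get("continuity", {}).get("modern_population")
                if target is None:
                    non_out_pops = sorted(set(modern_f.populations)
                                          - {tree.outgroup})
                    target = non_out_pops[0]
                mod_idx = modern_f.pop_indices(target)
                cdata = build_continuity_input(
                    modern_f.subset_individuals(mod_idx), ancient_calls,
                    variants_pol)
                result = fit_continuity(cdata)
                report["continuity"] = {
                    "modern_population": target,
                    "t1": result.null.t1, "t2": result.alt.t2,
                    "loglik_null": result.null.loglik,
                    "loglik_alt": result.alt.loglik,
                    "lrt": result.lrt, "p_value": result.p_value,
                    "n_sites": result.n_sites,
                }
                with open(out / "continuity.json", "w") as fh:
                    json.dump(report["continuity"], fh, indent=2, sort_keys=True)
                event("continuity", lrt=result.lrt, p=result.p_value)

        # --- sex determination ---------------------------------------------
        if toggles["sexdet"]:
            sx = cfg["sexdet"]
            rows = []
            for i, (ind, true_sex) in enumerate(sorted(sx["sexes"].items())):
                profile = simdata.simulate_coverage_profile(
                    true_sex, float(sx["autosomal_depth"]),
                    seed=seeds["sexdet"] + i, cv=float(sx["cv"]))
                call = reads.sex_from_coverage(profile)
                rows.append({"individual": ind, "true_sex": true_sex,
                             "ratio": call.ratio, "call": call.call})
            sex_df = pd.DataFrame(rows)
            _write_tsv(sex_df, out / "sex_calls.tsv")
            report["sexdet"] = sex_df.to_dict(orient="records")
            event("sexdet", n_individuals=len(rows))

        # --- insertion genotyping ------------------------------------------
        if toggles["insgeno"]:
            ig = cfg["insgeno"]
            rows = []
            for i, (ind, carrier) in enumerate(sorted(ig["carriers"].items())):
                read_df = simdata.simulate_insertion_reads(
                    bool(carrier), int(ig["n_reads"]),
                    read_length=int(ig["read_length"]),
                    seed=seeds["insgeno"] + i)
                rp = read_df[read_df["reference_version"] == "insertion-present"]
                ra = read_df[read_df["reference_version"] == "insertion-absent"]
                call = reads.genotype_insertion(
                    rp, ra, min_overhang=int(ig["min_overhang"]),
                    max_overhang_mismatches=int(ig["max_overhang_mismatches"]))
                rows.append({"individual": ind, "true_carrier": bool(carrier),
                             "support_present": call.support_present,
                             "support_absent": call.support_absent,
                             "call": call.call,
                             "low_confidence": call.low_confidence})
            ins_df = pd.DataFrame(rows)
            _write_tsv(ins_df, out / "insertion_calls.tsv")
            report["insgeno"] = ins_df.to_dict(orient="records")
            event("insgeno", n_individuals=len(rows))

    except Exception as exc:  # preserve partial outputs + machine-readable error
        events.write(json.dumps({"stage": "error", "type": type(exc).__name__,
                                 "message": str(exc)}) + "\n")
        events.close()
        raise
    events.close()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _refit_freqs(genotypes) -> pd.DataFrame:
    """Per-population observed frequencies (fallback when the simulated
    truth frequencies no longer align with the filtered site set)."""
    from .stats import group_allele_freqs
    freq, _ = group_allele_freqs(genotypes)
    return freq.fillna(0.5)
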