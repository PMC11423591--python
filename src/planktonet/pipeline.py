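"""End-to-end orchestration: simulate or load, then run every analysis
stage per kingdom and per abundance class, writing a report bundle.

The bundle mirrors the tables a cross-kingdom community-ecology study
reports: abundance-class labels, per-sample diversity, Mantel tables,
niche-breadth summaries, neutral-model fits, assembly-process fractions,
network files with topology and node roles, and stability summaries, plus
a provenance block (config, seed, package version) so every artifact is
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import assembly as asm
from . import core_io, diversity_niche as dn, network as net, preprocess as pp
from . import stability as stab
from . import synthetic_data as sd

logger = logging.getLogger("planktonet")

DEFAULTS = {
    "seed": 0,
    "rarefaction_depth": None,
    "sum_convention": "total",
    "n_null": 999,
    "n_perm": 999,
    "correlation_method": "spearman",
    "r_min": 0.6,
    "q_max": 0.05,
    "prevalence_min": 0.5,
    "remove_fraction": 0.5,
    "robustness_reps": 100,
    "fragmentation_steps": 10,
    "classes": ["all", "abundant", "rare"],
    "assembly_classes": ["all"],
}

CI_PROFILE = {"n_null": 199, "n_perm": 499, "robustness_reps": 30}


@dataclass
class ReportBundle:
    out_dir: Path
    artifacts: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)


def validate_config(config: dict) -> dict:
    cfg = dict(DEFAULTS)
    cfg.update(config or {})
    if cfg.get("ci"):
        for k, v in CI_PROFILE.items():
            if k not in (config or {}):
                cfg[k] = v
    has_sim = "simulate" in cfg
    has_inputs = "inputs" in cfg
    if has_sim == has_inputs:
        raise ValueError("config must contain exactly one of "
                         "'simulate' or 'inputs'")
    if has_inputs:
        kingdoms = cfg["inputs"].get("kingdoms")
        if not kingdoms:
            raise ValueError("config field 'inputs.kingdoms' is missing")
        for name, paths in kingdoms.items():
            for key in ("table", "tree", "metadata"):
                if key not in paths:
                    raise ValueError(
                        f"config field 'inputs.kingdoms.{name}.{key}' "
                        "is missing")
    return cfg


def _load_kingdoms(cfg: dict) -> dict:
    """Return {kingdom: (table, tree, metadata)}."""
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        seed = sim.pop("seed", cfg["seed"])
        neutral, selection = sd.simulate_cross_kingdom_fixture(seed, **sim)
        return {"neutral_kingdom": (neutral.table, neutral.tree,
                                    neutral.metadata),
                "selection_kingdom": (selection.table, selection.tree,
                                      selection.metadata)}
    out = {}
    for name, paths in cfg["inputs"]["kingdoms"].items():
        out[name] = core_io.load_dataset(paths["table"], paths["tree"],
                                         paths["metadata"],
                                         orientation=paths.get(
                                             "orientation", "samples_rows"))
    return out


def run_pipeline(config: dict, out_dir) -> ReportBundle:
    """Execute preprocess -> partition -> diversity/niche -> assembly ->
    network -> stability for every kingdom; partial failures (e.g. an
    edgeless network) degrade to warnings, never silent omission."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out)
    seed = int(cfg["seed"])

    for kingdom, (table, tree, meta) in _load_kingdoms(cfg).items():
        kdir = out / kingdom
        kdir.mkdir(exist_ok=True)
        res: dict = {}
        table = pp.filter_features(table)
        if cfg["rarefaction_depth"]:
            table = pp.rarefy(table, int(cfg["rarefaction_depth"]), seed)
        tips = {t.name for t in tree.tips()}
        if tips - set(table.columns):
            tree = tree.shear(set(table.columns))
            tree.prune()
        labels = pp.classify_abundance_groups(
            table, sum_convention=cfg["sum_convention"])
        rel = pp.relative_abundance(table)
        pd.DataFrame({
            "class": labels,
            "mean_relabund": rel.mean(axis=0),
            "occupancy": (table > 0).mean(axis=0),
        }).to_csv(kdir / "abundance_classes.tsv", sep="\t")
        res["class_counts"] = labels.value_counts().to_dict()

        B, niche_summary = dn.levins_niche_breadth(table, labels)
        B.to_frame().join(labels).to_csv(kdir / "niche_breadth.tsv", sep="\t")
        core_io.write_json(niche_summary, kdir / "niche_breadth_summary.json")
        res["niche_breadth"] = niche_summary

        res["ncm"], res["alpha_diversity"] = {}, {}
        for cls in cfg["classes"]:
            sub = pp.subcommunity(table, labels, cls)
            if sub.shape[1] < 2 or (sub.sum(axis=1) == 0).any():
                logger.warning("%s/%s: too few features or empty samples; "
                               "class skipped", kingdom, cls)
                continue
            alpha = dn.alpha_diversity(sub, tree if cls == "all" else None)
            alpha.to_csv(kdir / f"alpha_diversity_{cls}.tsv", sep="\t")
            res["alpha_diversity"][cls] = alpha.mean(numeric_only=True).to_dict()
            fit = asm.fit_ncm(sub)
            fit.freq.to_csv(kdir / f"ncm_frequencies_{cls}.tsv", sep="\t")
            core_io.write_json(fit.summary(), kdir / f"ncm_fit_{cls}.json")
            res["ncm"][cls] = fit.summary()

        bc = dn.bray_curtis_matrix(table)
        env_vars = [c for c in core_io.METADATA_ENV_COLUMNS
                    if c in meta.columns]
        mantel = dn.mantel_table(bc, meta, env_vars,
                                 n_perm=int(cfg["n_perm"]),
                                 method=cfg["correlation_method"], seed=seed)
        mantel.to_csv(kdir / "mantel.tsv", sep="\t")
        res["mantel"] = mantel["r"].to_dict()

        res["assembly"] = {}
        for cls in cfg["assembly_classes"]:
            sub = pp.subcommunity(table, labels, cls)
            if sub.shape[1] < 3 or (sub.sum(axis=1) == 0).any():
                logger.warning("%s/%s: assembly skipped", kingdom, cls)
                continue
            ses = asm.ses_mntd(sub, tree, n_null=int(cfg["n_null"]),
                               seed=seed)
            ses.to_csv(kdir / f"ses_mntd_{cls}.tsv", sep="\t")
            bnti = asm.beta_nti(sub, tree, n_null=int(cfg["n_null"]),
                                seed=seed)
            bnti.to_csv(kdir / f"bnti_{cls}.tsv", sep="\t")
            rc = asm.raup_crick_bray(sub, n_null=int(cfg["n_null"]),
                                     seed=seed)
            rc.to_csv(kdir / f"rcbray_{cls}.tsv", sep="\t")
            result = asm.classify_assembly(bnti, rc)
            result.seed = seed
            core_io.write_json(result.fractions,
                               kdir / f"process_fractions_{cls}.json")
            res["assembly"][cls] = result.fractions

        try:
            g = net.build_network(
                table, prevalence_min=float(cfg["prevalence_min"]),
                method=cfg["correlation_method"], r_min=float(cfg["r_min"]),
                q_max=float(cfg["q_max"]))
            if g.number_of_edges() == 0:
                raise ValueError("network has no edges at these thresholds")
            net.detect_modules(g, seed=seed)
            topo = net.topology_summary(g)
            metrics = net.node_metrics(g)
            core_io.write_network(g, kdir / "network.graphml")
            core_io.write_network(g, kdir / "network_edges.tsv",
                                  format="edge_list_tsv")
            metrics.to_csv(kdir / "node_metrics.tsv", sep="\t")
            core_io.write_json(topo.to_dict(), kdir / "topology.json")
            res["topology"] = topo.to_dict()
            stab_res = stab.stability_analysis(
                g, metrics, remove_fraction=float(cfg["remove_fraction"]),
                reps=int(cfg["robustness_reps"]),
                n_steps=int(cfg["fragmentation_steps"]), seed=seed)
            stab_res.fragmentation_series.to_csv(
                kdir / "fragmentation.tsv", sep="\t", index=False)
            core_io.write_json(stab_res.summary(), kdir / "stability.json")
            res["stability"] = stab_res.summary()
        except ValueError as exc:
            logger.warning("%s: network/stability stage degraded: %s",
                           kingdom, exc)
            res["topology"] = None

        bundle.results[kingdom] = res

    provenance = {"config": {k: v for k, v in cfg.items()},
                  "seed": seed, "version": __version__}
    core_io.write_json(provenance, out / "provenance.json")
    bundle.artifacts = {p.name: str(p) for p in sorted(out.rglob("*"))
                        if p.is_file()}
    return bundle
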