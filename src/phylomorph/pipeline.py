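"""End-to-end analysis pipeline driven by a YAML config.

Order of operations mirrors the full study design: GPA -> species means ->
PCA + broken stick -> phylomorphospace -> phylogenetic signal -> convergence
-> disparity through time -> modularity / integration model comparison ->
evolutionary rates.  Subgroups (e.g. subfamilies) with at least five species
rerun the model comparison on species means from the joint superimposition;
smaller subgroups are skipped with a logged warning.  All randomness flows
from the single config seed through numpy's SeedSequence spawning, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gpa import gpa_align, species_mean_shapes
from .io import (DEFAULT_SPECIES_REGEX, match_taxa, read_landmarks,
                 read_module_map, read_tree, write_landmarks)
from .macro import (convergence_c_metrics, convnum_ellipse, detect_bursts,
                    disparity_through_time)
from .modularity import (compare_cr_models, default_battery, emmli_fit,
                         integration_test, modularity_test)
from .ordination import broken_stick_axes, pca_shapes, phylomorphospace
from .phylo import kmult
from .plotting import (module_network_json, module_network_svg, plot_dtt,
                       plot_phylomorphospace)
from .rates import module_rate_ratio_test, multirate_bm

log = logging.getLogger("phylomorph")

__all__ = ["AnalysisConfig", "run_pipeline"]


@dataclass
class AnalysisConfig:
    landmarks: str
    tree: str
    module_map: str
    output_dir: str
    seed: int
    landmark_format: str = "tps"
    n_perm: int = 1000
    species_regex: str = DEFAULT_SPECIES_REGEX
    species_table: str | None = None
    subgroups: str | None = None          # CSV: species,group
    focal_taxa: list[str] = field(default_factory=list)
    n_slices: int = 31
    burst_threshold: float = 10.0
    min_subgroup_species: int = 5
    multirate_lambda: float = 1.0
    plots: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is required")
        if self.n_perm < 100:
            raise ValueError(f"n_perm={self.n_perm} refused: permutation "
                             "tests need at least 100 iterations")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns a manifest of produced files."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    log.setLevel(logging.INFO)

    specimens = read_landmarks(config.landmarks, config.landmark_format,
                               species_regex=config.species_regex,
                               species_table=config.species_table)
    tree = read_tree(config.tree)
    module_map = read_module_map(config.module_map)
    battery = default_battery(module_map) if module_map.n_modules == 7 else None

    aligned = gpa_align(specimens)
    means = species_mean_shapes(aligned)
    means, tree, report = match_taxa(means, tree)
    log.info("taxon matching dropped %s (shapes) / %s (tree)",
             report.dropped_from_shapes, report.dropped_from_tree)
    d = means.d

    write_landmarks(
        [type(specimens[0])(sid, sp, c) for sid, sp, c in
         zip(means.specimen_ids, means.species, means.coords)],
        out / "species_means.csv", format="table")

    groups: dict[str, list[str]] = {"all": list(means.species)}
    if config.subgroups:
        sub = pd.read_csv(config.subgroups)
        cols = {c.lower(): c for c in sub.columns}
        for g, block in sub.groupby(cols["group"]):
            sp = [s for s in block[cols["species"]] if s in means.species]
            if len(sp) < config.min_subgroup_species:
                log.warning("subgroup %s skipped: %d species < %d",
                            g, len(sp), config.min_subgroup_species)
                continue
            groups[str(g)] = sp

    manifest = {"version": __version__, "seed": config.seed, "groups": {},
                "n_perm": config.n_perm}
    for group, species in groups.items():
        gdir = out / group
        gdir.mkdir(exist_ok=True)
        gm = means.subset_species(sorted(species))
        gtree = tree if group == "all" else tree.prune(species)
        gm = gm.subset_species(gtree.tip_labels)
        group_seed = (config.seed if group == "all"
                      else config.seed + (zlib.crc32(group.encode()) % 100000) + 1)
        rngs = _rngs(group_seed, 8)
        manifest["groups"][group] = _run_group(
            gm, gtree, module_map, battery, config, gdir, rngs, d)
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, default=str)
    log.removeHandler(fh)
    return manifest


def _run_group(means, tree, module_map, battery, config, gdir, rngs, d) -> dict:
    files = {}
    X = means.flattened()
    taxa = means.species

    space = pca_shapes(means)
    n_sig = broken_stick_axes(space.proportion)
    pd.DataFrame(space.scores, index=space.species,
                 columns=[f"PC{i+1}" for i in range(space.n_axes)]
                 ).to_csv(gdir / "scores.csv")
    pd.DataFrame({"eigenvalue": space.eigenvalues,
                  "proportion": space.proportion}).to_csv(
        gdir / "eigenvalues.csv", index=False)
    files["scores"] = "scores.csv"

    sig = kmult(X, tree, n_perm=config.n_perm, rng=rngs[0], taxa=taxa)
    with open(gdir / "signal.json", "w") as f:
        json.dump({"K": sig.K, "p": sig.p, "n_perm": sig.n_perm,
                   "significant_axes": int(n_sig)}, f, indent=1)
    files["signal"] = "signal.json"

    mod = modularity_test(X, module_map, tree, n_perm=config.n_perm,
                          d=d, rng=rngs[1], taxa=taxa)
    mod.pairwise.to_csv(gdir / "cr_pairwise.csv")
    integ = integration_test(X, module_map, tree, n_perm=config.n_perm,
                             d=d, rng=rngs[2], taxa=taxa)
    integ.pairwise_rpls.to_csv(gdir / "rpls_pairwise.csv")
    integ.pairwise_p.to_csv(gdir / "rpls_pairwise_p.csv")
    summary = {"CR": mod.cr, "CR_p": mod.p, "CR_z": mod.effect_size_z,
               "rPLS": integ.rpls, "rPLS_p": integ.p}

    if battery is not None:
        table = compare_cr_models(X, battery, tree, n_perm=config.n_perm,
                                  d=d, rng=rngs[3], taxa=taxa)
        table.to_csv(gdir / "cr_models.csv", index=False)
        dev = (np.asarray(means.coords) -
               means.coords.mean(axis=0, keepdims=True))
        em = emmli_fit(dev, battery, sample_size=means.n)
        em.table.to_csv(gdir / "emmli.csv", index=False)
        summary["best_cr_model"] = table.loc[0, "model"]
        summary["best_emmli_model"] = em.best_model
        files["models"] = "cr_models.csv"

    rate = module_rate_ratio_test(X, module_map, tree, n_sim=config.n_perm,
                                  d=d, rng=rngs[4], taxa=taxa)
    with open(gdir / "rates.json", "w") as f:
        json.dump({"sigma2": rate.sigma2_per_module, "ratio": rate.ratio,
                   "p": rate.p}, f, indent=1)
    files["rates"] = "rates.json"

    rows = []
    for axis in range(min(n_sig, space.n_axes) or 1):
        mr = multirate_bm(space.scores[:, axis], tree,
                          lam=config.multirate_lambda, taxa=space.species)
        tip_rates = {tree.labels[t]: float(mr.rates[t])
                     for t in tree.tip_indices}
        rows.append({"axis": f"PC{axis+1}", "single_rate": mr.single_rate,
                     **tip_rates})
    pd.DataFrame(rows).to_csv(gdir / "multirate_bm.csv", index=False)

    if tree.is_ultrametric():
        profiles = disparity_through_time(space.scores[:, :max(n_sig, 1)],
                                          tree, n_slices=config.n_slices,
                                          taxa=space.species)
        for prof in profiles.values():
            detect_bursts(prof, config.burst_threshold)
        recs = [{"clade": p.clade, "time": t, "disparity": v,
                 "burst": any(i2 == j for _, j, _ in p.bursts)}
                for p in profiles.values()
                for j, (t, v) in enumerate(zip(p.times, p.disparity))
                for i2 in [j]]
        pd.DataFrame(recs).to_csv(gdir / "disparity.csv", index=False)
        files["disparity"] = "disparity.csv"
        if config.plots:
            plot_dtt(profiles, gdir / "dtt.png")

    focal = [t for t in config.focal_taxa if t in tree.tip_labels]
    if len(focal) >= 2:
        conv = convergence_c_metrics(space.scores[:, :max(n_sig, 2)], tree,
                                     focal, n_sim=config.n_perm, rng=rngs[5],
                                     taxa=space.species)
        result = {"C1": conv.c1, "C2": conv.c2, "C3": conv.c3, "C4": conv.c4,
                  "p": conv.p}
        if len(focal) >= 3:
            cross = convnum_ellipse(space.scores[:, :2], tree, focal,
                                    taxa=space.species)
            result["ellipse_crossings"] = cross.count
            result["ellipse_crossings_nonfocal"] = cross.count_nonfocal
            result["ellipse_area"] = cross.area
        with open(gdir / "convergence.json", "w") as f:
            json.dump(result, f, indent=1)
        files["convergence"] = "convergence.json"

    net = module_network_json(mod.pairwise, integ.pairwise_rpls,
                              gdir / "module_network.json")
    module_network_svg(net, gdir / "module_network.svg")
    if config.plots:
        pm = phylomorphospace(space, tree)
        plot_phylomorphospace(pm, gdir / "phylomorphospace.png")

    with open(gdir / "summary.json", "w") as f:
        json.dump(summary, f, indent=1)
    files["summary"] = "summary.json"
    return files
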