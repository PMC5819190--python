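"""End-to-end study orchestration with a reproducible run manifest.

A study runs some or all of: simulate (or ingest) proteomes → mine
peptidases → profile statistics (ANOSIM / SIMPER on the count matrix) →
composition comparison → hallmark partition → structure metrics. Every
stage is a pure function of (inputs, config, seed); the manifest records
versions, seeds, parameters and input checksums so any report can be
reproduced from it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import compare_groups, profiles_table, species_profile
from .datasets import MESOPHILIC, THERMOPHILIC, load_peptidase_counts
from .hallmarks import filter_functional, write_partition
from .matrix import CountMatrix
from .mining import MiningParams, annotations_table, build_kmer_index, classify_proteome, profile_species
from .stats import anosim, kruskal_wallis, matrix_distances, simper
from .synthetic import (
    THERMOPHILIC_SHIFT,
    ProteomeRegime,
    derive_seed,
    make_hallmark_set,
    make_proteome,
    make_reference_library,
    make_structure,
)
from .structure import count_cavities

log = logging.getLogger("thermopep")

ALL_STAGES = ("simulate", "mine", "profile-stats", "compstats", "hallmark", "struct")


@dataclass
class StudyConfig:
    """Validated configuration of one study run."""

    out_dir: str = "results/study"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 42
    # statistics settings
    metric: str = "braycurtis"
    relativize: bool = False
    n_perm: int = 9999
    alpha: float = 0.05
    group_pair: tuple[str, str] = (MESOPHILIC, THERMOPHILIC)
    # inputs: None -> synthetic / packaged defaults
    count_matrix_tsv: str | None = None
    # synthetic study shape
    n_species_per_group: int = 4
    n_proteins: int = 120
    peptidase_fraction: float = 0.1
    mutation_rate: float = 0.1
    shift: dict[str, float] = field(default_factory=lambda: dict(THERMOPHILIC_SHIFT))
    reference_families: list = field(default_factory=lambda: [
        ("A01", "A", 4, 350), ("S08", "S", 4, 400), ("M12", "M", 4, 300),
    ])
    n_structures_per_group: int = 3
    cavity_means: tuple[float, float] = (6.0, 4.0)
    hallmark_n_pos: int = 20
    hallmark_n_neg: int = 20

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.metric not in ("braycurtis", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.n_perm < 1 or self.seed < 0:
            raise ValueError("n_perm must be >= 1 and seed >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("stages", "group_pair", "cavity_means"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        cfg.reference_families = [tuple(f) for f in cfg.reference_families]
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_matrix(config: StudyConfig) -> tuple[CountMatrix, str]:
    if config.count_matrix_tsv:
        return CountMatrix.from_tsv(config.count_matrix_tsv), config.count_matrix_tsv
    return load_peptidase_counts(), "builtin:fungal_peptidase_counts.tsv"


def run_profile_stats(matrix: CountMatrix, config: StudyConfig, out: Path) -> dict:
    """ANOSIM + SIMPER on the two focal groups of a count matrix."""
    two = matrix.subset_groups(list(config.group_pair))
    dm = matrix_distances(two, metric=config.metric, relativize=config.relativize)
    res_a = anosim(dm, two.groups.to_numpy(), n_perm=config.n_perm, seed=config.seed)
    res_s = simper(two, config.group_pair, relativize=config.relativize)
    dm.to_frame().to_csv(out / "distance_matrix.tsv", sep="\t")
    res_s.table.to_csv(out / "simper.tsv", sep="\t", index=False)
    summary = {
        "anosim_R": res_a.R, "anosim_p": res_a.p_value,
        "anosim_n_perm": res_a.n_permutations,
        "simper_overall_percent": res_s.overall,
        "metric": config.metric, "relativize": config.relativize,
        "groups": list(config.group_pair),
        "n_units": res_a.n_units,
    }
    (out / "profile_stats.json").write_text(json.dumps(summary, indent=2))
    log.info("ANOSIM R=%.4f P=%.4g; SIMPER overall=%.2f%%",
             res_a.R, res_a.p_value, res_s.overall)
    return summary


def run_study(config: StudyConfig) -> dict:
    """Execute the configured stages and return the report summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = config.seed
    report: dict = {"stages": {}}
    manifest: dict = {
        "version": __version__, "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "out_dir"},
        "inputs": {},
    }

    reference = proteomes = truths = None
    if "simulate" in config.stages:
        log.info("simulate: seed=%d", rng_seed)
        reference = make_reference_library(config.reference_families,
                                           seed=derive_seed(rng_seed, 0))
        proteomes, truths = {}, {}
        for g, group in enumerate(config.group_pair):
            shift = config.shift if group == config.group_pair[1] else {}
            for i in range(config.n_species_per_group):
                sp = f"{group}_{i + 1:02d}"
                regime = ProteomeRegime(
                    n_proteins=config.n_proteins,
                    peptidase_fraction=config.peptidase_fraction,
                    mutation_rate=config.mutation_rate,
                    seed=derive_seed(rng_seed, 1000 * (g + 1) + i),
                ).with_shift(shift)
                proteomes[sp], truths[sp] = make_proteome(regime, reference, sp, group)
        truth_df = pd.concat([t.proteins for t in truths.values()], ignore_index=True)
        truth_df.to_csv(out / "simulation_truth.tsv", sep="\t", index=False)
        report["stages"]["simulate"] = {
            "n_species": len(proteomes),
            "n_proteins": int(sum(len(p) for p in proteomes.values())),
        }

    if "mine" in config.stages:
        if proteomes is None:
            raise ValueError("mine stage requires the simulate stage (or FASTA inputs via the CLI)")
        params = MiningParams()
        index = build_kmer_index(reference, k=params.k)
        annotations = []
        for sp, records in proteomes.items():
            anns, _ = classify_proteome(records, index, params)
            annotations.extend(anns)
        groups = {sp: recs[0].group for sp, recs in proteomes.items()}
        mined = profile_species(annotations, groups, level="catalytic_type")
        annotations_table(annotations).to_csv(out / "annotations.tsv", sep="\t", index=False)
        mined.to_tsv(out / "mined_counts.tsv")
        report["stages"]["mine"] = {"n_annotations": len(annotations)}

    if "profile-stats" in config.stages:
        matrix, source = _load_matrix(config)
        if config.count_matrix_tsv:
            manifest["inputs"]["count_matrix"] = {
                "path": source, "sha256": _sha256(Path(source))}
        else:
            manifest["inputs"]["count_matrix"] = {"path": source}
        report["stages"]["profile-stats"] = run_profile_stats(matrix, config, out)

    if "compstats" in config.stages:
        if proteomes is None:
            raise ValueError("compstats stage requires the simulate stage (or FASTA inputs via the CLI)")
        profiles = profiles_table([
            species_profile(records, sp) for sp, records in proteomes.items()])
        groups = pd.Series({sp: recs[0].group for sp, recs in proteomes.items()})
        table = compare_groups(profiles, groups,
                               (config.group_pair[1], config.group_pair[0]),
                               alpha=config.alpha)
        table.to_csv(out / "composition_tests.tsv", sep="\t", index=False)
        sig = table[table["direction"] != "ns"]
        report["stages"]["compstats"] = {
            "n_significant": int(len(sig)),
            "increased": sorted(sig.loc[sig["direction"] == "+", "variable"]),
            "decreased": sorted(sig.loc[sig["direction"] == "-", "variable"]),
        }

    if "hallmark" in config.stages:
        records, truth = make_hallmark_set(config.hallmark_n_pos,
                                           config.hallmark_n_neg, seed=rng_seed)
        functional, nonfunctional, rep = filter_functional(records)
        write_partition(functional, nonfunctional, rep, out / "hallmark")
        report["stages"]["hallmark"] = {
            "n_functional": len(functional), "n_non_functional": len(nonfunctional)}

    if "struct" in config.stages:
        rng = np.random.default_rng(rng_seed)
        counts_by_group: dict[str, list[int]] = {}
        for mean, group in zip(config.cavity_means, config.group_pair):
            ks = rng.poisson(mean, config.n_structures_per_group)
            got = []
            for j, k in enumerate(ks):
                model, _ = make_structure(int(min(k, 4)), seed=rng_seed + j,
                                          source_id=f"{group}_{j}")
                got.append(count_cavities(model).n_cavities)
            counts_by_group[group] = got
        kw = kruskal_wallis(list(counts_by_group.values()))
        report["stages"]["struct"] = {
            "cavity_counts": counts_by_group, "kw_H": kw.H, "kw_p_chi2": kw.p_chi2}

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return report
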