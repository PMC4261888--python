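"""End-to-end pipeline: simulate/load -> QC -> pairwise LD -> decay -> phase.

A run is configured by a single :class:`RunConfig` (mirroring a YAML file),
executes the stages in order, writes every result table as TSV with
unit-bearing headers, and records a JSON manifest (config echo, version,
per-stage row counts, wall-clock, seed trail) sufficient to reproduce the
outputs exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import GenotypeMatrix, MarkerMap
from .decay import DecayDataset, bin_summary, equality_test, fit_sved, pairwise_equality
from .errors import ConfigurationError, LdphaseError
from .io import (
    read_genotype_tsv,
    read_marker_map,
    read_vcf,
    write_genotype_tsv,
    write_marker_map,
    write_vcf,
)
from .ld import pair_ld_table
from .persistence import align_pairs, evaluate_bin_widths, persistence_curve
from .qc import intersect_markers, run_qc
from .sim import SimConfig, default_scenario, scenario_from_dict, simulate_scenario

__all__ = ["RunConfig", "run"]

# Group definitions for phase comparisons: the F1 against its parent dam
# lines; each terminal cross against its parental and grandparental lines;
# and all pure lines against each other.
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "group1": ("DLF1", "DL1", "DL2"),
    "group2": ("TER1", "SL1", "DLF1", "DL1", "DL2"),
    "group3": ("TER2", "SL2", "DLF1", "DL1", "DL2"),
    "group4": ("SL1", "SL2", "SL3", "DL1", "DL2"),
}

TABLE3_BINS = ((0, 50), (200, 250), (500, 550), (1000, 1050), (2000, 2050), (3000, 3050))


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    out_dir: str
    mode: str = "simulate"  # or "load"
    seed: int = 2014
    sim: SimConfig | None = None  # default_scenario(seed) when None
    load_dir: str | None = None  # directory of VCFs (load mode)
    populations: tuple[str, ...] | None = None  # load mode: which VCF stems
    excluded_chroms: tuple[str, ...] = ("X",)
    call_rate_min: float = 0.90
    maf_min: float = 0.05
    hwe_p_min: float = 1e-4
    max_distance_kb: float = 5000.0
    predict_distances: tuple[float, ...] = (50, 250, 500, 1000, 2000, 3000)
    bin_width_kb: float = 50.0
    persistence_max_kb: float = 5000.0
    groups: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    alpha: float = 0.05

    def validate(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ConfigurationError("mode must be 'simulate' or 'load'")
        if self.mode == "load" and not self.load_dir:
            raise ConfigurationError("load mode requires load_dir")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.bin_width_kb <= 0 or self.persistence_max_kb <= 0:
            raise ConfigurationError("bin_width_kb and persistence_max_kb must be > 0")
        if self.max_distance_kb <= 0:
            raise ConfigurationError("max_distance_kb must be > 0")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("sim", None)
        if sim is not None:
            sim = scenario_from_dict(sim)
        groups = raw.pop("groups", None)
        cfg = cls(sim=sim, **raw)
        if groups is not None:
            cfg.groups = {k: tuple(v) for k, v in groups.items()}
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_genotypes(config: RunConfig) -> tuple[dict[str, GenotypeMatrix], MarkerMap]:
    load_dir = Path(config.load_dir)
    vcfs = sorted(load_dir.glob("*.vcf"))
    if config.populations:
        vcfs = [load_dir / f"{p}.vcf" for p in config.populations]
    if not vcfs:
        raise ConfigurationError(f"no VCF files found in {load_dir}")
    genotypes: dict[str, GenotypeMatrix] = {}
    marker_map: MarkerMap | None = None
    for path in vcfs:
        g, vmap = read_vcf(path)
        genotypes[g.population] = g
        marker_map = vmap if marker_map is None else marker_map
    map_path = load_dir / "marker_map.tsv"
    if map_path.exists():
        marker_map = read_marker_map(map_path)
    return genotypes, marker_map


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "stages": {},
    }
    t_all = time.perf_counter()

    def stage(name: str):
        return _StageTimer(manifest, name)

    try:
        # --- genotypes -----------------------------------------------------
        with stage("genotypes") as st:
            if config.mode == "simulate":
                sim = config.sim or default_scenario(config.seed)
                genotypes, marker_map, seed_log = simulate_scenario(sim)
                manifest["seed_trail"] = seed_log
                geno_dir = out / "genotypes"
                geno_dir.mkdir(exist_ok=True)
                write_marker_map(marker_map, geno_dir / "marker_map.tsv")
                for name, g in genotypes.items():
                    write_vcf(g, marker_map, geno_dir / f"{name}.vcf")
                    write_genotype_tsv(g, geno_dir / f"{name}.tsv")
            else:
                genotypes, marker_map = _load_genotypes(config)
            st.counts = {name: g.n_samples for name, g in genotypes.items()}
            st.counts["n_snps"] = len(marker_map)

        # --- QC ------------------------------------------------------------
        with stage("qc") as st:
            qcd: dict[str, GenotypeMatrix] = {}
            reports = []
            for name, g in genotypes.items():
                filtered, report = run_qc(
                    g,
                    marker_map,
                    excluded_chroms=config.excluded_chroms,
                    call_rate_min=config.call_rate_min,
                    maf_min=config.maf_min,
                    hwe_p_min=config.hwe_p_min,
                )
                qcd[name] = filtered
                reports.append(report.to_frame())
            qc_frame = pd.concat(reports, ignore_index=True)
            qc_frame.to_csv(out / "qc_report.tsv", sep="\t", index=False)
            st.counts = {
                row["population"]: int(row["n_retained"])
                for _, row in qc_frame.iterrows()
            }

        # --- pairwise LD on the all-population intersection ----------------
        with stage("ld") as st:
            common = intersect_markers(list(qcd.values()))
            ld_dir = out / "ld"
            ld_dir.mkdir(exist_ok=True)
            pair_tables: dict[str, pd.DataFrame] = {}
            for g in common:
                table = pair_ld_table(g, marker_map, config.max_distance_kb)
                table.to_csv(ld_dir / f"{g.population}_pairs.tsv", sep="\t", index=False)
                pair_tables[g.population] = table
            st.counts = {name: len(t) for name, t in pair_tables.items()}
            st.counts["n_common_snps"] = common[0].n_snps

        # --- decay model ----------------------------------------------------
        with stage("decay") as st:
            decay_dir = out / "decay"
            decay_dir.mkdir(exist_ok=True)
            data = DecayDataset.from_pairs(list(pair_tables.values()))
            fit = fit_sved(data)
            coef = fit.to_frame()
            coef.to_csv(decay_dir / "decay_coefficients.tsv", sep="\t", index=False)
            predicted = pd.DataFrame(
                {
                    "line": coef["line"],
                    **{
                        f"r2_at_{int(d)}kb": [
                            fit.predict(line, d) for line in coef["line"]
                        ]
                        for d in config.predict_distances
                    },
                }
            )
            predicted.to_csv(decay_dir / "predicted_r2.tsv", sep="\t", index=False)
            binned = pd.concat(
                [
                    bin_summary(t, TABLE3_BINS).assign(line=name)
                    for name, t in pair_tables.items()
                ],
                ignore_index=True,
            )
            binned.to_csv(decay_dir / "binned_r2.tsv", sep="\t", index=False)
            overall = equality_test(data)
            pairwise = pairwise_equality(data, alpha=config.alpha)
            pairwise.to_csv(decay_dir / "pairwise_tests.tsv", sep="\t", index=False)
            manifest["decay"] = {
                "n_records": data.n_records,
                "overall_chi2": overall.chi2,
                "overall_df": overall.df,
                "overall_p_value": overall.p_value,
                "n_pairwise_tests": pairwise.attrs["n_tests"],
                "bonferroni_alpha_star": pairwise.attrs["alpha_star"],
                "n_pairwise_significant": int(pairwise["significant"].sum()),
            }
            st.counts = {"n_records": data.n_records, "n_lines": len(coef)}

        # --- persistence of phase -------------------------------------------
        with stage("persistence") as st:
            pers_dir = out / "persistence"
            pers_dir.mkdir(exist_ok=True)
            n_curves = 0
            for group_name, members in config.groups.items():
                members = [m for m in members if m in qcd]
                if len(members) < 2:
                    continue
                gdir = pers_dir / group_name
                gdir.mkdir(exist_ok=True)
                g_common = intersect_markers([qcd[m] for m in members])
                g_tables = {
                    g.population: pair_ld_table(g, marker_map, config.persistence_max_kb)
                    for g in g_common
                }
                # every unordered pair within the group shares the group's
                # marker intersection
                joined_any = None
                comparisons = [
                    (a, b) for i, a in enumerate(members) for b in members[i + 1:]
                ]
                for a, b in comparisons:
                    joined = align_pairs(g_tables[a], g_tables[b])
                    curve = persistence_curve(
                        joined, config.bin_width_kb, config.persistence_max_kb
                    )
                    curve.to_csv(gdir / f"{a}_vs_{b}.tsv", sep="\t", index=False)
                    joined_any = joined
                    n_curves += 1
                if joined_any is not None:
                    cv = evaluate_bin_widths(joined_any, max_kb=config.persistence_max_kb)
                    cv.to_csv(gdir / "cv_bin_widths.tsv", sep="\t", index=False)
            st.counts = {"n_curves": n_curves}
    except LdphaseError as exc:
        manifest["failed_stage"] = getattr(exc, "_stage", "unknown")
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    manifest["wall_clock_s"] = round(time.perf_counter() - t_all, 3)
    manifest["config"] = _config_echo(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _config_echo(config: RunConfig) -> dict:
    echo = {k: v for k, v in vars(config).items() if k != "sim"}
    echo["groups"] = {k: list(v) for k, v in config.groups.items()}
    if config.sim is not None:
        echo["sim"] = {
            **{
                k: v
                for k, v in vars(config.sim).items()
                if k != "lines"
            },
            "lines": [vars(spec) for spec in config.sim.lines],
        }
    return json.loads(json.dumps(echo, default=str))


class _StageTimer:
    """Context manager recording wall-clock and row counts per stage."""

    def __init__(self, manifest: dict, name: str) -> None:
        self.manifest = manifest
        self.name = name
        self.counts: dict = {}

    def __enter__(self) -> "_StageTimer":
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc is not None and isinstance(exc, LdphaseError):
            exc._stage = self.name
            return
        self.manifest["stages"][self.name] = {
            "wall_clock_s": round(time.perf_counter() - self.t0, 3),
            "counts": self.counts,
        }
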