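"""Declarative run configuration and end-to-end pipeline orchestration.

A single YAML file declares either real inputs (a protein-groups table
plus gene-set files) or a synthetic study, the sector scheme, the
balance groups, growth/R-line inputs and the model parameters. A run
executes allocate -> sectorize -> balance -> growth fits -> R-line ->
model and writes deterministic artifacts (tidy CSV + JSON + a run log
with input checksums and the seed); identical config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import allocation, growth_model, io, physiology, synthetic
from .errors import ConfigError, ProteoallocError


@dataclass
class RunConfig:
    """Parsed run configuration; see :func:`default_demo_config` for shape."""

    seed: int = 0
    output_dir: Path = Path("results/run")
    proteome: dict = field(default_factory=dict)
    balance: dict = field(default_factory=dict)
    growth: dict = field(default_factory=dict)
    rline: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        issues = validate_config(data)
        if issues:
            raise ConfigError("invalid run config: " + "; ".join(issues))
        return cls(
            seed=int(data.get("seed", 0)),
            output_dir=Path(data.get("output_dir", "results/run")),
            proteome=dict(data.get("proteome", {})),
            balance=dict(data.get("balance", {})),
            growth=dict(data.get("growth", {})),
            rline=dict(data.get("rline", {})),
            model=dict(data.get("model", {})),
            log_level=str(data.get("log_level", "INFO")),
            raw=dict(data),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)


def default_demo_config() -> dict:
    """The self-contained demo: synthetic study contrast + growth + model."""
    return {
        "seed": 0,
        "output_dir": "results/demo",
        "proteome": {
            "synthetic": {"noise_cv": 0.05, "n_replicates": 3, "contrast": True}
        },
        "balance": {
            "increase": ["aa_biosynthesis", "motility"],
            "decrease": ["translation", "nt_biosynthesis"],
        },
        "growth": {
            "synthetic": {
                "rates": dict(synthetic.STUDY_GROWTH_RATES),
                "downshift": {
                    "lambda_post": synthetic.STUDY_GROWTH_RATES["glucose_min"],
                    "lags": dict(synthetic.STUDY_LAG_TIMES),
                },
                "noise_cv": 0.02,
            }
        },
        "rline": {"synthetic": {"slope": 0.10, "intercept": 0.08, "noise_sd": 0.004, "n": 10}},
        "model": {"phi_Q": 0.45, "gamma": 10.0, "nu": 2.0, "phi_U": 0.0, "phi_R0": 0.0},
    }


def validate_config(data: Any) -> list[str]:
    """List every problem in a raw config mapping without running it.

    Never raises on content problems — fuzzed input yields a report.
    """
    issues: list[str] = []
    if not isinstance(data, Mapping):
        return [f"config must be a mapping, got {type(data).__name__}"]
    known = {"seed", "output_dir", "proteome", "balance", "growth", "rline", "model", "log_level"}
    for key in data:
        if key not in known:
            issues.append(f"unknown top-level section {key!r}")
    seed = data.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        issues.append("seed must be an integer")

    prot = data.get("proteome", {})
    if not isinstance(prot, Mapping):
        issues.append("proteome section must be a mapping")
    else:
        has_syn = "synthetic" in prot
        has_real = "inputs" in prot
        if has_syn and has_real:
            issues.append("proteome: supply exactly one of 'synthetic' or 'inputs', not both")
        if has_real:
            inputs = prot["inputs"]
            if not isinstance(inputs, Mapping):
                issues.append("proteome.inputs must be a mapping")
            else:
                if "protein_groups" not in inputs:
                    issues.append("proteome.inputs.protein_groups is required")
                gene_sets = inputs.get("gene_sets")
                if not isinstance(gene_sets, Mapping) or not gene_sets:
                    issues.append("proteome.inputs.gene_sets must map sector names to files")
        if has_syn and not isinstance(prot["synthetic"], Mapping):
            issues.append("proteome.synthetic must be a mapping")

    bal = data.get("balance", {})
    if not isinstance(bal, Mapping):
        issues.append("balance section must be a mapping")
    else:
        for group in ("increase", "decrease"):
            if group in bal and not isinstance(bal[group], (list, tuple)):
                issues.append(f"balance.{group} must be a list of sector names")

    model = data.get("model", {})
    if not isinstance(model, Mapping):
        issues.append("model section must be a mapping")
    else:
        for key in ("phi_Q", "gamma", "nu", "phi_U", "phi_R0"):
            if key in model and not isinstance(model[key], (int, float)):
                issues.append(f"model.{key} must be a number")
        if all(k in model for k in ("phi_Q", "gamma", "nu")):
            try:
                growth_model.AllocationModel(
                    phi_Q=float(model["phi_Q"]), gamma=float(model["gamma"]),
                    nu=float(model["nu"]), phi_U=float(model.get("phi_U", 0.0)),
                    phi_R0=float(model.get("phi_R0", 0.0)),
                )
            except (ProteoallocError, TypeError, ValueError) as exc:
                issues.append(f"model parameters invalid: {exc}")

    for section in ("growth", "rline"):
        sec = data.get(section, {})
        if not isinstance(sec, Mapping):
            issues.append(f"{section} section must be a mapping")
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageLog:
    """Deterministic plain-text run log (no wall-clock content)."""

    def __init__(self) -> None:
        self.lines: list[str] = []
        self.n_warnings = 0

    def info(self, msg: str) -> None:
        self.lines.append(msg)

    def warning(self, msg: str) -> None:
        self.n_warnings += 1
        self.lines.append(f"WARNING: {msg}")

    def write(self, path: Path) -> None:
        body = "\n".join(self.lines + [f"warnings: {self.n_warnings}"]) + "\n"
        path.write_text(body, encoding="utf-8")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ProteoallocError as exc:
                raise ConfigError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("proteome")
def _proteome_stage(cfg: RunConfig, log: _StageLog):
    prot = cfg.proteome
    if "synthetic" in prot or not prot:
        syn = dict(prot.get("synthetic", {}))
        contrast = bool(syn.pop("contrast", True))
        syn.setdefault("seed", cfg.seed)
        sconf = synthetic.SyntheticConfig(**syn)
        log.info(f"proteome: synthetic study (seed={sconf.seed}, cv={sconf.noise_cv}, "
                 f"replicates={sconf.n_replicates}, contrast={contrast})")
        proteome = (
            synthetic.generate_condition_contrast(sconf)
            if contrast else synthetic.generate_proteome(sconf)
        )
        return proteome.records, proteome.samples, proteome.gene_sets, proteome.truth
    inputs = prot["inputs"]
    pg_path = Path(inputs["protein_groups"])
    table = io.read_protein_groups(pg_path, inputs.get("column_map"))
    log.info(f"proteome: {pg_path} sha256={_sha256(pg_path)}")
    log.info(f"  retained={len(table.records)} contaminants={table.n_contaminants} "
             f"invalid_mw={table.n_invalid_mw}")
    gene_sets: dict[str, io.SectorDefinition] = {}
    for name, path in inputs["gene_sets"].items():
        gene_sets[name] = io.read_gene_set(path, name=name, mode=io.SectorMode.partition_member)
        log.info(f"  gene set {name}: {path} sha256={_sha256(Path(path))}")
    for name, path in inputs.get("overlays", {}).items():
        gene_sets[name] = io.read_gene_set(path, name=name, mode=io.SectorMode.overlay)
        log.info(f"  overlay {name}: {path} sha256={_sha256(Path(path))}")
    return table.records, table.samples, gene_sets, None


@_stage("allocate")
def _allocate_stage(records, samples, log: _StageLog):
    allocs = []
    for d in samples:
        alloc = allocation.compute_mass_fractions(records, d.sample_id)
        if alloc.n_missing:
            log.warning(f"sample {d.sample_id}: {alloc.n_missing} missing intensities set to 0")
        allocs.append(alloc)
    log.info(f"allocate: {len(allocs)} samples normalized")
    return allocs


@_stage("sectors")
def _sector_stage(allocs, samples, gene_sets, log: _StageLog):
    # a gene set named like the implicit remainder is exactly the remainder:
    # leave it out and let partition closure account for it
    partition = tuple(s for s in gene_sets.values()
                      if s.mode == io.SectorMode.partition_member
                      and s.name != allocation.OTHER_SECTOR)
    overlays = tuple(s for s in gene_sets.values() if s.mode == io.SectorMode.overlay)
    scheme = allocation.SectorScheme(partition=partition, overlays=overlays)
    table = allocation.aggregate_replicates(allocs, samples, scheme)
    log.info(f"sectors: {len(partition)} partition sectors (+other), {len(overlays)} overlays")
    return scheme, table


@_stage("balance")
def _balance_stage(cfg: RunConfig, table, scheme, samples, log: _StageLog):
    # wild type is the reference condition A; contrasts are read as A -> B
    conditions = sorted({(d.strain.value, d.medium) for d in samples},
                        key=lambda sm: (sm[0] != "wild_type", sm))
    if len(conditions) < 2:
        log.info("balance: single condition, skipped")
        return None
    (strain_a, medium_a), (strain_b, medium_b) = conditions[0], conditions[1]
    part_names = scheme.partition_names
    fa = {s: v for s, v in allocation.condition_slice(table, strain_a, medium_a).items()
          if s in part_names}
    fb = {s: v for s, v in allocation.condition_slice(table, strain_b, medium_b).items()
          if s in part_names}
    increase = list(cfg.balance.get("increase", []))
    decrease = list(cfg.balance.get("decrease", []))
    if not increase or not decrease:
        log.info("balance: no increase/decrease groups configured, skipped")
        return None
    report = allocation.balance_analysis(
        fa, fb, increase, decrease,
        condition_a=f"{strain_a}/{medium_a}", condition_b=f"{strain_b}/{medium_b}",
    )
    log.info(f"balance: {report.condition_a} -> {report.condition_b} "
             f"increase={report.increase_total:.4f} decrease={report.decrease_total:.4f} "
             f"residual={report.residual:.4f}")
    return report


@_stage("growth")
def _growth_stage(cfg: RunConfig, log: _StageLog):
    sec = cfg.growth
    results: dict[str, dict] = {"rates": {}, "lags": {}}
    if "synthetic" in sec:
        syn = sec["synthetic"]
        cv = float(syn.get("noise_cv", 0.02))
        for i, (medium, lam) in enumerate(sorted(syn.get("rates", {}).items())):
            curve = synthetic.generate_growth_curve(
                float(lam), noise_cv=cv, seed=cfg.seed * 1000 + i, medium=medium)
            fit = physiology.fit_growth_rate(curve)
            results["rates"][medium] = {
                "lambda": fit.lam, "r_squared": fit.r_squared,
                "doubling_time_h": fit.doubling_time, "true_lambda": float(lam),
            }
        down = syn.get("downshift", {})
        lam_post = float(down.get("lambda_post", 0.9))
        for i, (strain, lag) in enumerate(sorted(down.get("lags", {}).items())):
            curve = synthetic.generate_downshift_curve(
                lam_post, float(lag), noise_cv=cv, seed=cfg.seed * 1000 + 500 + i, strain=strain)
            est = physiology.estimate_lag_time(curve)
            results["lags"][strain] = {
                "lag_h": est.lag, "lambda_post": est.lambda_post, "true_lag_h": float(lag),
            }
    for spec in sec.get("curves", []):
        curve = io.read_growth_curve(spec["path"], strain=spec.get("strain", ""),
                                     medium=spec.get("medium", ""))
        fit = physiology.fit_growth_rate(curve)
        key = spec.get("medium") or Path(spec["path"]).stem
        results["rates"][key] = {"lambda": fit.lam, "r_squared": fit.r_squared,
                                 "doubling_time_h": fit.doubling_time}
    if results["rates"] or results["lags"]:
        log.info(f"growth: fitted {len(results['rates'])} curves, "
                 f"{len(results['lags'])} downshift lags")
        return results
    log.info("growth: nothing configured, skipped")
    return None


@_stage("rline")
def _rline_stage(cfg: RunConfig, log: _StageLog):
    sec = cfg.rline
    points = None
    if "points" in sec:
        points = [tuple(map(float, p)) for p in sec["points"]]
    elif "csv" in sec:
        import pandas as pd

        df = pd.read_csv(sec["csv"], encoding="utf-8")
        points = list(zip(df.iloc[:, 0].astype(float), df.iloc[:, 1].astype(float)))
    elif "synthetic" in sec:
        syn = sec["synthetic"]
        rng = np.random.default_rng(cfg.seed + 77)
        lam = np.linspace(0.3, 2.0, int(syn.get("n", 10)))
        rp = (float(syn.get("intercept", 0.08)) + float(syn.get("slope", 0.10)) * lam
              + float(syn.get("noise_sd", 0.004)) * rng.standard_normal(lam.size))
        points = list(zip(lam, rp))
    if points is None:
        log.info("rline: nothing configured, skipped")
        return None
    fit = growth_model.fit_rline(points)
    log.info(f"rline: slope={fit.slope:.4f} intercept={fit.intercept:.4f} "
             f"r2={fit.r_squared:.4f} n={fit.n_points}")
    return fit


@_stage("model")
def _model_stage(cfg: RunConfig, log: _StageLog):
    sec = cfg.model
    if not all(k in sec for k in ("phi_Q", "gamma", "nu")):
        log.info("model: phi_Q/gamma/nu not configured, skipped")
        return None
    model = growth_model.AllocationModel(
        phi_Q=float(sec["phi_Q"]), gamma=float(sec["gamma"]), nu=float(sec["nu"]),
        phi_U=float(sec.get("phi_U", 0.0)), phi_R0=float(sec.get("phi_R0", 0.0)),
    )
    pred = growth_model.steady_state(model)
    burden = {}
    for phi_u in (0.0, 0.02, 0.05, 0.08):
        m = growth_model.AllocationModel(
            phi_Q=model.phi_Q, gamma=model.gamma, nu=model.nu,
            phi_U=phi_u, phi_R0=model.phi_R0)
        burden[f"{phi_u:.2f}"] = growth_model.steady_state(m).lam
    log.info(f"model: lambda={pred.lam:.4f} phi_R={pred.phi_R:.4f} phi_A={pred.phi_A:.4f}")
    return {
        "parameters": {"phi_Q": model.phi_Q, "gamma": model.gamma, "nu": model.nu,
                       "phi_U": model.phi_U, "phi_R0": model.phi_R0},
        "steady_state": {"lambda": pred.lam, "phi_R": pred.phi_R, "phi_A": pred.phi_A},
        "lambda_vs_phi_U": burden,
    }


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute every configured stage and write the report bundle.

    Returns the artifact paths. Any stage failure raises
    :class:`ConfigError` tagged with the stage name.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog()
    log.info(f"seed: {cfg.seed}")
    log.info(f"config: {json.dumps(cfg.raw, sort_keys=True, default=str)}")
    artifacts: dict[str, Path] = {}

    records, samples, gene_sets, truth = _proteome_stage(cfg, log)
    allocs = _allocate_stage(records, samples, log)
    scheme, table = _sector_stage(allocs, samples, gene_sets, log)
    io.write_sector_table(table, out / "sector_fractions.csv")
    artifacts["sector_fractions"] = out / "sector_fractions.csv"

    io.write_proteomaps_input(allocs[0], out / "proteomaps.tsv")
    artifacts["proteomaps"] = out / "proteomaps.tsv"

    report = _balance_stage(cfg, table, scheme, samples, log)
    if report is not None:
        (out / "balance.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True), encoding="utf-8")
        artifacts["balance"] = out / "balance.json"

    growth_results = _growth_stage(cfg, log)
    if growth_results is not None:
        (out / "growth.json").write_text(
            json.dumps(growth_results, indent=2, sort_keys=True), encoding="utf-8")
        artifacts["growth"] = out / "growth.json"

    rfit = _rline_stage(cfg, log)
    if rfit is not None:
        (out / "rline.json").write_text(
            json.dumps({"slope": rfit.slope, "intercept": rfit.intercept,
                        "r_squared": rfit.r_squared, "n_points": rfit.n_points},
                       indent=2, sort_keys=True), encoding="utf-8")
        artifacts["rline"] = out / "rline.json"

    model_results = _model_stage(cfg, log)
    if model_results is not None:
        (out / "model.json").write_text(
            json.dumps(model_results, indent=2, sort_keys=True), encoding="utf-8")
        artifacts["model"] = out / "model.json"

    if truth is not None:
        truth.to_json(out / "truth.json")
        artifacts["truth"] = out / "truth.json"

    log.write(out / "run.log")
    artifacts["log"] = out / "run.log"
    return artifacts
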