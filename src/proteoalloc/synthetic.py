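"""Synthetic proteomes, growth curves and assay readings with known truth.

The generator emulates the data a condition-dependent allocation study
produces, so that every pipeline stage can be tested against ground
truth without the deposited datasets:

* multi-sector proteomes — each sector has a stated true mass fraction;
  within-sector protein abundances are lognormal (proteomes are
  heavy-tailed) and renormalized so sector sums match truth exactly;
  replicate iBAQ intensities carry multiplicative lognormal measurement
  noise of a stated CV, matching intensity-scale MS error;
* strain/condition contrasts — a second condition re-weights sector
  fractions to stated targets while keeping the same protein universe,
  so differential-balance accounting can be validated by construction;
* exponential OD600 curves with a stated growth rate, and downshift
  curves OD(t) = OD0 * exp(lambda * max(0, t - lag)) with a stated lag.

Default sector fractions reproduce the wild-type LB study condition
(ribosomal/translation 25%, nucleotide biosynthesis 4%, amino-acid
biosynthesis 5%, motility 0.76%) and the codY-null contrast moves
8.24% of proteome mass from translation+NT onto AA+motility (AA +6.5
points, motility 0.76% -> 2.5%), the magnitude of reallocation the
derepressed regulon produces. Everything is deterministic given
(config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .io import (
    ProteinRecord,
    SampleDescriptor,
    SampleIntensity,
    SectorDefinition,
    SectorMode,
    parse_sample_id,
    write_protein_groups,
)
from .physiology import GrowthCurve


@dataclass(frozen=True)
class SectorSpec:
    name: str
    fraction: float
    n_proteins: int


#: wild-type LB study condition: sector mass fractions and universe sizes
STUDY_SECTORS: tuple[SectorSpec, ...] = (
    SectorSpec("translation", 0.25, 60),
    SectorSpec("nt_biosynthesis", 0.04, 25),
    SectorSpec("aa_biosynthesis", 0.05, 60),
    SectorSpec("motility", 0.0076, 30),
    SectorSpec("other", 0.6524, 225),
)

#: codY-null LB: AA +6.5 points, motility 0.76% -> 2.5%, paid by translation+NT
STUDY_CONTRAST_EFFECT: dict[str, float] = {
    "aa_biosynthesis": 0.115,
    "motility": 0.025,
    "translation": 0.18,
    "nt_biosynthesis": 0.0276,
}

#: plausible exponential growth rates (h^-1) per medium for the demo runs
STUDY_GROWTH_RATES: dict[str, float] = {
    "LB": 2.0,
    "glu_cAA": 1.6,
    "glucose_min": 0.9,
    "mannose_min": 0.7,
    "arabinose_min": 0.6,
}

#: downshift lag times (h) rich -> glucose minimal for the demo runs
STUDY_LAG_TIMES: dict[str, float] = {"WT": 2.5, "codY-null": 1.0}

#: share of each sector's proteins carried by the regulon overlay gene set
STUDY_REGULON_OVERLAY: dict[str, float] = {"aa_biosynthesis": 0.4, "motility": 1.0}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the proteome generator.

    ``protein_spread`` is the lognormal sigma of within-sector relative
    abundance; ``noise_cv`` the multiplicative measurement CV per
    replicate. Replicate count defaults to 3 biological replicates.
    """

    seed: int = 0
    sectors: tuple[SectorSpec, ...] = STUDY_SECTORS
    protein_spread: float = 1.0
    noise_cv: float = 0.05
    n_replicates: int = 3
    mw_range: tuple[float, float] = (10_000.0, 100_000.0)
    strain: str = "WT"
    medium: str = "LB"
    ibaq_scale: float = 1e7

    def __post_init__(self) -> None:
        total = math.fsum(s.fraction for s in self.sectors)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"sector fractions sum to {total!r}, not 1")
        if any(s.n_proteins < 1 for s in self.sectors):
            raise ConfigError("every sector needs >= 1 protein")
        if any(s.fraction <= 0 for s in self.sectors):
            raise ConfigError("sector fractions must be positive")
        if self.noise_cv < 0 or self.protein_spread < 0:
            raise ConfigError("noise_cv and protein_spread must be nonnegative")
        if self.n_replicates < 1:
            raise ConfigError("need >= 1 replicate")


@dataclass
class SyntheticTruth:
    """Ground-truth manifest: exactly what the pipeline should recover."""

    sector_fractions: dict[str, dict[str, float]]   # "strain|medium" -> sector -> phi
    protein_masses: dict[str, dict[str, float]]     # condition key -> locus -> phi_i
    sector_of: dict[str, str]                       # locus -> sector name
    growth: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


@dataclass
class SyntheticProteome:
    records: list[ProteinRecord]
    samples: list[SampleDescriptor]
    truth: SyntheticTruth
    gene_sets: dict[str, SectorDefinition]


def condition_key(strain: str, medium: str) -> str:
    return f"{strain}|{medium}"


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Median-1 multiplicative noise with the requested CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(sigma * rng.standard_normal(size))


def generate_proteome(
    config: SyntheticConfig,
    conditions: Sequence[tuple[str, str, Mapping[str, float] | None]] | None = None,
) -> SyntheticProteome:
    """Generate protein records for one or more conditions plus the truth.

    ``conditions`` is a list of (strain, medium, sector_fractions) with
    ``None`` fractions meaning the config defaults. The protein universe
    (locus tags, molecular weights, within-sector relative abundances)
    is shared across conditions; only sector totals are re-weighted, so
    contrasts differ by sector-level reallocation only.
    """
    if conditions is None:
        conditions = [(config.strain, config.medium, None)]
    rng = np.random.default_rng(config.seed)
    names = [s.name for s in config.sectors]
    default_fracs = {s.name: s.fraction for s in config.sectors}

    # protein universe: locus tags on a BSU-style grid, MW on a 125 Da
    # grid (10-100 kDa) so the kDa file column round-trips bit-exactly
    counts = [s.n_proteins for s in config.sectors]
    n_total = sum(counts)
    mw = 125.0 * rng.integers(80, 801, size=n_total).astype(float)
    rel = np.exp(config.protein_spread * rng.standard_normal(n_total))
    locus_tags = [f"BSU{(i + 1) * 10:05d}" for i in range(n_total)]
    sector_of: dict[str, str] = {}
    idx_of_sector: dict[str, np.ndarray] = {}
    start = 0
    for spec in config.sectors:
        idx = np.arange(start, start + spec.n_proteins)
        idx_of_sector[spec.name] = idx
        for i in idx:
            sector_of[locus_tags[i]] = spec.name
        start += spec.n_proteins

    # per-condition true per-protein mass fractions (sector sums exact)
    truth_masses: dict[str, dict[str, float]] = {}
    truth_sectors: dict[str, dict[str, float]] = {}
    cond_mass = {}
    for strain, medium, fracs in conditions:
        fr = dict(default_fracs) if fracs is None else dict(fracs)
        if set(fr) != set(names):
            raise ConfigError(f"condition ({strain}, {medium}) must specify all sectors {names}")
        total = math.fsum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"condition ({strain}, {medium}) fractions sum to {total!r}, not 1")
        mass = np.empty(n_total)
        for name in names:
            idx = idx_of_sector[name]
            mass[idx] = rel[idx] / rel[idx].sum() * fr[name]
        key = condition_key(strain, medium)
        cond_mass[(strain, medium)] = mass
        truth_masses[key] = {locus_tags[i]: float(mass[i]) for i in range(n_total)}
        truth_sectors[key] = fr

    # replicate iBAQ intensities with multiplicative measurement noise
    intensities: list[dict[str, SampleIntensity]] = [{} for _ in range(n_total)]
    sample_ids: list[str] = []
    for strain, medium, _ in conditions:
        mass = cond_mass[(strain, medium)]
        for rep in range(1, config.n_replicates + 1):
            sid = f"{strain}_{medium}_{rep}"
            sample_ids.append(sid)
            noise = _lognormal_noise(rng, config.noise_cv, n_total)
            ibaq = mass / mw * config.ibaq_scale * noise
            for i in range(n_total):
                intensities[i][sid] = SampleIntensity(ibaq=float(ibaq[i]))

    records = [
        ProteinRecord(
            protein_id=f"SYN_{locus_tags[i]}",
            locus_tag=locus_tags[i],
            gene_name=f"{sector_of[locus_tags[i]][:3]}{i + 1}",
            mol_weight=float(mw[i]),
            intensities=intensities[i],
        )
        for i in range(n_total)
    ]
    samples = [parse_sample_id(sid) for sid in sample_ids]

    gene_sets = {
        spec.name: SectorDefinition(
            name=spec.name,
            members=frozenset(locus_tags[i] for i in idx_of_sector[spec.name]),
            mode=SectorMode.partition_member,
        )
        for spec in config.sectors
    }
    # regulon-style overlay: all of motility plus part of AA biosynthesis
    overlay_members: set[str] = set()
    for name, share in STUDY_REGULON_OVERLAY.items():
        if name in idx_of_sector:
            idx = idx_of_sector[name]
            overlay_members |= {locus_tags[i] for i in idx[: max(1, int(share * len(idx)))]}
    if overlay_members:
        gene_sets["cody_regulon"] = SectorDefinition(
            name="cody_regulon", members=frozenset(overlay_members), mode=SectorMode.overlay
        )

    truth = SyntheticTruth(
        sector_fractions=truth_sectors,
        protein_masses=truth_masses,
        sector_of=sector_of,
    )
    return SyntheticProteome(records=records, samples=samples, truth=truth, gene_sets=gene_sets)


def generate_condition_contrast(
    config: SyntheticConfig,
    effect: Mapping[str, float] | None = None,
    strain_b: str = "codY-null",
    medium_b: str | None = None,
) -> SyntheticProteome:
    """Paired conditions: config defaults vs sector fractions re-weighted
    to ``effect`` targets (sectors not named keep their default value).

    The resulting full fraction vector must sum to 1 — reallocation must
    be balanced explicitly, which is what makes Sum(delta phi) = 0 hold
    by construction.
    """
    if effect is None:
        effect = STUDY_CONTRAST_EFFECT
    defaults = {s.name: s.fraction for s in config.sectors}
    unknown = set(effect) - set(defaults)
    if unknown:
        raise ConfigError(f"effect names unknown sectors: {sorted(unknown)}")
    target = dict(defaults)
    target.update(effect)
    total = math.fsum(target.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"contrast target fractions sum to {total!r}, not 1")
    return generate_proteome(
        config,
        conditions=[
            (config.strain, config.medium, None),
            (strain_b, medium_b or config.medium, target),
        ],
    )


def generate_growth_curve(
    lam: float,
    od0: float = 0.05,
    grid: Sequence[float] | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    n_points: int = 7,
    strain: str = "",
    medium: str = "",
) -> GrowthCurve:
    """Exponential OD600 curve OD(t) = OD0 * exp(lam*t) * noise.

    The default grid gives ``n_points`` readings spanning OD ~0.05-0.5
    (the usual exponential sampling range). Noise is multiplicative
    lognormal with median 1, so the log-linear slope stays unbiased.
    """
    if grid is None:
        t_end = math.log(0.5 / od0) / lam if lam > 0 else 2.0
        grid = np.linspace(0.0, t_end, n_points)
    t = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    od = od0 * np.exp(lam * t) * _lognormal_noise(rng, noise_cv, t.size)
    return GrowthCurve(times=t, od600=od, strain=strain, medium=medium)


def generate_downshift_curve(
    lam_post: float,
    lag: float,
    od0: float = 0.1,
    grid: Sequence[float] | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    n_points: int = 24,
    strain: str = "",
    medium: str = "",
) -> GrowthCurve:
    """Downshift curve OD(t) = OD0 * exp(lam_post * max(0, t - lag)) * noise."""
    if lam_post <= 0:
        raise ConfigError("post-shift growth rate must be positive")
    if lag < 0:
        raise ConfigError("lag must be nonnegative")
    if grid is None:
        grid = np.linspace(0.0, lag + 2.5 / lam_post, n_points)
    t = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    od = od0 * np.exp(lam_post * np.maximum(0.0, t - lag)) * _lognormal_noise(rng, noise_cv, t.size)
    return GrowthCurve(times=t, od600=od, strain=strain, medium=medium)


def write_bundle(proteome: SyntheticProteome, out_dir: str | Path) -> dict[str, Path]:
    """Write the generated study to disk in the formats the readers consume.

    Emits the MaxQuant-dialect protein-groups TSV, one gene-set file per
    sector (two columns: locus tag, gene name), and the truth manifest
    as JSON. Returns the paths keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    pg = out_dir / "protein_groups.tsv"
    write_protein_groups(proteome.records, pg)
    paths["protein_groups"] = pg

    gene_name_of = {r.locus_tag: r.gene_name for r in proteome.records}
    for name, sector in proteome.gene_sets.items():
        p = out_dir / f"geneset_{name}.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            for tag in sorted(sector.members):
                fh.write(f"{tag}\t{gene_name_of.get(tag, '')}\n")
        paths[f"geneset_{name}"] = p

    tp = out_dir / "truth.json"
    proteome.truth.to_json(tp)
    paths["truth"] = tp
    return paths
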