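"""iBAQ-mass fractions, sector aggregation and allocation balance.

The central quantity is the per-protein proteome mass fraction

    phi_i = iBAQ_i * MW_i / sum_j (iBAQ_j * MW_j)

("iBAQ mass" normalized by the whole-proteome iBAQ mass). Sector
fractions phi_S are sums of phi_i over a gene set S, computed per sample
and then averaged over biological replicates. For a disjoint partition of
the proteome (with an implicit "other" remainder sector) the sector
fractions close to 1, so between any two conditions the per-sector
changes sum to zero — the conservation property that underlies the
balance accounting: mass gained by derepressed sectors (e.g. amino-acid
biosynthesis, motility) must be paid for by other sectors (translation
machinery, nucleotide biosynthesis).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import DegenerateSampleError, ValidationError
from .io import ProteinRecord, SampleDescriptor, SectorDefinition

logger = logging.getLogger(__name__)

#: name of the implicit remainder sector closing a partition scheme
OTHER_SECTOR = "other"


@dataclass(frozen=True)
class SectorScheme:
    """A disjoint partition (plus implicit remainder) and optional overlays.

    Partition sectors must be pairwise disjoint; overlay sets (e.g. the
    CodY regulon, which intersects the amino-acid-biosynthesis sector)
    may overlap anything and are excluded from conservation accounting.
    """

    partition: tuple[SectorDefinition, ...]
    overlays: tuple[SectorDefinition, ...] = ()

    def __post_init__(self) -> None:
        names = [s.name for s in self.partition] + [s.name for s in self.overlays]
        if len(names) != len(set(names)):
            raise ValidationError("sector names must be unique within a scheme")
        if OTHER_SECTOR in names:
            raise ValidationError(f"{OTHER_SECTOR!r} is reserved for the remainder sector")
        seen: set[str] = set()
        for s in self.partition:
            overlap = seen & s.members
            if overlap:
                raise ValidationError(
                    f"partition sectors overlap (e.g. {sorted(overlap)[:3]}); "
                    "use overlay mode for intersecting sets"
                )
            seen |= s.members

    @property
    def partition_names(self) -> list[str]:
        return [s.name for s in self.partition] + [OTHER_SECTOR]


@dataclass
class AllocationResult:
    """Per-protein mass fractions of one sample; fractions sum to 1."""

    sample_id: str
    fractions: dict[str, float]
    total_ibaq_mass: float
    n_missing: int = 0

    def __post_init__(self) -> None:
        total = math.fsum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValidationError(f"fractions sum to {total!r}, not 1")


class SectorFraction(NamedTuple):
    value: float
    n_matched: int


@dataclass
class BalanceReport:
    """Differential allocation between two conditions over one partition.

    ``delta`` holds phi_B - phi_A per sector; ``increase_total`` /
    ``decrease_total`` sum the deltas over the two named sector groups;
    ``residual = increase_total - |decrease_total|`` measures how far the
    gains are from exactly paying for the losses. ``closure`` is the sum
    of deltas over the full partition (0 up to numerical noise).
    """

    condition_a: str
    condition_b: str
    delta: dict[str, float]
    increase_sectors: list[str]
    decrease_sectors: list[str]
    increase_total: float
    decrease_total: float
    residual: float
    closure: float = 0.0

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "delta": self.delta,
            "increase_sectors": self.increase_sectors,
            "decrease_sectors": self.decrease_sectors,
            "increase_total": self.increase_total,
            "decrease_total": self.decrease_total,
            "residual": self.residual,
            "closure": self.closure,
        }


def compute_mass_fractions(
    records: Sequence[ProteinRecord],
    sample_id: str,
    missing_policy: str = "zero",
) -> AllocationResult:
    """Compute phi_i = iBAQ_i * MW_i / sum_j iBAQ_j * MW_j for one sample.

    Missing intensities contribute zero mass under the default
    ``missing_policy="zero"`` (the count of missing cells is kept for QC).

    Raises
    ------
    DegenerateSampleError
        If no record has a positive iBAQ intensity in this sample.
    """
    if missing_policy != "zero":
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    masses: dict[str, float] = {}
    n_missing = 0
    for rec in records:
        cell = rec.intensities.get(sample_id)
        if cell is None or cell.ibaq is None:
            n_missing += 1
            masses[rec.locus_tag] = 0.0
        else:
            masses[rec.locus_tag] = cell.ibaq * rec.mol_weight
    total = math.fsum(masses.values())
    if total <= 0.0:
        raise DegenerateSampleError(f"sample {sample_id!r} has no positive iBAQ intensity")
    if n_missing:
        logger.info("sample %s: %d proteins without intensity treated as zero mass", sample_id, n_missing)
    fractions = {tag: m / total for tag, m in masses.items()}
    return AllocationResult(sample_id=sample_id, fractions=fractions,
                            total_ibaq_mass=total, n_missing=n_missing)


def sector_fraction(alloc: AllocationResult, sector: SectorDefinition) -> SectorFraction:
    """phi_S = sum of phi_i over sector members present in the proteome."""
    matched = [t for t in sector.members if t in alloc.fractions]
    if not matched:
        logger.warning("sector %s shares no locus tags with sample %s", sector.name, alloc.sample_id)
    return SectorFraction(value=math.fsum(alloc.fractions[t] for t in matched), n_matched=len(matched))


def _per_sample_partition_fractions(
    alloc: AllocationResult, scheme: SectorScheme
) -> dict[str, float]:
    fracs = {s.name: sector_fraction(alloc, s).value for s in scheme.partition}
    fracs[OTHER_SECTOR] = 1.0 - math.fsum(fracs.values())
    return fracs


def aggregate_replicates(
    allocs: Sequence[AllocationResult],
    descriptors: Sequence[SampleDescriptor],
    scheme: SectorScheme,
) -> pd.DataFrame:
    """Sector-fraction table with replicate mean and SD per condition.

    Per-sample sector fractions are computed first (each sample's proteome
    closes to 1), then averaged across replicates of the same
    (strain, medium). Partition sectors are closed by the implicit
    ``other`` remainder; overlay sectors are reported alongside but do
    not participate in closure.

    Returns a tidy frame with columns
    ``strain, medium, sector, mean_fraction, sd_fraction, n_replicates``.
    """
    desc_by_id = {d.sample_id: d for d in descriptors}
    missing = [a.sample_id for a in allocs if a.sample_id not in desc_by_id]
    if missing:
        raise ValidationError(f"no descriptor for sample(s) {missing}")

    rows = []
    for alloc in allocs:
        d = desc_by_id[alloc.sample_id]
        fracs = _per_sample_partition_fractions(alloc, scheme)
        if fracs[OTHER_SECTOR] < -1e-6:
            raise ValidationError(
                f"partition sectors of sample {alloc.sample_id} sum above 1; scheme is not disjoint"
            )
        for s in scheme.overlays:
            fracs[s.name] = sector_fraction(alloc, s).value
        for sector, value in fracs.items():
            rows.append({"strain": d.strain.value, "medium": d.medium,
                         "sector": sector, "fraction": value})
    long = pd.DataFrame(rows)
    out = (
        long.groupby(["strain", "medium", "sector"], sort=True)["fraction"]
        .agg(mean_fraction="mean", sd_fraction="std", n_replicates="count")
        .reset_index()
    )
    out["sd_fraction"] = out["sd_fraction"].fillna(0.0)
    return out


def condition_slice(table: pd.DataFrame, strain: str, medium: str) -> dict[str, float]:
    """Extract {sector: mean_fraction} for one (strain, medium) condition."""
    sub = table[(table["strain"] == strain) & (table["medium"] == medium)]
    if sub.empty:
        raise ValidationError(f"no rows for condition ({strain}, {medium})")
    return dict(zip(sub["sector"], sub["mean_fraction"]))


def balance_analysis(
    fractions_a: Mapping[str, float],
    fractions_b: Mapping[str, float],
    increase_set: Sequence[str],
    decrease_set: Sequence[str],
    condition_a: str = "A",
    condition_b: str = "B",
) -> BalanceReport:
    """Differential-allocation balance between two conditions.

    Both inputs are {sector: fraction} over the *same* partition (use
    :func:`condition_slice` on an aggregated table). Delta is B - A;
    grouped totals are summed over ``increase_set`` and ``decrease_set``
    and the residual is ``increase_total - |decrease_total|``.
    """
    if set(fractions_a) != set(fractions_b):
        raise ValidationError(
            f"sector mismatch between conditions: {sorted(set(fractions_a) ^ set(fractions_b))}"
        )
    for name in list(increase_set) + list(decrease_set):
        if name not in fractions_a:
            raise ValidationError(f"unknown sector {name!r} in balance groups")
    delta = {s: fractions_b[s] - fractions_a[s] for s in fractions_a}
    increase_total = math.fsum(delta[s] for s in increase_set)
    decrease_total = math.fsum(delta[s] for s in decrease_set)
    return BalanceReport(
        condition_a=condition_a,
        condition_b=condition_b,
        delta=delta,
        increase_sectors=list(increase_set),
        decrease_sectors=list(decrease_set),
        increase_total=increase_total,
        decrease_total=decrease_total,
        residual=increase_total - abs(decrease_total),
        closure=math.fsum(delta.values()),
    )


def overlay_decomposition(
    alloc: AllocationResult,
    overlay: SectorDefinition,
    partition_sector: SectorDefinition,
) -> tuple[float, float]:
    """Split phi(partition_sector) into overlay-inside and -outside parts.

    Example: the amino-acid-biosynthesis sector split into its
    CodY-regulon members and the rest. Returns ``(inside, outside)`` with
    ``inside + outside == phi(partition_sector)`` exactly (same summation).
    """
    inside_set = overlay.members & partition_sector.members
    outside_set = partition_sector.members - overlay.members
    inside = math.fsum(alloc.fractions[t] for t in inside_set if t in alloc.fractions)
    outside = math.fsum(alloc.fractions[t] for t in outside_set if t in alloc.fractions)
    return inside, outside
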