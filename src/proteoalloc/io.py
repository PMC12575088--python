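"""Readers and writers for protein-groups tables, gene sets and results.

The quantitative input is a MaxQuant-style ``proteinGroups`` TSV: one row
per protein group with identifier columns, a molecular-weight column in
kDa, and one iBAQ (and optionally LFQ) intensity column per sample.
Contaminant and decoy rows (identifier prefixes ``CON__`` / ``REV__``) are
dropped at read time, molecular weight is converted to Daltons, and zero
or empty intensity cells are recorded as *missing* rather than zero so
that downstream quality control can count them.

Gene sets (e.g. a regulon list exported from Subtiwiki, or a functional
sector list) are one- or two-column text tables keyed by locus tag; locus
tags are the join key throughout the package and are case-normalized on
read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: identifier prefixes MaxQuant uses for contaminants and reversed decoys
CONTAMINANT_PREFIXES = ("CON__", "REV__")

#: default MaxQuant-dialect column names; override via ``column_map``
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "protein_id": "Protein IDs",
    "locus_tag": "Locus tag",
    "gene_name": "Gene names",
    "mol_weight_kda": "Mol. weight [kDa]",
    "ibaq_prefix": "iBAQ ",
    "lfq_prefix": "LFQ intensity ",
}


class Strain(str, Enum):
    wild_type = "wild_type"
    codY_null = "codY_null"
    other = "other"


class SectorMode(str, Enum):
    #: member of a disjoint partition of the proteome (conservation holds)
    partition_member = "partition_member"
    #: overlay set that may intersect partition sectors (e.g. a regulon)
    overlay = "overlay"


@dataclass(frozen=True)
class SampleIntensity:
    """Per-sample intensities of one protein; ``None`` means not detected."""

    ibaq: float | None
    lfq: float | None = None


@dataclass(frozen=True)
class ProteinRecord:
    """One protein group: identifiers, molecular weight and intensities.

    ``mol_weight`` is in Daltons (converted from the kDa file column);
    ``intensities`` maps sample_id to the per-sample readings.
    """

    protein_id: str
    locus_tag: str
    gene_name: str
    mol_weight: float
    intensities: Mapping[str, SampleIntensity] = field(default_factory=dict)


@dataclass(frozen=True)
class SampleDescriptor:
    """Identity of one proteome sample: strain x medium x replicate."""

    sample_id: str
    strain: Strain
    medium: str
    replicate: int


@dataclass(frozen=True)
class SectorDefinition:
    """A named gene set given as locus tags, used as a proteome sector."""

    name: str
    members: frozenset[str]
    mode: SectorMode = SectorMode.overlay

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("sector name must be non-empty")
        if not self.members:
            raise ValidationError(f"sector {self.name!r} has no members")


@dataclass
class ProteinGroupsTable:
    """Parsed protein-groups table plus the filter accounting.

    Invariant: ``n_contaminants + n_invalid_mw + len(records)`` equals the
    number of data rows in the input file.
    """

    records: list[ProteinRecord]
    samples: list[SampleDescriptor]
    n_contaminants: int = 0
    n_invalid_mw: int = 0


_STRAIN_ALIASES = {
    "wt": Strain.wild_type,
    "wildtype": Strain.wild_type,
    "168": Strain.wild_type,
    "py79": Strain.wild_type,
    "codynull": Strain.codY_null,
    "dcody": Strain.codY_null,
}


def parse_sample_id(sample_id: str) -> SampleDescriptor:
    """Parse ``<strain>_<medium>_<replicate>`` sample identifiers.

    The medium may itself contain underscores (``glu_cAA``); the strain is
    the first token and the replicate the trailing integer. Identifiers
    not matching the convention fall back to strain ``other``/replicate 1.
    """
    parts = sample_id.split("_")
    if len(parts) >= 3 and parts[-1].isdigit():
        token = re.sub(r"[^0-9a-z]", "", parts[0].lower())
        strain = _STRAIN_ALIASES.get(token, Strain.other)
        return SampleDescriptor(
            sample_id=sample_id,
            strain=strain,
            medium="_".join(parts[1:-1]),
            replicate=int(parts[-1]),
        )
    return SampleDescriptor(sample_id=sample_id, strain=Strain.other, medium=sample_id, replicate=1)


def normalize_locus_tag(tag: str) -> str:
    return tag.strip().upper()


def _cell_to_intensity(value) -> float | None:
    # MaxQuant writes 0 for not-detected; treat as missing at read time
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    v = float(value)
    return None if v == 0.0 else v


def read_protein_groups(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> ProteinGroupsTable:
    """Read a MaxQuant-style proteinGroups TSV.

    Parameters
    ----------
    path
        Tab-separated table with a header row.
    column_map
        Overrides for :data:`DEFAULT_COLUMN_MAP` entries (identifier,
        molecular-weight and intensity-column naming).

    Raises
    ------
    FormatError
        If a mandatory column is absent (the message names it).
    ValidationError
        If locus tags are duplicated after contaminant removal.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, sep="\t", encoding="utf-8", dtype={cmap["protein_id"]: str},
                     float_precision="round_trip")
    for key in ("protein_id", "locus_tag", "mol_weight_kda"):
        if cmap[key] not in df.columns:
            raise FormatError(f"mandatory column {cmap[key]!r} missing from {path}")

    ibaq_cols = {c[len(cmap["ibaq_prefix"]):]: c for c in df.columns if c.startswith(cmap["ibaq_prefix"])}
    lfq_cols = {c[len(cmap["lfq_prefix"]):]: c for c in df.columns if c.startswith(cmap["lfq_prefix"])}
    sample_ids = sorted(set(ibaq_cols) | set(lfq_cols))

    is_contaminant = df[cmap["protein_id"]].fillna("").str.startswith(CONTAMINANT_PREFIXES)
    n_contaminants = int(is_contaminant.sum())
    df = df[~is_contaminant]

    mw_kda = pd.to_numeric(df[cmap["mol_weight_kda"]], errors="coerce")
    bad_mw = ~(mw_kda > 0)
    n_invalid_mw = int(bad_mw.sum())
    if n_invalid_mw:
        logger.info("dropped %d rows without a positive molecular weight", n_invalid_mw)
    df = df[~bad_mw]
    mw_kda = mw_kda[~bad_mw]

    gene_col = cmap["gene_name"] if cmap["gene_name"] in df.columns else None
    records: list[ProteinRecord] = []
    for (_, row), kda in zip(df.iterrows(), mw_kda):
        intensities = {
            sid: SampleIntensity(
                ibaq=_cell_to_intensity(row[ibaq_cols[sid]]) if sid in ibaq_cols else None,
                lfq=_cell_to_intensity(row[lfq_cols[sid]]) if sid in lfq_cols else None,
            )
            for sid in sample_ids
        }
        records.append(
            ProteinRecord(
                protein_id=str(row[cmap["protein_id"]]),
                locus_tag=normalize_locus_tag(str(row[cmap["locus_tag"]])),
                gene_name="" if gene_col is None or pd.isna(row[gene_col]) else str(row[gene_col]),
                mol_weight=kda * 1000.0,
                intensities=intensities,
            )
        )

    tags = [r.locus_tag for r in records]
    dupes = sorted({t for t in tags if tags.count(t) > 1}) if len(set(tags)) != len(tags) else []
    if dupes:
        raise ValidationError(f"duplicate locus tags after filtering: {', '.join(dupes)}")

    samples = [parse_sample_id(sid) for sid in sample_ids]
    return ProteinGroupsTable(
        records=records, samples=samples,
        n_contaminants=n_contaminants, n_invalid_mw=n_invalid_mw,
    )


def write_protein_groups(
    records: Sequence[ProteinRecord],
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write records back to the MaxQuant-dialect TSV the reader consumes.

    Missing intensities are written as 0 (the MaxQuant convention); the
    molecular weight column is in kDa.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    sample_ids = sorted({sid for r in records for sid in r.intensities})
    rows = []
    for r in records:
        row: dict[str, object] = {
            cmap["protein_id"]: r.protein_id,
            cmap["locus_tag"]: r.locus_tag,
            cmap["gene_name"]: r.gene_name,
            cmap["mol_weight_kda"]: r.mol_weight / 1000.0,
        }
        for sid in sample_ids:
            cell = r.intensities.get(sid)
            row[cmap["ibaq_prefix"] + sid] = 0.0 if cell is None or cell.ibaq is None else cell.ibaq
            if cell is not None and cell.lfq is not None:
                row[cmap["lfq_prefix"] + sid] = cell.lfq
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_gene_set(
    path: str | Path,
    name: str | None = None,
    mode: SectorMode = SectorMode.overlay,
) -> SectorDefinition:
    """Read a one- or two-column (locus_tag[, gene_name]) gene list.

    Lines starting with ``#`` are comments. Locus tags are trimmed and
    upper-cased; duplicates are collapsed with a logged count.

    Raises
    ------
    ValidationError
        If the file contains no locus tags.
    """
    path = Path(path)
    tags: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tag = re.split(r"[\t,;]|\s{2,}| ", line)[0]
            if tag:
                tags.append(normalize_locus_tag(tag))
    if not tags:
        raise ValidationError(f"gene-set file {path} contains no locus tags")
    members = frozenset(tags)
    n_dupes = len(tags) - len(members)
    if n_dupes:
        logger.warning("gene set %s: %d duplicate locus tags collapsed", path.name, n_dupes)
    return SectorDefinition(name=name or path.stem, members=members, mode=mode)


def membership_report(sector: SectorDefinition, proteome_tags: Iterable[str]) -> dict[str, object]:
    """Which sector members are (not) present in a proteome table."""
    tags = {normalize_locus_tag(t) for t in proteome_tags}
    matched = sector.members & tags
    unmatched = sector.members - tags
    return {
        "sector": sector.name,
        "n_members": len(sector.members),
        "n_matched": len(matched),
        "unmatched": sorted(unmatched),
    }


def write_proteomaps_input(alloc, path: str | Path) -> None:
    """Write the two-column (locus_tag TAB mass-fraction) submission file.

    Row order is deterministic (sorted by locus tag) and the fraction
    column sums to 1 by construction of the allocation.
    """
    if not alloc.fractions:
        raise ValidationError("cannot write proteomaps input for an empty allocation")
    with open(path, "w", encoding="utf-8") as fh:
        for tag in sorted(alloc.fractions):
            fh.write(f"{tag}\t{alloc.fractions[tag]!r}\n")


def read_growth_curve(path: str | Path, strain: str = "", medium: str = ""):
    """Read a (time_h, od600) CSV into a :class:`~proteoalloc.physiology.GrowthCurve`."""
    from .physiology import GrowthCurve

    df = pd.read_csv(path, encoding="utf-8")
    cols = {c.lower().strip(): c for c in df.columns}
    if "time_h" not in cols or "od600" not in cols:
        raise FormatError(f"growth-curve file {path} needs columns time_h, od600")
    return GrowthCurve(
        times=df[cols["time_h"]].to_numpy(float),
        od600=df[cols["od600"]].to_numpy(float),
        strain=strain,
        medium=medium,
    )


def write_sector_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the tidy long-format sector-fraction table as CSV."""
    table.to_csv(path, index=False, encoding="utf-8")
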