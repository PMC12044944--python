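"""Curation of ChEMBL-style activity tables.

Raw activity exports list one assay measurement per row: a compound
identifier, a SMILES string, a relation symbol for the reported value
(``=``, ``<``, ``>``, ``/``), and a standard value in nM.  Curation keeps
only exact (``=``) IC50 measurements, converts them to pIC50
(−log10 of the molar concentration), collapses duplicate structures by
median pIC50, assigns activity labels by pIC50 cutoffs, and produces a
stratified train/independent-test split.  Every dropped row is audited
with a reason code so that input and output counts always reconcile.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .errors import (
    ConfigurationError,
    DomainError,
    EmptyDatasetError,
    InputError,
    StratificationError,
)

ACTIVE = "active"
INACTIVE = "inactive"
INTERMEDIATE = "intermediate"

#: default column mapping for ChEMBL CSV exports
DEFAULT_COLUMN_MAP = {
    "compound_id": "Molecule ChEMBL ID",
    "smiles": "Smiles",
    "relation": "Standard Relation",
    "value": "Standard Value",
    "units": "Standard Units",
    "assay_kind": "Assay Type",
}

#: default pIC50 activity cutoffs (configurable everywhere they are used)
DEFAULT_ACTIVE_CUTOFF = 6.0
DEFAULT_INACTIVE_CUTOFF = 5.0


@dataclass
class CompoundRecord:
    """A single assay measurement for one compound."""

    compound_id: str
    smiles: str
    relation: str
    standard_value: float | None = None  # nM
    assay_kind: str = ""
    pic50: float | None = None
    label: str | None = None

    def __post_init__(self):
        if self.standard_value is not None and not self.standard_value > 0:
            raise DomainError(
                f"standard_value must be > 0 nM, got {self.standard_value}"
            )
        if self.relation == "=" and self.pic50 is None and self.standard_value:
            self.pic50 = to_pic50(self.standard_value)


@dataclass
class DropRecord:
    """One audited row drop: input row index plus a reason code."""

    row: int
    reason: str  # "relation" | "missing value" | "smiles"
    detail: str = ""


@dataclass
class ParseResult:
    """Outcome of :func:`parse_activity_table`: retained records + audit."""

    records: list[CompoundRecord]
    drops: list[DropRecord]
    n_rows: int

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def drop_reasons(self) -> dict[str, int]:
        return dict(Counter(d.reason for d in self.drops))


@dataclass
class CuratedDataset:
    """Deduplicated, labeled dataset plus a drop audit."""

    records: list[CompoundRecord]
    n_active: int
    n_inactive: int
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if r.label == ACTIVE else 0 for r in self.records])

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.records],
                "canonical_smiles": [r.smiles for r in self.records],
                "pic50": [r.pic50 for r in self.records],
                "label": [r.label for r in self.records],
            }
        )

    def write_csv(self, path, audit_path=None) -> None:
        self.to_frame().to_csv(path, index=False)
        if audit_path is not None:
            with open(audit_path, "w") as fh:
                json.dump(self.provenance, fh, indent=2)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CuratedDataset":
        records = [
            CompoundRecord(
                compound_id=str(row.compound_id),
                smiles=row.canonical_smiles,
                relation="=",
                pic50=float(row.pic50),
                label=row.label,
            )
            for row in df.itertuples()
        ]
        n_act = sum(r.label == ACTIVE for r in records)
        n_inact = sum(r.label == INACTIVE for r in records)
        return cls(records, n_act, n_inact, {"source": "from_frame"})

    @classmethod
    def read_csv(cls, path) -> "CuratedDataset":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class SplitSpec:
    """Stratified train/test split parameters."""

    train_fraction: float = 0.75
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError(
                f"train_fraction must be in (0,1), got {self.train_fraction}"
            )


def to_pic50(standard_value: float) -> float:
    """Convert an IC50 in nM to pIC50 = −log10(IC50 in molar).

    1000 nM → 6.0; 1 nM → 9.0.  Strictly decreasing in the input.
    """
    if not standard_value > 0:
        raise DomainError(f"IC50 must be positive, got {standard_value}")
    return -math.log10(standard_value * 1e-9)


def label_activity(
    pic50: float,
    active_cutoff: float = DEFAULT_ACTIVE_CUTOFF,
    inactive_cutoff: float = DEFAULT_INACTIVE_CUTOFF,
) -> str:
    """Assign active / inactive / intermediate by pIC50 cutoffs.

    pic50 ≥ active_cutoff → active; pic50 < inactive_cutoff → inactive;
    the band in between is intermediate (excluded from modeling).
    """
    if active_cutoff < inactive_cutoff:
        raise ConfigurationError(
            f"active_cutoff ({active_cutoff}) < inactive_cutoff ({inactive_cutoff})"
        )
    if pic50 >= active_cutoff:
        return ACTIVE
    if pic50 < inactive_cutoff:
        return INACTIVE
    return INTERMEDIATE


def _clean_relation(raw) -> str:
    """Normalize a relation cell; ChEMBL exports quote it as ``'='``."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return ""
    return str(raw).strip().strip("'\"")


def parse_activity_table(
    path,
    column_map: dict | None = None,
    sep: str | None = None,
) -> ParseResult:
    """Parse a CSV/TSV activity table into compound records.

    Rows are retained only when the relation is exactly ``=`` and a
    positive standard value is present; any other row is dropped with an
    audited reason code (``relation``, ``missing value``, ``smiles``).
    Row order is preserved.  Deduplication is deferred to
    :func:`curate_dataset`.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise InputError(f"activity table {path} contains no rows")

    for key in ("smiles", "relation", "value"):
        if cmap[key] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {cmap[key]!r} (role {key!r}) not found; "
                f"available: {list(df.columns)}"
            )
    have_id = cmap["compound_id"] in df.columns
    have_assay = cmap["assay_kind"] in df.columns
    have_units = cmap["units"] in df.columns

    records: list[CompoundRecord] = []
    drops: list[DropRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        relation = _clean_relation(row[cmap["relation"]])
        if relation != "=":
            drops.append(DropRecord(i, "relation", relation or "(blank)"))
            continue
        value = row[cmap["value"]]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            drops.append(DropRecord(i, "missing value"))
            continue
        value = float(value)
        if value <= 0:
            drops.append(DropRecord(i, "missing value", "non-positive"))
            continue
        if have_units:
            units = str(row[cmap["units"]]).strip()
            if units in ("uM", "µM"):
                value *= 1e3
            elif units in ("M",):
                value *= 1e9
            elif units not in ("nM", "nan", ""):
                drops.append(DropRecord(i, "missing value", f"units {units}"))
                continue
        smiles = row[cmap["smiles"]]
        if not isinstance(smiles, str) or not smiles.strip():
            drops.append(DropRecord(i, "smiles", "(blank)"))
            continue
        records.append(
            CompoundRecord(
                compound_id=str(row[cmap["compound_id"]]) if have_id else f"row{i}",
                smiles=smiles.strip(),
                relation="=",
                standard_value=value,
                assay_kind=str(row[cmap["assay_kind"]]) if have_assay else "",
            )
        )
    return ParseResult(records=records, drops=drops, n_rows=len(df))


def curate_dataset(
    records,
    active_cutoff: float = DEFAULT_ACTIVE_CUTOFF,
    inactive_cutoff: float = DEFAULT_INACTIVE_CUTOFF,
    standardizer=None,
) -> CuratedDataset:
    """Deduplicate by canonical structure, label, and count the classes.

    Duplicate structures are aggregated by median pIC50 (robust to the
    occasional discordant assay).  Intermediates are counted in the audit
    but excluded from the dataset.  Idempotent: curating a curated
    dataset changes nothing.

    Parameters
    ----------
    standardizer : callable, optional
        SMILES → canonical-structure-key function.  Defaults to
        :func:`chemstack.featurize.standardize_structure`.  Unparsable
        structures are dropped with an audit entry.
    """
    if isinstance(records, ParseResult):
        records = records.records
    records = list(records)
    if standardizer is None:
        from .featurize import standardize_structure

        standardizer = standardize_structure

    from .errors import SmilesParseError

    by_key: dict[str, list[CompoundRecord]] = {}
    n_unparsable = 0
    for rec in records:
        try:
            key = standardizer(rec.smiles)
        except SmilesParseError:
            n_unparsable += 1
            continue
        by_key.setdefault(key, []).append(rec)

    curated: list[CompoundRecord] = []
    n_intermediate = 0
    n_duplicate_rows = 0
    for key, group in by_key.items():
        pics = [r.pic50 for r in group if r.pic50 is not None]
        if not pics:
            n_unparsable += 1
            continue
        n_duplicate_rows += len(group) - 1
        pic = float(np.median(pics))
        label = label_activity(pic, active_cutoff, inactive_cutoff)
        if label == INTERMEDIATE:
            n_intermediate += 1
            continue
        curated.append(
            replace(group[0], smiles=key, pic50=pic, label=label,
                    standard_value=None, relation="=")
        )

    n_active = sum(r.label == ACTIVE for r in curated)
    n_inactive = sum(r.label == INACTIVE for r in curated)
    if n_active + n_inactive == 0:
        raise EmptyDatasetError(
            "no active or inactive compounds remain after curation "
            f"({n_intermediate} intermediates, {n_unparsable} unparsable)"
        )
    provenance = {
        "n_input": len(records),
        "n_retained": len(curated),
        "n_active": n_active,
        "n_inactive": n_inactive,
        "n_intermediate_excluded": n_intermediate,
        "n_duplicate_rows_merged": n_duplicate_rows,
        "n_unparsable": n_unparsable,
        "active_cutoff": active_cutoff,
        "inactive_cutoff": inactive_cutoff,
        "duplicate_rule": "median pIC50 per canonical structure",
    }
    return CuratedDataset(curated, n_active, n_inactive, provenance)


def split_train_test(
    ds: CuratedDataset, spec: SplitSpec
) -> tuple[CuratedDataset, CuratedDataset]:
    """Stratified train/independent-test split of a curated dataset.

    Per-class counts land within ±1 of ``fraction × class size``;
    partitions are disjoint and deterministic under a fixed seed.
    """
    labels = [r.label for r in ds.records]
    for cls in (ACTIVE, INACTIVE):
        if labels.count(cls) < 2:
            raise StratificationError(
                f"class {cls!r} has {labels.count(cls)} member(s); "
                "need >= 2 to stratify"
            )
    idx = np.arange(len(ds.records))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=labels if spec.stratified else None,
        random_state=spec.seed,
    )

    def _subset(indices, part):
        recs = [ds.records[i] for i in sorted(indices)]
        return CuratedDataset(
            recs,
            sum(r.label == ACTIVE for r in recs),
            sum(r.label == INACTIVE for r in recs),
            {**ds.provenance, "partition": part, "seed": spec.seed,
             "train_fraction": spec.train_fraction},
        )

    return _subset(train_idx, "train"), _subset(test_idx, "test")
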