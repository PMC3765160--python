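"""Compound tables, activity transforms and file I/O.

The package ships a curated fixture of the published repellency dataset:
44 carboxamides (including DEET) and 27 assorted hydroxyl/ether/ester/
amine/nitro/halogen compounds form the 71-compound training set
(minimum effective dosage, MED, in µmol/cm²), and 23 hit-expansion
compounds form the evaluation set (µg/cm²; censored entries are flagged
with their assay ceiling).  Structures were curated by the package
authors from the published IUPAC names; the expansion compounds' names
and structures were published only as a figure, so those records carry
ids and dosages but no SMILES.

Units are stored per record exactly as published; there is no silent
µmol↔µg conversion.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, List, Optional, Sequence

from rdkit import Chem

__all__ = [
    "CompoundRecord",
    "ActivityVector",
    "load_training_set",
    "load_expansion_set",
    "log_activity",
    "read_records_csv",
    "write_records_csv",
    "write_smiles_file",
    "read_smiles_file",
    "write_sdf",
    "read_sdf",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompoundRecord:
    """One compound of the repellency dataset.

    ``med_obs``/``med_pred`` are dosages in ``units`` (µmol/cm² for the
    training tables, µg/cm² for the expansion table).  ``censored`` marks
    records whose activity was not observed below the assay ceiling
    (``censor_bound``); such records may still carry the ceiling as a
    numeric ``med_obs`` when the published model used it at face value.
    """

    id: str
    name: str
    smiles: str
    med_obs: Optional[float]
    med_pred: Optional[float]
    units: str
    censored: bool
    censor_bound: Optional[float]
    source_table: str

    def __post_init__(self):
        if self.med_obs is not None and self.med_obs <= 0:
            raise ValueError(f"{self.id}: MED must be positive, got {self.med_obs}")
        if self.censored and self.censor_bound is None:
            raise ValueError(f"{self.id}: censored record lacks a censoring bound")


@dataclass(frozen=True)
class ActivityVector:
    """Log-transformed activities aligned with a list of compound ids."""

    ids: tuple
    values: tuple  # log10 units, dimensionless
    direction: str  # "lower_med_more_active" or "higher_more_active"

    def __len__(self):
        return len(self.values)


def _parse_row(row: dict) -> CompoundRecord:
    def num(key):
        v = row.get(key, "").strip()
        return float(v) if v else None

    return CompoundRecord(
        id=row["id"].strip(),
        name=row.get("name", "").strip(),
        smiles=row.get("smiles", "").strip(),
        med_obs=num("med_obs"),
        med_pred=num("med_pred"),
        units=row.get("units", "").strip(),
        censored=row.get("censored", "false").strip().lower() == "true",
        censor_bound=num("censor_bound"),
        source_table=row.get("source_table", "").strip(),
    )


def _load_fixture() -> List[CompoundRecord]:
    try:
        text = (
            resources.files("repelqsar.data")
            .joinpath("compounds.csv")
            .read_text(encoding="utf-8")
        )
    except FileNotFoundError as exc:
        raise RuntimeError(
            "packaged fixture repelqsar/data/compounds.csv is missing"
        ) from exc
    records = [_parse_row(r) for r in csv.DictReader(io.StringIO(text))]
    if not records:
        raise RuntimeError("packaged fixture compounds.csv is empty or corrupt")
    return records


def load_training_set() -> List[CompoundRecord]:
    """The 71-compound training set (both training tables, incl. DEET).

    Every returned record has a parseable SMILES and a numeric MED; the
    five carboxamides published at the 25.0 µmol/cm² assay ceiling are
    additionally flagged censored so that fitting policies can exclude
    them (the published model retained them at face value).
    """
    recs = [
        r for r in _load_fixture() if r.source_table in ("table1", "table2")
    ]
    ids = [r.id for r in recs]
    if len(set(ids)) != len(ids):
        raise RuntimeError("duplicate compound ids in training fixture")
    for r in recs:
        if Chem.MolFromSmiles(r.smiles) is None:  # pragma: no cover
            raise RuntimeError(f"fixture SMILES for {r.id} does not parse")
    return recs


def load_expansion_set() -> List[CompoundRecord]:
    """The hit-expansion evaluation set (23 records, µg/cm²).

    Rows published as ">2.5" are censored with bound 2.5 and carry no
    numeric observed MED.  Structures for these compounds were published
    only graphically, so the records carry no SMILES.
    """
    return [r for r in _load_fixture() if r.source_table == "table5"]


def log_activity(
    records: Sequence[CompoundRecord],
    direction: str = "lower_med_more_active",
    censoring: str = "error",
) -> ActivityVector:
    """log10-transformed MEDs (the free-energy-linear activity scale).

    Parameters
    ----------
    direction:
        ``"lower_med_more_active"`` returns plain ``log10(MED)``;
        ``"higher_more_active"`` returns its negation so that larger
        values mean stronger repellency.
    censoring:
        ``"error"`` (default) refuses censored records, ``"exclude"``
        drops them with a warning, ``"use-bound"`` substitutes the
        censoring bound.  Records flagged censored that still carry a
        numeric observed MED (the assay-ceiling carboxamides) use that
        number except under ``"exclude"``.
    """
    if direction not in ("lower_med_more_active", "higher_more_active"):
        raise ValueError(f"unknown direction {direction!r}")
    ids, values = [], []
    for r in records:
        if r.censored:
            if censoring == "error":
                raise ValueError(
                    f"{r.id} is censored; pass censoring='exclude' or 'use-bound'"
                )
            if censoring == "exclude":
                log.warning("dropping censored record %s", r.id)
                continue
            med = r.med_obs if r.med_obs is not None else r.censor_bound
        else:
            med = r.med_obs
        if med is None:
            raise ValueError(f"{r.id} has no observed MED")
        if med <= 0:
            raise ValueError(f"{r.id}: MED must be positive for log transform")
        v = math.log10(med)
        values.append(-v if direction == "higher_more_active" else v)
        ids.append(r.id)
    return ActivityVector(ids=tuple(ids), values=tuple(values), direction=direction)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_CSV_FIELDS = [
    "id", "name", "smiles", "med_obs", "med_pred",
    "units", "censored", "censor_bound", "source_table",
]


def write_records_csv(records: Iterable[CompoundRecord], path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_FIELDS)
        for r in records:
            w.writerow(
                [
                    r.id, r.name, r.smiles,
                    "" if r.med_obs is None else repr(r.med_obs),
                    "" if r.med_pred is None else repr(r.med_pred),
                    r.units,
                    "true" if r.censored else "false",
                    "" if r.censor_bound is None else repr(r.censor_bound),
                    r.source_table,
                ]
            )


def read_records_csv(path: str) -> List[CompoundRecord]:
    with open(path, encoding="utf-8") as fh:
        return [_parse_row(r) for r in csv.DictReader(fh)]


def write_smiles_file(records: Iterable[CompoundRecord], path: str) -> None:
    """One record per line, ``SMILES<TAB>id``; structure-less records skipped."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            if r.smiles:
                fh.write(f"{r.smiles}\t{r.id}\n")


def read_smiles_file(path: str) -> List[tuple]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            out.append((parts[0], parts[1].strip() if len(parts) > 1 else ""))
    return out


def write_sdf(records: Iterable[CompoundRecord], path: str) -> None:
    """SDF export carrying the record metadata as SD tags."""
    writer = Chem.SDWriter(path)
    try:
        for r in records:
            if not r.smiles:
                continue
            mol = Chem.MolFromSmiles(r.smiles)
            mol.SetProp("_Name", r.id)
            mol.SetProp("name", r.name)
            if r.med_obs is not None:
                mol.SetProp("med_obs", repr(r.med_obs))
            if r.med_pred is not None:
                mol.SetProp("med_pred", repr(r.med_pred))
            mol.SetProp("units", r.units)
            mol.SetProp("censored", "true" if r.censored else "false")
            if r.censor_bound is not None:
                mol.SetProp("censor_bound", repr(r.censor_bound))
            mol.SetProp("source_table", r.source_table)
            writer.write(mol)
    finally:
        writer.close()


def read_sdf(path: str) -> List[CompoundRecord]:
    out = []
    for mol in Chem.SDMolSupplier(path):
        if mol is None:
            continue

        def prop(key, default=""):
            return mol.GetProp(key) if mol.HasProp(key) else default

        out.append(
            CompoundRecord(
                id=mol.GetProp("_Name"),
                name=prop("name"),
                smiles=Chem.MolToSmiles(mol),
                med_obs=float(prop("med_obs")) if mol.HasProp("med_obs") else None,
                med_pred=float(prop("med_pred")) if mol.HasProp("med_pred") else None,
                units=prop("units"),
                censored=prop("censored") == "true",
                censor_bound=(
                    float(prop("censor_bound"))
                    if mol.HasProp("censor_bound")
                    else None
                ),
                source_table=prop("source_table"),
            )
        )
    return out
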