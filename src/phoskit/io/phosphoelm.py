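"""Phospho.ELM-style tab-delimited report reader."""

from __future__ import annotations

import csv
import os
import warnings
from dataclasses import dataclass, field

from ..core import PHOSPHORYLATION, Protein, PTMAnnotation, Status
from ..errors import FormatError

#: Default column mapping, matching the public dump; override for dialect drift.
DEFAULT_COLUMNS = {
    "accession": "acc",
    "sequence": "sequence",
    "position": "position",
    "residue": "code",
}


@dataclass
class PhosphoElmResult:
    proteins: list[Protein] = field(default_factory=list)
    n_skipped: int = 0


def read_phosphoelm_report(
    path: str | os.PathLike, columns: dict[str, str] | None = None
) -> PhosphoElmResult:
    """Read a tab-delimited report with one phosphosite per row.

    Proteins are keyed by accession; every row adds one Phosphorylation
    annotation with source "Phospho.ELM" and experimental status. Rows whose
    residue letter disagrees with the sequence are skipped with a warning.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    result = PhosphoElmResult()
    by_acc: dict[str, Protein] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            return result
        missing = [c for c in cols.values() if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"report is missing required columns: {missing}")
        for row in reader:
            accession = row[cols["accession"]].strip()
            sequence = row[cols["sequence"]].strip().upper()
            position = int(row[cols["position"]])
            residue = row[cols["residue"]].strip().upper()
            protein = by_acc.get(accession)
            if protein is None:
                protein = Protein(accession=accession, sequence=sequence)
                by_acc[accession] = protein
                result.proteins.append(protein)
            if not 1 <= position <= len(protein.sequence) or (
                protein.sequence[position - 1] != residue
            ):
                warnings.warn(
                    f"{accession}: row residue {residue!r} at position {position} "
                    "does not match sequence; skipped"
                )
                result.n_skipped += 1
                continue
            key = (position, PHOSPHORYLATION)
            existing = protein.annotations.get(key)
            if existing is None:
                protein.annotations[key] = PTMAnnotation(
                    position=position,
                    residue=residue,
                    ptm_type=PHOSPHORYLATION,
                    sources={"Phospho.ELM"},
                    status=Status.EXPERIMENTAL,
                )
            else:
                existing.sources.add("Phospho.ELM")
    return result
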