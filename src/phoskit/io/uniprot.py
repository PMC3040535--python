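"""UniProt XML conversion: 'modified residue' features become PTM annotations.

A feature description beginning with ``Phospho`` yields a Phosphorylation
annotation; the modified residue is inferred from the description
(Phosphoserine -> S, Phosphothreonine -> T, Phosphotyrosine -> Y) and checked
against the sequence. Evidence status is parsed from legacy description
qualifiers ("; by similarity", "; probable", "; potential"; none ->
experimental). Non-phospho modified residues are retained with the
description text as their PTM type.
"""

from __future__ import annotations

import os
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from ..core import PHOSPHORYLATION, Protein, PTMAnnotation, Status
from ..errors import FormatError

NS = "{http://uniprot.org/uniprot}"

_PHOSPHO_RESIDUE = {
    "phosphoserine": "S",
    "phosphothreonine": "T",
    "phosphotyrosine": "Y",
    "phosphohistidine": "H",
    "phosphoaspartate": "D",
    "phosphocysteine": "C",
}

_QUALIFIER_STATUS = {
    "by similarity": Status.BY_SIMILARITY,
    "probable": Status.PROBABLE,
    "potential": Status.POTENTIAL,
}


def _parse_description(description: str) -> tuple[str, Status]:
    """Split a feature description into (base text, evidence status)."""
    parts = [p.strip() for p in description.split(";")]
    base = parts[0]
    status = Status.EXPERIMENTAL
    for qualifier in parts[1:]:
        q = qualifier.lower()
        if q in _QUALIFIER_STATUS:
            status = _QUALIFIER_STATUS[q]
    return base, status


@dataclass
class UniProtConversion:
    proteins: list[Protein] = field(default_factory=list)
    skipped: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def convert_uniprot_xml(
    path: str | os.PathLike, status_filter: set[Status] | None = None
) -> UniProtConversion:
    """Convert a UniProt XML entry stream to proteins with PTM annotations.

    ``status_filter`` keeps only annotations whose status is in the set
    (default: all four statuses). Features whose stated residue disagrees
    with the sequence are skipped with a warning and counted.
    """
    if status_filter is None:
        status_filter = set(Status)
    else:
        status_filter = {Status(s) if isinstance(s, str) else s for s in status_filter}
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise FormatError(f"malformed UniProt XML in {path}: {exc}") from exc
    result = UniProtConversion()
    for entry in tree.getroot().findall(f"{NS}entry"):
        acc_el = entry.find(f"{NS}accession")
        seq_el = entry.find(f"{NS}sequence")
        if acc_el is None or seq_el is None or not (seq_el.text or "").strip():
            continue
        accession = acc_el.text.strip()
        sequence = "".join((seq_el.text or "").split()).upper()
        name_el = entry.find(f"{NS}name")
        protein = Protein(
            accession=accession,
            sequence=sequence,
            name=name_el.text.strip() if name_el is not None and name_el.text else None,
        )
        for feat in entry.findall(f"{NS}feature"):
            if feat.get("type") != "modified residue":
                continue
            pos_el = feat.find(f"{NS}location/{NS}position")
            if pos_el is None:
                continue
            position = int(pos_el.get("position"))
            base, status = _parse_description(feat.get("description", ""))
            if status not in status_filter:
                continue
            expected = _PHOSPHO_RESIDUE.get(base.lower())
            if not 1 <= position <= len(sequence):
                warnings.warn(
                    f"{accession}: feature position {position} outside sequence; skipped"
                )
                result.skipped.append((accession, position, base))
                continue
            actual = sequence[position - 1]
            if expected is not None and actual != expected:
                warnings.warn(
                    f"{accession}: {base} at position {position} but sequence has "
                    f"{actual!r}; skipped"
                )
                result.skipped.append((accession, position, base))
                continue
            ptm_type = PHOSPHORYLATION if base.lower().startswith("phospho") else base
            protein.annotations[(position, ptm_type)] = PTMAnnotation(
                position=position,
                residue=actual,
                ptm_type=ptm_type,
                sources={"UniProt"},
                status=status,
            )
        result.proteins.append(protein)
    return result
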