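"""Native PTM XML dialect: lossless round trip for proteins with annotations
and per-residue score tracks.

Schema (UTF-8, 1-based positions)::

    <musite>
      <protein accession="P1" name="optional">
        <sequence>MSTK...</sequence>
        <ptm type="Phosphorylation" position="2" residue="S" status="experimental">
          <source>UniProt</source>
        </ptm>
        <track name="disorder">0.12,0.5,...</track>
      </protein>
    </musite>
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from typing import Iterable

from ..core import Protein, PTMAnnotation, Status
from ..errors import FormatError


def read_ptm_xml(path: str | os.PathLike) -> list[Protein]:
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise FormatError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    proteins = []
    for pel in root.findall("protein"):
        accession = pel.get("accession")
        if not accession:
            raise FormatError("protein element without accession attribute")
        seq_el = pel.find("sequence")
        sequence = (seq_el.text or "").strip() if seq_el is not None else ""
        protein = Protein(
            accession=accession, sequence=sequence, name=pel.get("name") or None
        )
        for ptm in pel.findall("ptm"):
            position = int(ptm.get("position"))
            residue = ptm.get("residue")
            ptm_type = ptm.get("type")
            if not 1 <= position <= len(sequence):
                raise FormatError(
                    f"{accession}: ptm position {position} outside 1..{len(sequence)}"
                )
            if sequence[position - 1] != residue:
                raise FormatError(
                    f"{accession}: ptm residue {residue!r} at position {position} "
                    f"does not match sequence residue {sequence[position - 1]!r}"
                )
            sources = {s.text for s in ptm.findall("source") if s.text}
            protein.annotations[(position, ptm_type)] = PTMAnnotation(
                position=position,
                residue=residue,
                ptm_type=ptm_type,
                sources=sources or {"unknown"},
                status=Status(ptm.get("status", "experimental")),
            )
        for track in pel.findall("track"):
            text = (track.text or "").strip()
            values = [float(v) for v in text.split(",")] if text else []
            protein.add_track(track.get("name"), values)
        proteins.append(protein)
    return proteins


def write_ptm_xml(proteins: Iterable[Protein], path: str | os.PathLike) -> None:
    root = ET.Element("musite")
    for p in proteins:
        attrs = {"accession": p.accession}
        if p.name:
            attrs["name"] = p.name
        pel = ET.SubElement(root, "protein", attrs)
        ET.SubElement(pel, "sequence").text = p.sequence
        for key in sorted(p.annotations):
            ann = p.annotations[key]
            ptm = ET.SubElement(
                pel,
                "ptm",
                {
                    "type": ann.ptm_type,
                    "position": str(ann.position),
                    "residue": ann.residue,
                    "status": ann.status.value,
                },
            )
            for source in sorted(ann.sources):
                ET.SubElement(ptm, "source").text = source
        for tname in sorted(p.tracks):
            tel = ET.SubElement(pel, "track", {"name": tname})
            # repr round-trips floats exactly through read_ptm_xml
            tel.text = ",".join(repr(v) for v in p.tracks[tname])
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), encoding="utf-8", xml_declaration=True)
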