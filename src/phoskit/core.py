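"""Core data model: proteins, PTM annotations, candidate sites, and dataset
construction.

Coordinates are 1-based throughout, following the UniProt convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import AnnotationError, DatasetError, MergeConflictError

PHOSPHORYLATION = "Phosphorylation"

#: Letters accepted in sequences besides the 20 standard amino acids.
NONSTANDARD_LETTERS = frozenset("XUBZ")
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class Status(enum.Enum):
    """Annotation evidence status, ordered from strongest to weakest."""

    EXPERIMENTAL = "experimental"
    PROBABLE = "probable"
    POTENTIAL = "potential"
    BY_SIMILARITY = "by_similarity"

    @property
    def rank(self) -> int:
        return _STATUS_RANK[self]


_STATUS_RANK = {
    Status.EXPERIMENTAL: 0,
    Status.PROBABLE: 1,
    Status.POTENTIAL: 2,
    Status.BY_SIMILARITY: 3,
}


def strongest_status(a: Status, b: Status) -> Status:
    return a if a.rank <= b.rank else b


@dataclass
class PTMAnnotation:
    """One modified residue. ``(position, ptm_type)`` is unique per protein."""

    position: int
    residue: str
    ptm_type: str = PHOSPHORYLATION
    sources: set[str] = field(default_factory=set)
    status: Status = Status.EXPERIMENTAL

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("annotation must carry at least one source")
        if isinstance(self.status, str):
            self.status = Status(self.status)

    def copy(self) -> "PTMAnnotation":
        return PTMAnnotation(
            self.position, self.residue, self.ptm_type, set(self.sources), self.status
        )


@dataclass
class Protein:
    """An identified amino-acid sequence with PTM annotations and optional
    per-residue score tracks (e.g. ``"disorder"``)."""

    accession: str
    sequence: str
    name: str | None = None
    annotations: dict[tuple[int, str], PTMAnnotation] = field(default_factory=dict)
    tracks: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_at(self, position: int) -> str:
        """1-based residue lookup."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]

    def annotations_of(self, ptm_type: str) -> list[PTMAnnotation]:
        return sorted(
            (a for a in self.annotations.values() if a.ptm_type == ptm_type),
            key=lambda a: a.position,
        )

    def phospho_positions(self) -> set[int]:
        return {a.position for a in self.annotations.values() if a.ptm_type == PHOSPHORYLATION}

    def is_phosphoprotein(self) -> bool:
        return bool(self.phospho_positions())

    def add_track(self, name: str, values: Sequence[float]) -> None:
        if len(values) != len(self.sequence):
            raise ValueError(
                f"track '{name}' has length {len(values)}, sequence has {len(self.sequence)}"
            )
        self.tracks[name] = list(values)

    def copy(self) -> "Protein":
        return Protein(
            accession=self.accession,
            sequence=self.sequence,
            name=self.name,
            annotations={k: a.copy() for k, a in self.annotations.items()},
            tracks={k: list(v) for k, v in self.tracks.items()},
        )


class Label(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNLABELED = "unlabeled"


class NegativePolicy(enum.Enum):
    """Universe from which negative sites are drawn when building datasets."""

    PHOSPHOPROTEINS_ONLY = "phosphoproteins_only"
    ALL_PROTEINS = "all_proteins"


@dataclass(frozen=True)
class CandidateSite:
    protein_accession: str
    position: int
    residue: str
    label: Label


@dataclass
class SiteStatistics:
    n_proteins: int
    n_phosphoproteins: int
    per_residue_site_counts: dict[str, int]


def annotate_site(
    protein: Protein,
    position: int,
    residue: str,
    ptm_type: str = PHOSPHORYLATION,
    source: str = "user",
    status: Status = Status.EXPERIMENTAL,
) -> Protein:
    """Add a PTM annotation in place; returns the protein for chaining.

    Idempotent: re-adding the same ``(position, ptm_type)`` merges sources and
    keeps the strongest status (experimental > probable > potential >
    by_similarity). Rejects annotations whose residue letter disagrees with
    the sequence.
    """
    if not 1 <= position <= len(protein.sequence):
        raise AnnotationError(
            f"{protein.accession}: position {position} outside 1..{len(protein.sequence)}"
        )
    actual = protein.residue_at(position)
    if actual != residue.upper():
        raise AnnotationError(
            f"{protein.accession}: annotation residue {residue!r} at position "
            f"{position} does not match sequence residue {actual!r}"
        )
    if isinstance(status, str):
        status = Status(status)
    key = (position, ptm_type)
    existing = protein.annotations.get(key)
    if existing is None:
        protein.annotations[key] = PTMAnnotation(
            position=position,
            residue=actual,
            ptm_type=ptm_type,
            sources={source},
            status=status,
        )
    else:
        existing.sources.add(source)
        existing.status = strongest_status(existing.status, status)
    return protein


def merge_annotations(
    primary: Iterable[Protein], secondary: Iterable[Protein]
) -> list[Protein]:
    """Union annotation sets of proteins matched by accession.

    Sequences for shared accessions must be identical — conflicting sequences
    raise :class:`MergeConflictError` rather than silently remapping
    coordinates. Proteins unique to either input are retained. Output order:
    primary order, then new secondary proteins in their input order.
    """
    merged: dict[str, Protein] = {}
    order: list[str] = []
    for p in primary:
        merged[p.accession] = p.copy()
        order.append(p.accession)
    for p in secondary:
        if p.accession not in merged:
            merged[p.accession] = p.copy()
            order.append(p.accession)
            continue
        target = merged[p.accession]
        if target.sequence != p.sequence:
            raise MergeConflictError(
                f"accession {p.accession}: sequences differ between inputs"
            )
        for ann in p.annotations.values():
            for source in sorted(ann.sources):
                annotate_site(
                    target, ann.position, ann.residue, ann.ptm_type, source, ann.status
                )
        for tname, tvals in p.tracks.items():
            target.tracks.setdefault(tname, list(tvals))
    return [merged[acc] for acc in order]


def enumerate_candidate_sites(
    protein: Protein,
    residue_types: set[str] | frozenset[str],
    phosphoproteins_only: bool = False,
) -> list[CandidateSite]:
    """One candidate per matching residue, ascending by position.

    A site is positive when a Phosphorylation annotation exists at its
    position, otherwise negative. With ``phosphoproteins_only`` active,
    unannotated residues of proteins that carry no phospho-annotation at all
    are labeled :attr:`Label.UNLABELED` instead of negative.
    """
    if not residue_types:
        raise ValueError("residue_types must be non-empty")
    residue_types = {r.upper() for r in residue_types}
    positives = protein.phospho_positions()
    no_phospho = not positives
    sites = []
    for i, aa in enumerate(protein.sequence, start=1):
        if aa not in residue_types:
            continue
        if i in positives:
            label = Label.POSITIVE
        elif phosphoproteins_only and no_phospho:
            label = Label.UNLABELED
        else:
            label = Label.NEGATIVE
        sites.append(CandidateSite(protein.accession, i, aa, label))
    return sites


def site_statistics(
    proteins: Iterable[Protein], ptm_type: str = PHOSPHORYLATION
) -> SiteStatistics:
    """Count proteins, proteins carrying the PTM, and sites per residue letter."""
    n_proteins = 0
    n_modified = 0
    counts: dict[str, int] = {}
    for p in proteins:
        n_proteins += 1
        anns = p.annotations_of(ptm_type)
        if anns:
            n_modified += 1
        for a in anns:
            counts[a.residue] = counts.get(a.residue, 0) + 1
    return SiteStatistics(n_proteins, n_modified, counts)


@dataclass
class Dataset:
    """Non-redundant labeled site collection with parallel windows.

    ``windows`` holds :class:`~phoskit.features.SiteWindow` objects; the type
    lives in :mod:`phoskit.features` to keep this module dependency-free.
    """

    sites: list[CandidateSite]
    windows: list
    residue_types: frozenset[str]
    half_width: int

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def labels(self) -> list[Label]:
        return [s.label for s in self.sites]

    def n_positive(self) -> int:
        return sum(1 for s in self.sites if s.label is Label.POSITIVE)

    def n_negative(self) -> int:
        return sum(1 for s in self.sites if s.label is Label.NEGATIVE)


def build_nonredundant_dataset(
    proteins: Iterable[Protein],
    residue_types: set[str],
    half_width: int = 12,
    negative_policy: NegativePolicy = NegativePolicy.PHOSPHOPROTEINS_ONLY,
) -> Dataset:
    """Enumerate candidate sites, extract windows, and deduplicate.

    Redundancy handling:

    * exact-duplicate window peptides with equal labels collapse to the first
      occurrence;
    * a peptide seen with both labels keeps the positive and drops the
      negative (a verified positive dominates an unverified absence);
    * under :attr:`NegativePolicy.PHOSPHOPROTEINS_ONLY` negatives come only
      from proteins bearing at least one phospho-annotation.
    """
    from .features import extract_window  # local import: avoid cycle

    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    if isinstance(negative_policy, str):
        negative_policy = NegativePolicy(negative_policy)
    phospho_only = negative_policy is NegativePolicy.PHOSPHOPROTEINS_ONLY

    seen: dict[str, int] = {}  # peptide -> index into out lists
    out_sites: list[CandidateSite] = []
    out_windows: list = []
    for protein in proteins:
        for site in enumerate_candidate_sites(
            protein, residue_types, phosphoproteins_only=phospho_only
        ):
            if site.label is Label.UNLABELED:
                continue
            window = extract_window(protein.sequence, site.position, half_width)
            idx = seen.get(window.peptide)
            if idx is None:
                seen[window.peptide] = len(out_sites)
                out_sites.append(site)
                out_windows.append(window)
            elif site.label is Label.POSITIVE and out_sites[idx].label is Label.NEGATIVE:
                out_sites[idx] = site
                out_windows[idx] = window
    dataset = Dataset(
        sites=out_sites,
        windows=out_windows,
        residue_types=frozenset(r.upper() for r in residue_types),
        half_width=half_width,
    )
    if dataset.n_positive() == 0:
        raise DatasetError("dataset contains no positive sites; cannot train")
    return dataset
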