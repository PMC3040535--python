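"""Synthetic phosphoproteome generator with planted, learnable signal.

Sequences are drawn from a fixed background amino-acid composition. A
configurable fraction of S/T residues become annotated phosphosites; each
positive site carries a planted motif context (R at -3, P at +1) with high
probability, while background sites receive it only rarely. Disorder tracks
are drawn from a two-component model (elevated around positive sites) and
smoothed, so all three feature families carry signal. Everything is
deterministic given the seed.

The planted motif is an arbitrary kinase-like context chosen purely to make
the signal learnable; it asserts nothing about real kinases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Protein, Status, annotate_site

# Average amino-acid composition of well-curated proteomes (percent).
BACKGROUND_COMPOSITION = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}

MOTIF_OFFSETS = {-3: "R", 1: "P"}  # relative to the phospho-acceptor
DISORDER_HALO = 7  # residues on each side of a positive site with elevated disorder
SMOOTH_WIDTH = 11
MIN_LENGTH = 30


@dataclass(frozen=True)
class SyntheticConfig:
    n_proteins: int = 200
    mean_length: int = 400
    phospho_prevalence: float = 0.05
    motif_strength: float = 0.8
    background_motif_rate: float = 0.05
    disorder_positive_mean: float = 0.7
    disorder_negative_mean: float = 0.4
    disorder_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for name in ("phospho_prevalence", "motif_strength", "background_motif_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    half = width // 2
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def generate_proteome(config: SyntheticConfig | None = None) -> list[Protein]:
    """Generate annotated proteins with populated "disorder" tracks."""
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    letters = np.array(list(BACKGROUND_COMPOSITION))
    probs = np.array(list(BACKGROUND_COMPOSITION.values()))
    probs = probs / probs.sum()

    proteins = []
    for i in range(config.n_proteins):
        length = max(MIN_LENGTH, int(rng.geometric(1.0 / config.mean_length)))
        seq = rng.choice(letters, size=length, p=probs)

        st_positions = np.flatnonzero(np.isin(seq, ["S", "T"])) + 1  # 1-based
        is_positive = rng.random(len(st_positions)) < config.phospho_prevalence
        positive_set = set(st_positions[is_positive].tolist())

        # plant the motif context; never overwrite a positive acceptor residue
        for pos, positive in zip(st_positions.tolist(), is_positive.tolist()):
            rate = config.motif_strength if positive else config.background_motif_rate
            if rng.random() >= rate:
                continue
            for offset, residue in MOTIF_OFFSETS.items():
                target = pos + offset
                if 1 <= target <= length and target not in positive_set:
                    seq[target - 1] = residue

        sequence = "".join(seq)
        protein = Protein(accession=f"SYN{i:05d}", sequence=sequence)
        for pos in sorted(positive_set):
            annotate_site(
                protein, pos, sequence[pos - 1],
                source="synthetic", status=Status.EXPERIMENTAL,
            )

        raw = rng.normal(config.disorder_negative_mean, config.disorder_sd, length)
        for pos in sorted(positive_set):
            lo = max(0, pos - 1 - DISORDER_HALO)
            hi = min(length - 1, pos - 1 + DISORDER_HALO)
            raw[lo : hi + 1] = rng.normal(
                config.disorder_positive_mean, config.disorder_sd, hi - lo + 1
            )
        track = np.clip(_smooth(np.clip(raw, 0.0, 1.0), SMOOTH_WIDTH), 0.0, 1.0)
        protein.add_track("disorder", track.tolist())
        proteins.append(protein)
    return proteins


def split_holdout(
    proteins: list[Protein], fraction: float, seed: int = 0
) -> tuple[list[Protein], list[Protein]]:
    """Protein-level split: ``round(fraction * n)`` proteins in the first
    side, the rest in the second, no overlap, input order preserved."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(proteins))
    n_first = int(round(fraction * len(proteins)))
    first = sorted(order[:n_first].tolist())
    second = sorted(order[n_first:].tolist())
    return [proteins[i] for i in first], [proteins[i] for i in second]
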