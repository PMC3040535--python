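"""End-to-end training and prediction with specificity-calibrated stringency.

Training builds a non-redundant labeled dataset, extracts features (KNN
scores computed with leave-self-out against the dataset itself), runs 5-fold
cross-validation to pool decision values of held-out *negative* sites into an
empirical calibration curve, then retrains the bagging ensemble on all data.
The calibration curve turns a raw decision threshold into an estimated
specificity — the fraction of true negatives scoring below it — so users can
dial prediction stringency continuously.
"""

from __future__ import annotations

import io
import json
import os
import warnings
import zipfile
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classifiers import BaggingConfig, BaggingEnsemble, predict_bagging, train_bagging
from .core import (
    Dataset,
    Label,
    NegativePolicy,
    Protein,
    build_nonredundant_dataset,
    enumerate_candidate_sites,
)
from .errors import MissingTrackError, PhoskitError, TrainingError
from .features import (
    DEFAULT_HALF_WIDTH,
    KNNConfig,
    aa_frequencies,
    default_disorder_track,
    disorder_feature,
    encode_windows,
    extract_window,
    feature_layout,
    knn_score_matrix,
)

FORMAT_VERSION = 1
MIN_POSITIVES = 30
WARN_POSITIVES = 100
MIN_CALIBRATION = 50
DEFAULT_STRINGENCY = 0.95


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class CalibrationCurve:
    """Ascending decision values of held-out negative sites."""

    sorted_negative_scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.sorted_negative_scores, dtype=np.float64)
        if scores.size and np.any(np.diff(scores) < 0):
            scores = np.sort(scores)
        self.sorted_negative_scores = scores

    @property
    def n(self) -> int:
        return int(self.sorted_negative_scores.size)


def estimate_specificity(curve: CalibrationCurve, threshold: float) -> float:
    """Fraction of calibration negatives below ``threshold``, with linear
    interpolation between adjacent order statistics."""
    s = curve.sorted_negative_scores
    if s.size == 0:
        raise ValueError("calibration curve is empty")
    if s.size == 1:
        return 0.0 if threshold <= s[0] else 1.0
    grid = np.linspace(0.0, 1.0, s.size)
    return float(np.interp(threshold, s, grid, left=0.0, right=1.0))


def threshold_for_stringency(curve: CalibrationCurve, stringency: float) -> float:
    """Score threshold whose estimated specificity equals ``stringency``.

    The stringency-quantile of the negative score distribution; inverse of
    :func:`estimate_specificity` up to interpolation.
    """
    if not 0.0 < stringency < 1.0:
        raise ValueError(f"stringency must be in (0, 1), got {stringency}")
    s = curve.sorted_negative_scores
    if s.size == 0:
        raise ValueError("calibration curve is empty")
    return float(np.quantile(s, stringency, method="linear"))


# ---------------------------------------------------------------------------
# Training configuration and model


@dataclass(frozen=True)
class TrainConfig:
    half_width: int = DEFAULT_HALF_WIDTH
    knn: KNNConfig = field(default_factory=KNNConfig)
    bagging: BaggingConfig = field(default_factory=BaggingConfig)
    negative_policy: NegativePolicy = NegativePolicy.PHOSPHOPROTEINS_ONLY
    n_folds: int = 5
    disorder_track: str = "disorder"
    disorder_provider: str = "builtin"  # "builtin" | "track"
    reference_cap: int = 20000
    seed: int = 0


@dataclass
class PredictionModel:
    """Trained ensemble plus everything prediction needs: feature
    configuration, calibration curve, and the labeled reference windows
    required to compute KNN features for new queries."""

    name: str
    residue_types: frozenset[str]
    half_width: int
    knn_config: KNNConfig
    disorder_provider: str
    disorder_track: str
    ensemble: BaggingEnsemble
    calibration: CalibrationCurve
    reference_peptides: list[str]
    reference_positive: np.ndarray
    comments: str = ""
    created: str = ""
    format_version: int = FORMAT_VERSION


def _disorder_track_for(protein: Protein, config_track: str, provider: str) -> list[float]:
    track = protein.tracks.get(config_track)
    if track is not None:
        return track
    if provider == "builtin":
        return default_disorder_track(protein.sequence)
    raise MissingTrackError(
        f"protein {protein.accession} has no '{config_track}' track and the "
        "disorder provider is 'track'; run disorder prediction first "
        "(see the `disorder` command)"
    )


def _feature_matrix_for_dataset(
    dataset: Dataset, proteins_by_acc: dict[str, Protein], config: TrainConfig
) -> np.ndarray:
    enc = encode_windows(dataset.windows)
    positive = np.array(
        [s.label is Label.POSITIVE for s in dataset.sites], dtype=np.float64
    )
    selfs = np.arange(len(dataset), dtype=np.int64) if config.knn.exclude_self else None
    knn = knn_score_matrix(enc, enc, positive, config.knn, self_indices=selfs)
    disorder = np.empty(len(dataset), dtype=np.float64)
    tracks: dict[str, list[float]] = {}
    for i, site in enumerate(dataset.sites):
        acc = site.protein_accession
        if acc not in tracks:
            tracks[acc] = _disorder_track_for(
                proteins_by_acc[acc], config.disorder_track, config.disorder_provider
            )
        disorder[i] = disorder_feature(tracks[acc], site.position, config.half_width)
    freqs = np.stack([aa_frequencies(w) for w in dataset.windows])
    return np.hstack([knn, disorder[:, None], freqs])


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Deterministic stratified fold assignment (round-robin after shuffle)."""
    fold = np.empty(len(y), dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def train_model(
    proteins: Iterable[Protein],
    residue_types: set[str],
    config: TrainConfig | None = None,
    name: str = "model",
    comments: str = "",
    created: str = "",
) -> PredictionModel:
    """Train a prediction model end to end (see module docstring)."""
    if config is None:
        config = TrainConfig()
    proteins = list(proteins)
    by_acc = {p.accession: p for p in proteins}
    dataset = build_nonredundant_dataset(
        proteins, residue_types, config.half_width, config.negative_policy
    )
    n_pos = dataset.n_positive()
    if n_pos < MIN_POSITIVES:
        raise TrainingError(
            f"only {n_pos} positive sites for residue types "
            f"{sorted(residue_types)}; at least {MIN_POSITIVES} required"
        )
    if n_pos < WARN_POSITIVES:
        warnings.warn(
            f"only {n_pos} positive sites; models trained on fewer than "
            f"{WARN_POSITIVES} positives may be unreliable"
        )

    X = _feature_matrix_for_dataset(dataset, by_acc, config)
    y = np.array([s.label is Label.POSITIVE for s in dataset.sites], dtype=int)
    layout = feature_layout(config.knn)

    # cross-validated pooling of held-out negative scores
    rng = np.random.default_rng([config.seed, 101])
    fold = _stratified_folds(y, config.n_folds, rng)
    negative_scores = []
    for f in range(config.n_folds):
        train_mask = fold != f
        held = np.flatnonzero(~train_mask)
        if not len(held):
            continue
        fold_cfg = replace(config.bagging, seed=int(config.bagging.seed + 1000 * (f + 1)))
        ensemble = train_bagging(X[train_mask], y[train_mask], fold_cfg, layout)
        scores = predict_bagging(ensemble, X[held])
        negative_scores.append(scores[y[held] == 0])
    pooled = np.sort(np.concatenate(negative_scores))
    if pooled.size < MIN_CALIBRATION:
        warnings.warn(
            f"calibration curve built from only {pooled.size} held-out negatives "
            f"(< {MIN_CALIBRATION}); specificity estimates will be coarse"
        )
    calibration = CalibrationCurve(pooled)

    final_ensemble = train_bagging(X, y, config.bagging, layout)

    # reference windows for predict-time KNN features, optionally down-sampled
    peptides = [w.peptide for w in dataset.windows]
    positive = y.astype(bool)
    if len(peptides) > config.reference_cap:
        keep_pos = np.flatnonzero(positive)
        neg = np.flatnonzero(~positive)
        n_keep_neg = max(0, config.reference_cap - len(keep_pos))
        rng_ref = np.random.default_rng([config.seed, 777])
        keep_neg = np.sort(rng_ref.choice(neg, size=n_keep_neg, replace=False))
        keep = np.sort(np.concatenate([keep_pos, keep_neg]))
        peptides = [peptides[i] for i in keep]
        positive = positive[keep]

    return PredictionModel(
        name=name,
        comments=comments,
        created=created,
        residue_types=frozenset(r.upper() for r in residue_types),
        half_width=config.half_width,
        knn_config=config.knn,
        disorder_provider=config.disorder_provider,
        disorder_track=config.disorder_track,
        ensemble=final_ensemble,
        calibration=calibration,
        reference_peptides=peptides,
        reference_positive=np.asarray(positive, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Prediction


RESULT_COLUMNS = ["accession", "position", "residue", "score", "est_specificity", "passes"]


@dataclass
class PredictionResult:
    """Per-site predictions, ordered by accession then position."""

    table: pd.DataFrame
    stringency: float
    threshold: float

    def __len__(self) -> int:
        return len(self.table)

    def n_passing(self) -> int:
        return int(self.table["passes"].sum())

    def to_tsv(self, path: str | os.PathLike) -> None:
        out = self.table.copy()
        out["score"] = out["score"].map(lambda v: f"{v:.6f}")
        out["est_specificity"] = out["est_specificity"].map(lambda v: f"{v:.6f}")
        out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def classify(
    model: PredictionModel,
    query_proteins: Iterable[Protein],
    stringency: float = DEFAULT_STRINGENCY,
) -> PredictionResult:
    """Score every residue of the model's residue types in the queries.

    KNN features are computed against the model's stored reference windows
    (no self-exclusion); disorder comes from each protein's stored track or
    the built-in provider.
    """
    if model.format_version > FORMAT_VERSION:
        raise PhoskitError(
            f"model format_version {model.format_version} is newer than supported "
            f"({FORMAT_VERSION})"
        )
    threshold = threshold_for_stringency(model.calibration, stringency)
    ref_enc = encode_windows(model.reference_peptides)
    ref_positive = model.reference_positive.astype(np.float64)

    rows = []
    windows = []
    disorder = []
    for protein in sorted(query_proteins, key=lambda p: p.accession):
        sites = enumerate_candidate_sites(protein, model.residue_types)
        if not sites:
            continue
        track = _disorder_track_for(protein, model.disorder_track, model.disorder_provider)
        for site in sites:
            windows.append(extract_window(protein.sequence, site.position, model.half_width))
            disorder.append(disorder_feature(track, site.position, model.half_width))
            rows.append((protein.accession, site.position, site.residue))

    if rows:
        enc = encode_windows(windows)
        knn = knn_score_matrix(enc, ref_enc, ref_positive, model.knn_config)
        freqs = np.stack([aa_frequencies(w) for w in windows])
        X = np.hstack([knn, np.asarray(disorder)[:, None], freqs])
        scores = predict_bagging(model.ensemble, X)
        grid = np.linspace(0.0, 1.0, model.calibration.n)
        spec = np.interp(
            scores, model.calibration.sorted_negative_scores, grid, left=0.0, right=1.0
        )
        passes = scores >= threshold
    else:
        scores = spec = passes = []

    table = pd.DataFrame(
        {
            "accession": [r[0] for r in rows],
            "position": pd.Series([r[1] for r in rows], dtype=np.int64),
            "residue": [r[2] for r in rows],
            "score": pd.Series(scores, dtype=np.float64),
            "est_specificity": pd.Series(spec, dtype=np.float64),
            "passes": pd.Series(passes, dtype=bool),
        }
    )
    return PredictionResult(table=table, stringency=stringency, threshold=threshold)


def filter_predictions(
    result: PredictionResult,
    min_specificity: float = 0.0,
    residues: set[str] | None = None,
) -> PredictionResult:
    """Keep rows meeting the criteria; order preserved."""
    mask = result.table["est_specificity"] >= min_specificity
    if residues is not None:
        mask &= result.table["residue"].isin({r.upper() for r in residues})
    return PredictionResult(
        table=result.table[mask].reset_index(drop=True),
        stringency=result.stringency,
        threshold=result.threshold,
    )


def model_edit(
    model: PredictionModel,
    new_name: str | None = None,
    comments: str | None = None,
) -> PredictionModel:
    """Rename or re-comment a model; everything else is untouched."""
    edited = replace(model)
    if new_name is not None:
        edited.name = new_name
    if comments is not None:
        edited.comments = comments
    return edited


# ---------------------------------------------------------------------------
# Model archive (zip of JSON + TSV; fixed entry timestamps for determinism)


def _knn_config_to_dict(cfg: KNNConfig) -> dict:
    return {
        "k_fractions": list(cfg.k_fractions),
        "matrix_name": cfg.matrix_name,
        "matrix_entries": [list(e) for e in cfg.matrix_entries]
        if cfg.matrix_entries is not None
        else None,
        "exclude_self": cfg.exclude_self,
    }


def _knn_config_from_dict(d: dict) -> KNNConfig:
    entries = d.get("matrix_entries")
    return KNNConfig(
        k_fractions=tuple(d["k_fractions"]),
        matrix_name=d["matrix_name"],
        matrix_entries=tuple((a, b, float(v)) for a, b, v in entries)
        if entries is not None
        else None,
        exclude_self=bool(d["exclude_self"]),
    )


def save_model(model: PredictionModel, path: str | os.PathLike) -> None:
    meta = {
        "format_version": model.format_version,
        "name": model.name,
        "comments": model.comments,
        "created": model.created,
        "residue_types": sorted(model.residue_types),
        "half_width": model.half_width,
        "knn_config": _knn_config_to_dict(model.knn_config),
        "disorder_provider": model.disorder_provider,
        "disorder_track": model.disorder_track,
        "ensemble": model.ensemble.to_dict(),
        "calibration": model.calibration.sorted_negative_scores.tolist(),
    }
    reference = io.StringIO()
    for pep, pos in zip(model.reference_peptides, model.reference_positive):
        reference.write(f"{pep}\t{1 if pos else 0}\n")
    with zipfile.ZipFile(str(path), "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for arcname, payload in (
            ("model.json", json.dumps(meta, sort_keys=True, indent=1)),
            ("reference.tsv", reference.getvalue()),
        ):
            info = zipfile.ZipInfo(arcname, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, payload)


def load_model(path: str | os.PathLike) -> PredictionModel:
    with zipfile.ZipFile(str(path)) as zf:
        meta = json.loads(zf.read("model.json").decode("utf-8"))
        ref_lines = zf.read("reference.tsv").decode("utf-8").splitlines()
    peptides = []
    positive = []
    for line in ref_lines:
        pep, flag = line.split("\t")
        peptides.append(pep)
        positive.append(flag == "1")
    return PredictionModel(
        name=meta["name"],
        comments=meta["comments"],
        created=meta["created"],
        residue_types=frozenset(meta["residue_types"]),
        half_width=int(meta["half_width"]),
        knn_config=_knn_config_from_dict(meta["knn_config"]),
        disorder_provider=meta["disorder_provider"],
        disorder_track=meta["disorder_track"],
        ensemble=BaggingEnsemble.from_dict(meta["ensemble"]),
        calibration=CalibrationCurve(np.asarray(meta["calibration"], dtype=np.float64)),
        reference_peptides=peptides,
        reference_positive=np.asarray(positive, dtype=bool),
        format_version=int(meta["format_version"]),
    )
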