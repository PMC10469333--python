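"""Predict TF-binding-site overlap of called EDRs/ESRs from the damage
profile alone, with a sequence-only baseline trained under the identical
split protocol."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .enhancer_model import ModelHandle, DEFAULT_TRAIN
from .genomic_io import Genome, GenomicInterval, one_hot_encode
from .saturated_mutagenesis import EDProfile, EDRegion

DEFAULT_WINDOW = 40


@dataclass
class RegionFeature:
    region: EDRegion
    vector: np.ndarray      # (W,) ED values or (W, 4) one-hot, centered on midpoint
    label: int


def label_regions(
    regions: list[EDRegion],
    tfbs_intervals: list[GenomicInterval],
    min_overlap: int = 1,
) -> list[int]:
    """Label 1 iff a region overlaps any TFBS interval by >= min_overlap bp."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in tfbs_intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    labels = []
    for r in regions:
        iv = r.interval
        lab = 0
        for t in by_chrom.get(iv.chrom, []):
            if min(iv.end, t.end) - max(iv.start, t.start) >= min_overlap:
                lab = 1
                break
        labels.append(lab)
    return labels


def extract_ed_features(
    regions: list[EDRegion],
    profiles: list[EDProfile],
    labels: list[int],
    window: int = DEFAULT_WINDOW,
    scale: str = "signed_log",
) -> list[RegionFeature]:
    """Fixed-length ED vector centered on each region midpoint, zero-padded
    where the window extends beyond the region's source profile.

    ``scale``: ``signed_log`` (default) divides by the profile's local noise
    sigma and applies sign(x)*log1p(|x|) — profiles vary over orders of
    magnitude in amplitude, and the classifier should learn bump shape, not
    per-profile scale. ``raw`` keeps plain ed values.
    """
    from .saturated_mutagenesis import profile_sigma

    prof_by_key = {}
    for p in profiles:
        prof_by_key.setdefault(p.interval.chrom, []).append(p)
    feats = []
    for r, lab in zip(regions, labels):
        prof = None
        for p in prof_by_key.get(r.interval.chrom, []):
            if p.interval.start <= r.interval.start and r.interval.end <= p.interval.end:
                prof = p
                break
        if prof is None:
            raise ValueError(f"no profile covers region {r.interval}")
        mid = r.interval.midpoint - prof.interval.start
        lo = mid - window // 2
        vec = np.zeros(window, dtype=np.float32)
        src_lo = max(0, lo)
        src_hi = min(len(prof.ed), lo + window)
        vec[src_lo - lo : src_hi - lo] = prof.ed[src_lo:src_hi]
        if scale == "signed_log":
            sigma = profile_sigma(prof.ed)
            if sigma > 0:
                vec = vec / sigma
            vec = np.sign(vec) * np.log1p(np.abs(vec))
        elif scale != "raw":
            raise ValueError("scale must be 'signed_log' or 'raw'")
        feats.append(RegionFeature(r, vec.astype(np.float32), lab))
    return feats


def extract_sequence_features(
    regions: list[EDRegion],
    genome: Genome,
    labels: list[int],
    window: int = DEFAULT_WINDOW,
) -> list[RegionFeature]:
    """One-hot sequence of the same window, for the sequence-only baseline."""
    feats = []
    for r, lab in zip(regions, labels):
        mid = r.interval.midpoint
        lo = mid - window // 2
        mat = np.zeros((window, 4), dtype=np.float32)
        src_lo = max(0, lo)
        src_hi = min(genome.length(r.interval.chrom), lo + window)
        seq = genome.fetch(r.interval.chrom, src_lo, src_hi)
        mat[src_lo - lo : src_hi - lo] = one_hot_encode(seq)
        feats.append(RegionFeature(r, mat, lab))
    return feats


def _split_features(feats, holdout_chroms, validation_chrom):
    splits = {"train": [], "validation": [], "test": []}
    for f in feats:
        chrom = f.region.interval.chrom
        if chrom in holdout_chroms:
            splits["test"].append(f)
        elif chrom == validation_chrom:
            splits["validation"].append(f)
        else:
            splits["train"].append(f)
    return splits


def _tfbs_architecture(window: int, channels: int) -> list[dict]:
    l1 = window - 7 + 1
    p1 = l1 // 2
    return [
        {"type": "Conv1D", "c_in": channels, "c_out": 16, "width": 7},
        {"type": "ReLU"},
        {"type": "MaxPool1D", "pool": 2},
        {"type": "Flatten"},
        {"type": "Dense", "n_in": p1 * 16, "n_out": 32},
        {"type": "ReLU"},
        {"type": "Dense", "n_in": 32, "n_out": 1},
    ]


def train_tfbs_model(
    features: list[RegionFeature],
    kind: str,
    seed: int = 0,
    holdout_chroms: tuple[str, ...] = ("chr4",),
    validation_chrom: str = "chr3",
    config: dict | None = None,
) -> tuple[ModelHandle, dict]:
    """Train a small 1-D conv classifier over region feature vectors.

    ``features`` may carry ED vectors (W,) or one-hot matrices (W, 4); the
    architecture adapts to the channel count. Returns the handle and the
    split bookkeeping (lists of RegionFeature per split) so the caller can
    evaluate on exactly the holdout regions.
    """
    if kind not in ("EDR", "ESR"):
        raise ValueError("kind must be 'EDR' or 'ESR'")
    feats = [f for f in features if f.region.kind == kind]
    labels = {f.label for f in feats}
    if labels != {0, 1}:
        raise ValueError("training requires both classes present")
    splits = _split_features(feats, holdout_chroms, validation_chrom)
    if not splits["train"] or not splits["validation"]:
        raise ValueError("empty train or validation split")

    def stack(fs):
        x = np.stack([np.atleast_2d(f.vector.T).T for f in fs])  # (n, W, C)
        if x.ndim == 2:
            x = x[:, :, None]
        y = np.array([f.label for f in fs], dtype=np.float32)
        return x, y

    x_tr, y_tr = stack(splits["train"])
    if x_tr.ndim == 2:
        x_tr = x_tr[:, :, None]
    x_va, y_va = stack(splits["validation"])
    window, channels = x_tr.shape[1], x_tr.shape[2]

    cfg = dict(DEFAULT_TRAIN)
    cfg.update({"epochs": 60, "patience": 8})
    if config:
        cfg.update(config)
    arch = cfg.pop("architecture", None) or _tfbs_architecture(window, channels)
    net = nn.build_network(arch, seed=seed)
    history = nn.train_network(
        net, x_tr, y_tr, x_va, y_va,
        epochs=cfg["epochs"], batch_size=cfg["batch_size"],
        lr=cfg["lr"], patience=cfg["patience"], seed=seed,
    )
    handle = ModelHandle(
        phase="tfbs",
        network=net,
        config={"architecture": arch, "kind": kind, **cfg},
        seed=seed,
        holdout_chroms=tuple(holdout_chroms),
        validation_chrom=validation_chrom,
        history=history,
    )
    return handle, splits


def train_sequence_baseline(
    regions: list[EDRegion],
    genome: Genome,
    labels: list[int],
    kind: str,
    seed: int = 0,
    window: int = DEFAULT_WINDOW,
    holdout_chroms: tuple[str, ...] = ("chr4",),
    validation_chrom: str = "chr3",
    config: dict | None = None,
) -> tuple[ModelHandle, dict]:
    """Sequence-only baseline under the identical split protocol."""
    feats = extract_sequence_features(regions, genome, labels, window)
    return train_tfbs_model(
        feats, kind, seed=seed, holdout_chroms=holdout_chroms,
        validation_chrom=validation_chrom, config=config,
    )


def predict_features(handle: ModelHandle, features: list[RegionFeature]) -> np.ndarray:
    x = np.stack([f.vector for f in features])
    if x.ndim == 2:
        x = x[:, :, None]
    return handle.predict(x)[:, 0]
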