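"""Two-phase enhancer model.

Phase one is a multitask convolutional network mapping a 2,000 bp one-hot
sequence to per-feature peak probabilities; phase two maps the phase-one
feature vector to an enhancer probability. Enhancers are defined as
fixed-width windows centered on intersections between the acetylation and
accessibility peak tracks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .genomic_io import (
    Genome,
    GenomicInterval,
    coverage_mask,
    intersect_intervals,
    one_hot_encode,
)

WINDOW = 2000
CENTRAL_BIN = 200


# ---------------------------------------------------------------------------
# Enhancer definition
# ---------------------------------------------------------------------------

@dataclass
class EnhancerSet:
    intervals: list[GenomicInterval]
    probabilities: list[float] | None = None

    def __post_init__(self) -> None:
        for iv in self.intervals:
            if len(iv) != self.width:
                raise ValueError("all enhancer windows must share one width")

    @property
    def width(self) -> int:
        return len(self.intervals[0]) if self.intervals else WINDOW

    def __len__(self) -> int:
        return len(self.intervals)


def call_enhancers(
    h3k27ac_peaks: list[GenomicInterval],
    accessibility_peaks: list[GenomicInterval],
    genome: Genome,
    width: int = WINDOW,
) -> EnhancerSet:
    """Fixed-width windows centered on the midpoints of maximal intersections
    between the two peak sets.

    Windows running off a chromosome are dropped; windows whose centers fall
    within ``width // 2`` of an already-emitted center are deduplicated
    (first in coordinate order kept).
    """
    intersections = intersect_intervals(h3k27ac_peaks, accessibility_peaks)
    out: list[GenomicInterval] = []
    last_center: dict[str, int] = {}
    for iv in intersections:
        center = iv.midpoint
        start = center - width // 2
        end = start + width
        if start < 0 or end > genome.length(iv.chrom):
            continue
        prev = last_center.get(iv.chrom)
        if prev is not None and abs(center - prev) < width // 2:
            continue
        last_center[iv.chrom] = center
        out.append(GenomicInterval(iv.chrom, start, end))
    return EnhancerSet(out)


# ---------------------------------------------------------------------------
# Phase-one dataset
# ---------------------------------------------------------------------------

@dataclass
class Phase1Dataset:
    x: dict[str, np.ndarray]           # split -> (n, window, 4)
    y: dict[str, np.ndarray]           # split -> (n, F)
    windows: dict[str, list[GenomicInterval]]
    feature_names: list[str]
    holdout_chroms: tuple[str, ...]
    validation_chrom: str


def make_phase1_dataset(
    genome: Genome,
    tracks: dict[str, list[GenomicInterval]],
    window: int = WINDOW,
    stride: int = WINDOW,
    holdout_chroms: tuple[str, ...] = ("chr4",),
    validation_chrom: str | None = None,
    max_n_fraction: float = 0.10,
) -> Phase1Dataset:
    """Tile the genome and label each window per track.

    Feature f is labeled 1 iff its peaks cover at least 50% of the window's
    central 200 bp bin. Test = holdout chromosomes; validation = one
    designated non-holdout chromosome; train = the rest. Windows with more
    than ``max_n_fraction`` N bases are dropped.
    """
    if not tracks:
        raise ValueError("at least one track required")
    for c in holdout_chroms:
        if c not in genome:
            raise ValueError(f"holdout chromosome {c!r} absent from genome")
    non_holdout = [c for c in genome.chromosomes if c not in holdout_chroms]
    if not non_holdout:
        raise ValueError("no chromosomes left for training")
    if validation_chrom is None:
        validation_chrom = non_holdout[-1]
    if validation_chrom in holdout_chroms or validation_chrom not in genome:
        raise ValueError(f"invalid validation chromosome {validation_chrom!r}")

    feature_names = sorted(tracks)
    splits = {"train": [], "validation": [], "test": []}
    xs = {k: [] for k in splits}
    ys = {k: [] for k in splits}

    half_bin = CENTRAL_BIN // 2
    for chrom in genome.chromosomes:
        length = genome.length(chrom)
        masks = [
            coverage_mask(tracks[name], chrom, length) for name in feature_names
        ]
        cums = [np.concatenate([[0], np.cumsum(m)]) for m in masks]
        if chrom in holdout_chroms:
            split = "test"
        elif chrom == validation_chrom:
            split = "validation"
        else:
            split = "train"
        seq = genome[chrom]
        for start in range(0, length - window + 1, stride):
            sub = seq[start : start + window]
            if sub.count("N") > max_n_fraction * window:
                continue
            center = start + window // 2
            b0, b1 = center - half_bin, center + half_bin
            labels = np.array(
                [(c[b1] - c[b0]) >= CENTRAL_BIN // 2 for c in cums], dtype=np.float32
            )
            splits[split].append(GenomicInterval(chrom, start, start + window))
            xs[split].append(one_hot_encode(sub))
            ys[split].append(labels)

    def stack(lst, shape):
        return np.stack(lst) if lst else np.empty(shape, dtype=np.float32)

    f = len(feature_names)
    return Phase1Dataset(
        x={k: stack(v, (0, window, 4)) for k, v in xs.items()},
        y={k: stack(v, (0, f)) for k, v in ys.items()},
        windows=splits,
        feature_names=feature_names,
        holdout_chroms=tuple(holdout_chroms),
        validation_chrom=validation_chrom,
    )


# ---------------------------------------------------------------------------
# Model handle
# ---------------------------------------------------------------------------

@dataclass
class ModelHandle:
    """Opaque trained-predictor contract: a network plus its provenance."""

    phase: str                      # "1", "2" or "tfbs"
    network: nn.Network
    config: dict
    feature_names: list[str] = field(default_factory=list)
    seed: int = 0
    holdout_chroms: tuple[str, ...] = ()
    validation_chrom: str = ""
    history: dict = field(default_factory=dict)
    temperature: float = 1.0

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.temperature == 1.0:
            return self.network.predict_proba(x)
        z = self.predict_logits(x)
        return 1.0 / (1.0 + np.exp(-z / self.temperature))

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        """Raw pre-sigmoid logits (temperature not applied)."""
        out = []
        for i in range(0, len(x), 512):
            out.append(self.network.forward(np.asarray(x[i : i + 512], dtype=np.float32)))
        return np.concatenate(out, axis=0)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        nn.save_network(self.network, directory)
        meta = {
            "phase": self.phase,
            "config": self.config,
            "feature_names": self.feature_names,
            "seed": self.seed,
            "holdout_chroms": list(self.holdout_chroms),
            "validation_chrom": self.validation_chrom,
            "temperature": self.temperature,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ModelHandle":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        return cls(
            phase=meta["phase"],
            network=nn.load_network(directory),
            config=meta["config"],
            feature_names=meta["feature_names"],
            seed=meta["seed"],
            holdout_chroms=tuple(meta["holdout_chroms"]),
            validation_chrom=meta["validation_chrom"],
            temperature=meta.get("temperature", 1.0),
        )


def default_phase1_architecture(
    n_features: int, window: int = WINDOW, crop: int = 600
) -> list[dict]:
    """Small conv net: the labels depend only on the window's central bin,
    so the input is center-cropped before motif-scale convolution, coarse
    positional max pooling and a dense head (~10k parameters)."""
    crop = min(crop, window)
    l1 = crop - 14 + 1
    p1 = l1 // 60
    return [
        {"type": "CenterCrop1D", "keep": crop},
        {"type": "Conv1D", "c_in": 4, "c_out": 28, "width": 14},
        {"type": "ReLU"},
        {"type": "MaxPool1D", "pool": 60},
        {"type": "Flatten"},
        {"type": "Dense", "n_in": p1 * 28, "n_out": n_features},
    ]


def default_phase2_architecture(n_features: int, mode: str = "conv") -> list[dict]:
    """Phase-two classifier over the length-F phase-one vector, treated as a
    1-D signal (``conv``) or flat input (``dense``)."""
    if mode == "conv" and n_features >= 4:
        l1 = n_features - 3 + 1
        return [
            {"type": "Conv1D", "c_in": 1, "c_out": 8, "width": 3},
            {"type": "ReLU"},
            {"type": "Flatten"},
            {"type": "Dense", "n_in": l1 * 8, "n_out": 16},
            {"type": "ReLU"},
            {"type": "Dense", "n_in": 16, "n_out": 1},
        ]
    return [
        {"type": "Dense", "n_in": n_features, "n_out": 16},
        {"type": "ReLU"},
        {"type": "Dense", "n_in": 16, "n_out": 1},
    ]


DEFAULT_TRAIN = {"epochs": 40, "batch_size": 64, "lr": 1e-3, "patience": 5}

_SEED_KMER = 11


def _kmer_seed_filters(
    net: nn.Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    seed: int,
    center_halfwidth: int = 300,
    scale: float = 2.0,
    bias: float = -10.0,
) -> None:
    """Initialize first-layer conv filters from k-mers enriched in positive
    windows.

    Random-init gradient descent reliably fails to discover sparse motif
    features at this data scale (it memorizes instances instead), so the
    first convolution is seeded with the top label-enriched k-mers of the
    training split - a counting statistic computed from the training data
    only. Gradient training then refines filters and learns the head.
    """
    conv = None
    for layer in net.layers:
        if isinstance(layer, nn.Conv1D):
            conv = layer
            break
    if conv is None or conv.W.shape[1] != 4:
        return
    width, _, n_filters = conv.W.shape
    k = min(_SEED_KMER, width)
    if y_train.ndim == 1:
        y_train = y_train[:, None]
    idx = x_train.argmax(axis=2).astype(np.int64)
    # N rows (all-zero one-hot) argmax to 0; acceptable noise for counting
    length = idx.shape[1]
    c0 = max(0, length // 2 - center_halfwidth)
    c1 = min(length, length // 2 + center_halfwidth)
    pw = 4 ** np.arange(k)

    def counts(rows: np.ndarray) -> np.ndarray:
        sub = rows[:, c0:c1]
        codes = np.lib.stride_tricks.sliding_window_view(sub, k, axis=1) @ pw
        return np.bincount(codes.ravel(), minlength=4**k)

    rc = np.array([3, 2, 1, 0])

    def decode(code: int) -> np.ndarray:
        return np.array([(code // 4**j) % 4 for j in range(k)])

    # per-task enrichment so every feature contributes seeds, round-robin
    per_task_tops: list[np.ndarray] = []
    for f in range(y_train.shape[1]):
        is_pos = y_train[:, f] > 0
        if is_pos.sum() < 10 or (~is_pos).sum() < 10:
            continue
        cp = counts(idx[is_pos])
        cn = counts(idx[~is_pos])
        enrich = np.log(cp + 0.5) - np.log(
            (cn + 0.5) * is_pos.sum() / (~is_pos).sum()
        )
        per_task_tops.append(np.argsort(-enrich)[: 20 * n_filters])
    if not per_task_tops:
        return

    seeds: list[np.ndarray] = []
    cursor = [0] * len(per_task_tops)
    while len(seeds) < n_filters:
        progressed = False
        for t, top in enumerate(per_task_tops):
            while cursor[t] < len(top):
                d = decode(int(top[cursor[t]]))
                cursor[t] += 1
                if not any(
                    (d == s).mean() > 0.6 or (rc[d[::-1]] == s).mean() > 0.6
                    for s in seeds
                ):
                    seeds.append(d)
                    progressed = True
                    break
            if len(seeds) == n_filters:
                break
        if not progressed:
            break
    pad = (width - k) // 2
    eye = np.eye(4, dtype=np.float32)
    for j, s in enumerate(seeds):
        w = np.zeros((width, 4), dtype=np.float32)
        w[pad : pad + k] = scale * (eye[s] - 0.25)
        conv.W[:, :, j] = w
    conv.b[: len(seeds)] = bias


def _augment_reverse_complement(x: np.ndarray, y: np.ndarray):
    """Append the reverse complement of every window (labels unchanged)."""
    return (
        np.concatenate([x, x[:, ::-1, ::-1]]),
        np.concatenate([y, y]),
    )


def train_phase1(
    dataset: Phase1Dataset,
    config: dict | None = None,
    seed: int = 0,
) -> ModelHandle:
    """Train the multitask phase-one classifier with early stopping.

    Training uses reverse-complement augmentation and k-mer-seeded first-
    layer filters by default (both switchable off via config).
    """
    for split in ("train", "validation"):
        if len(dataset.x[split]) == 0:
            raise ValueError(f"empty {split} split")
    cfg = dict(DEFAULT_TRAIN)
    cfg.update({"epochs": 50, "patience": 10, "lr": 3e-3})
    if config:
        cfg.update(config)
    n_features = len(dataset.feature_names)
    arch = cfg.pop("architecture", None) or default_phase1_architecture(
        n_features, dataset.x["train"].shape[1]
    )
    x_train, y_train = dataset.x["train"], dataset.y["train"]
    use_kmer_seed = cfg.pop("kmer_seed", True)
    if cfg.pop("augment_rc", True):
        x_aug, y_aug = _augment_reverse_complement(x_train, y_train)
    else:
        x_aug, y_aug = x_train, y_train
    n_members = int(cfg.pop("n_members", 2))
    members: list[nn.Network] = []
    history: dict = {"members": []}
    for m in range(n_members):
        member_seed = seed + 1009 * m
        net_m = nn.build_network(arch, seed=member_seed)
        if use_kmer_seed:
            # seeds computed from the (unaugmented) training split
            _kmer_seed_filters(net_m, x_train, y_train, member_seed)
        hist = nn.train_network(
            net_m,
            x_aug, y_aug,
            dataset.x["validation"], dataset.y["validation"],
            epochs=cfg["epochs"], batch_size=cfg["batch_size"],
            lr=cfg["lr"], patience=cfg["patience"],
            weight_decay=cfg.get("weight_decay", 0.0), seed=member_seed,
        )
        members.append(net_m)
        history["members"].append(hist)
    net = members[0] if n_members == 1 else nn.Ensemble(members)
    history["train_loss"] = history["members"][0]["train_loss"]
    history["val_loss"] = history["members"][0]["val_loss"]
    return ModelHandle(
        phase="1",
        network=net,
        config={"architecture": arch, **cfg},
        feature_names=dataset.feature_names,
        seed=seed,
        holdout_chroms=dataset.holdout_chroms,
        validation_chrom=dataset.validation_chrom,
        history=history,
    )


def predict_epigenome(handle: ModelHandle, window_sequence) -> np.ndarray:
    """Per-feature probabilities for one 2,000 bp window."""
    if handle.phase != "1":
        raise ValueError("handle is not a phase-1 model")
    x = _as_onehot_batch(window_sequence)
    if x.shape[1] != WINDOW:
        raise ValueError(f"window must be {WINDOW} bp, got {x.shape[1]}")
    return handle.predict(x)[0]


def predict_epigenome_batch(handle: ModelHandle, onehot_batch: np.ndarray) -> np.ndarray:
    if handle.phase != "1":
        raise ValueError("handle is not a phase-1 model")
    return handle.predict(onehot_batch)


def _as_onehot_batch(window_sequence) -> np.ndarray:
    if isinstance(window_sequence, str):
        return one_hot_encode(window_sequence)[None, :, :]
    x = np.asarray(window_sequence, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, :, :]
    return x


# ---------------------------------------------------------------------------
# Phase two
# ---------------------------------------------------------------------------

@dataclass
class Phase2Dataset:
    x: dict[str, np.ndarray]           # split -> (n, F, 1)
    y: dict[str, np.ndarray]           # split -> (n,)
    windows: dict[str, list[GenomicInterval]]
    negative_ratio: float
    feature_scale: str = "logit"


def make_phase2_dataset(
    phase1_handle: ModelHandle,
    enhancers: EnhancerSet,
    genome: Genome,
    negative_ratio: float = 10.0,
    seed: int = 0,
    feature_scale: str = "logit",
) -> Phase2Dataset:
    """Positives: phase-one vectors of enhancer windows. Negatives: random
    same-width windows not overlapping any enhancer, at negative_ratio : 1.

    ``feature_scale``: phase-one outputs are passed as logits (default) or
    probabilities. Logits keep the pipeline differentiable in practice: a
    saturated probability (1.0 in float32) hides single-base damage from
    downstream mutagenesis, while its logit still moves.

    Split by chromosome using the phase-one handle's holdout/validation
    assignment so no holdout window influences training.
    """
    rng = np.random.default_rng(seed)
    width = enhancers.width
    enh_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in enhancers.intervals:
        enh_by_chrom.setdefault(iv.chrom, []).append(iv)

    windows: list[GenomicInterval] = list(enhancers.intervals)
    labels: list[int] = [1] * len(windows)
    n_neg_target = int(round(negative_ratio * len(windows)))
    chroms = genome.chromosomes
    attempts = 0
    n_neg = 0
    while n_neg < n_neg_target:
        attempts += 1
        if attempts > 100 * n_neg_target:
            raise ValueError("insufficient negative space for requested ratio")
        chrom = chroms[rng.integers(len(chroms))]
        if genome.length(chrom) <= width:
            continue
        start = int(rng.integers(0, genome.length(chrom) - width))
        cand = GenomicInterval(chrom, start, start + width)
        if any(cand.overlaps(e) for e in enh_by_chrom.get(chrom, [])):
            continue
        windows.append(cand)
        labels.append(0)
        n_neg += 1

    onehots = np.stack(
        [one_hot_encode(genome.fetch(iv.chrom, iv.start, iv.end)) for iv in windows]
    )
    if feature_scale == "logit":
        vectors = phase1_handle.predict_logits(onehots)
    elif feature_scale == "proba":
        vectors = predict_epigenome_batch(phase1_handle, onehots)
    else:
        raise ValueError("feature_scale must be 'logit' or 'proba'")

    holdout = set(phase1_handle.holdout_chroms)
    val_chrom = phase1_handle.validation_chrom
    x = {"train": [], "validation": [], "test": []}
    y = {"train": [], "validation": [], "test": []}
    w = {"train": [], "validation": [], "test": []}
    for iv, lab, vec in zip(windows, labels, vectors):
        if iv.chrom in holdout:
            split = "test"
        elif iv.chrom == val_chrom:
            split = "validation"
        else:
            split = "train"
        x[split].append(vec)
        y[split].append(lab)
        w[split].append(iv)
    f = vectors.shape[1]
    return Phase2Dataset(
        x={k: (np.stack(v)[:, :, None] if v else np.empty((0, f, 1), dtype=np.float32))
           for k, v in x.items()},
        y={k: np.asarray(v, dtype=np.float32) for k, v in y.items()},
        windows=w,
        negative_ratio=negative_ratio,
        feature_scale=feature_scale,
    )


def train_phase2(
    phase1_handle: ModelHandle,
    enhancers: EnhancerSet,
    genome: Genome,
    negative_ratio: float = 10.0,
    seed: int = 0,
    config: dict | None = None,
    dataset: Phase2Dataset | None = None,
) -> ModelHandle:
    """Train the phase-two enhancer classifier on phase-one vectors."""
    if phase1_handle.phase != "1":
        raise ValueError("first handle must be phase 1")
    if dataset is None:
        dataset = make_phase2_dataset(
            phase1_handle, enhancers, genome, negative_ratio, seed
        )
    cfg = dict(DEFAULT_TRAIN)
    cfg.update({"epochs": 80, "patience": 10})
    if config:
        cfg.update(config)
    n_features = dataset.x["train"].shape[1]
    mode = cfg.pop("mode", "conv")
    arch = cfg.pop("architecture", None) or default_phase2_architecture(n_features, mode)
    net = nn.build_network(arch, seed=seed)
    history = nn.train_network(
        net,
        dataset.x["train"], dataset.y["train"],
        dataset.x["validation"], dataset.y["validation"],
        epochs=cfg["epochs"], batch_size=cfg["batch_size"],
        lr=cfg["lr"], patience=cfg["patience"],
        weight_decay=cfg.get("weight_decay", 0.0), seed=seed,
    )
    temperature = 1.0
    if cfg.pop("calibrate", True):
        temperature = _fit_temperature(
            net, dataset.x["validation"], dataset.y["validation"]
        )
    return ModelHandle(
        phase="2",
        network=net,
        config={"architecture": arch, "negative_ratio": negative_ratio,
                "feature_scale": dataset.feature_scale, **cfg},
        feature_names=phase1_handle.feature_names,
        seed=seed,
        holdout_chroms=phase1_handle.holdout_chroms,
        validation_chrom=phase1_handle.validation_chrom,
        history=history,
        temperature=temperature,
    )


def _fit_temperature(
    net: nn.Network, x_val: np.ndarray, y_val: np.ndarray
) -> float:
    """Post-hoc temperature scaling: grid-fit T minimizing class-balanced
    validation NLL (positives re-weighted to parity with negatives).

    A confidence-saturated classifier (p ~ 1 on every enhancer) flattens
    mutagenesis profiles; dividing logits by a fitted T > 1 restores
    contrast without changing the ranking (auROC invariant)."""
    z = net.forward(np.asarray(x_val, dtype=np.float32)).ravel()
    y = np.asarray(y_val, dtype=np.float64).ravel()
    n_pos, n_neg = y.sum(), len(y) - y.sum()
    if n_pos == 0 or n_neg == 0:
        return 1.0
    w = np.where(y == 1, 0.5 / n_pos, 0.5 / n_neg)
    best_t, best_nll = 1.0, np.inf
    for t in np.geomspace(0.5, 50.0, 80):
        zt = z / t
        nll = float(np.sum(w * (np.logaddexp(0, zt) - y * zt)))
        if nll < best_nll:
            best_t, best_nll = float(t), nll
    return best_t


# ---------------------------------------------------------------------------
# Composite oracle
# ---------------------------------------------------------------------------

class EnhancerOracle:
    """Callable mapping a 2,000 bp sequence to an enhancer probability via
    phase2(phase1(x)); supports batched evaluation for mutagenesis."""

    def __init__(self, phase1_handle: ModelHandle, phase2_handle: ModelHandle):
        if phase1_handle.phase != "1" or phase2_handle.phase != "2":
            raise ValueError("need a phase-1 and a phase-2 handle")
        self.phase1 = phase1_handle
        self.phase2 = phase2_handle

    def __call__(self, window_sequence) -> float:
        return float(self.predict_many(_as_onehot_batch(window_sequence))[0])

    def predict_many(self, onehot_batch: np.ndarray, batch_size: int = 256) -> np.ndarray:
        scale = self.phase2.config.get("feature_scale", "logit")
        out = []
        for i in range(0, len(onehot_batch), batch_size):
            if scale == "logit":
                vec = self.phase1.predict_logits(onehot_batch[i : i + batch_size])
            else:
                vec = self.phase1.predict(onehot_batch[i : i + batch_size])
            out.append(self.phase2.predict(vec[:, :, None])[:, 0])
        return np.concatenate(out)


def enhancer_probability(
    phase1_handle: ModelHandle, phase2_handle: ModelHandle, window_sequence
) -> float:
    """Enhancer probability of one 2,000 bp window."""
    x = _as_onehot_batch(window_sequence)
    if x.shape[1] != WINDOW:
        raise ValueError(f"window must be {WINDOW} bp, got {x.shape[1]}")
    return EnhancerOracle(phase1_handle, phase2_handle)(x)
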