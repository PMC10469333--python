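"""In silico saturated mutagenesis and damage-profile segmentation.

For every position of a fixed 2,000 bp enhancer window, every non-reference
base is substituted and the window re-scored with an enhancer-probability
oracle. The per-base damage score is

    ed[i] = P_ref - mean(P_alt over the three non-reference bases at i)

so positive values mark damaging positions. Profiles are segmented into
damaging (EDR) and strengthening (ESR) runs against a profile-local
threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .genomic_io import Genome, GenomicInterval, one_hot_encode

_BASES = "ACGT"


@dataclass
class EDProfile:
    """Per-base enhancer-damage profile over one enhancer window."""

    interval: GenomicInterval
    ref_sequence: str
    p_ref: float
    alt_probs: np.ndarray        # (L, 3): non-reference alleles, A<C<G<T minus ref
    ed: np.ndarray               # (L,)
    mask: np.ndarray             # (L,) True where reference base is N

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.ed)):
            raise ValueError("ed profile contains non-finite values")

    def __len__(self) -> int:
        return len(self.ed)


@dataclass(frozen=True)
class EDRegion:
    """A called damaging (EDR) or strengthening (ESR) segment."""

    interval: GenomicInterval
    kind: str                    # "EDR" or "ESR"
    mean_ed: float
    peak_ed: float
    length: int

    def __post_init__(self) -> None:
        if self.kind not in ("EDR", "ESR"):
            raise ValueError(f"invalid kind {self.kind!r}")
        if self.length < 3:
            raise ValueError("regions must span >= 3 bp")
        if self.kind == "EDR" and self.mean_ed <= 0:
            raise ValueError("EDR must have positive mean ed")
        if self.kind == "ESR" and self.mean_ed >= 0:
            raise ValueError("ESR must have negative mean ed")


def saturated_mutagenesis(
    oracle: Callable,
    genome: Genome,
    enhancer_window: GenomicInterval,
) -> EDProfile:
    """Compute the ED profile of one enhancer window against an oracle.

    ``oracle`` maps a window sequence to a probability in [0, 1]; if it has
    a ``predict_many`` method taking a one-hot batch, all 3L+1 evaluations
    are batched through it. Positions whose reference base is N get ed = 0
    and a mask flag.
    """
    seq = genome.fetch(enhancer_window.chrom, enhancer_window.start, enhancer_window.end)
    length = len(seq)
    onehot = one_hot_encode(seq)

    mut_positions: list[tuple[int, int]] = []   # (position, alt slot 0..2)
    for i, ref_base in enumerate(seq):
        if ref_base == "N":
            continue
        for slot in range(3):
            mut_positions.append((i, slot))

    def alt_base(ref_base: str, slot: int) -> str:
        return [b for b in _BASES if b != ref_base][slot]

    if hasattr(oracle, "predict_many"):
        batch = np.repeat(onehot[None, :, :], len(mut_positions) + 1, axis=0)
        for row, (i, slot) in enumerate(mut_positions, start=1):
            b = alt_base(seq[i], slot)
            batch[row, i, :] = 0.0
            batch[row, i, _BASES.index(b)] = 1.0
        probs = np.asarray(oracle.predict_many(batch), dtype=float)
    else:
        probs = np.empty(len(mut_positions) + 1)
        probs[0] = oracle(seq)
        for row, (i, slot) in enumerate(mut_positions, start=1):
            b = alt_base(seq[i], slot)
            probs[row] = oracle(seq[:i] + b + seq[i + 1 :])

    if not np.all(np.isfinite(probs)) or probs.min() < 0 or probs.max() > 1:
        raise ValueError("oracle returned non-finite or out-of-range probability")

    p_ref = float(probs[0])
    alt = np.full((length, 3), p_ref)
    mask = np.zeros(length, dtype=bool)
    for row, (i, slot) in enumerate(mut_positions, start=1):
        alt[i, slot] = probs[row]
    for i, base in enumerate(seq):
        if base == "N":
            mask[i] = True
    ed = p_ref - alt.mean(axis=1)
    ed[mask] = 0.0
    return EDProfile(
        interval=enhancer_window,
        ref_sequence=seq,
        p_ref=p_ref,
        alt_probs=alt,
        ed=ed,
        mask=mask,
    )


def profile_sigma(ed: np.ndarray, mode: str = "trimmed") -> float:
    """Profile-local scale for thresholding.

    ``full`` is the plain SD. ``trimmed`` (default) estimates the noise
    floor by dropping positions beyond 3 full-SDs before recomputing, so a
    handful of strong true peaks does not inflate the threshold; it falls
    back to the full SD when the trimmed core is degenerate.
    """
    sd = float(ed.std())
    if mode == "full" or sd == 0.0:
        return sd
    core = ed[np.abs(ed) < 3 * sd]
    if len(core) < 10:
        return sd
    trimmed = float(core.std())
    return trimmed if trimmed > 0.0 else sd


def call_ed_regions(
    profile: EDProfile,
    tau_sd: float = 1.0,
    min_len: int = 3,
    gap: int = 0,
    sigma_mode: str = "trimmed",
) -> list[EDRegion]:
    """Segment a profile into EDRs (ed >= tau) and ESRs (ed <= -tau).

    tau = tau_sd * sigma, where sigma is a profile-local scale (see
    :func:`profile_sigma`). Runs shorter than ``min_len`` are discarded;
    runs separated by at most ``gap`` sub-threshold positions are merged
    (default: no merging). A zero-variance profile yields no regions.
    """
    ed = profile.ed
    sd = profile_sigma(ed, sigma_mode)
    if sd == 0.0:
        return []
    tau = tau_sd * sd
    regions: list[EDRegion] = []
    for kind, hit in (("EDR", ed >= tau), ("ESR", ed <= -tau)):
        for s, e in _runs(hit, gap):
            if e - s < min_len:
                continue
            seg = ed[s:e]
            mean_ed = float(seg.mean())
            peak = float(seg.max() if kind == "EDR" else seg.min())
            regions.append(
                EDRegion(
                    interval=GenomicInterval(
                        profile.interval.chrom,
                        profile.interval.start + s,
                        profile.interval.start + e,
                    ),
                    kind=kind,
                    mean_ed=mean_ed,
                    peak_ed=peak,
                    length=e - s,
                )
            )
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.kind))
    return regions


def _runs(hit: np.ndarray, gap: int = 0) -> list[tuple[int, int]]:
    """Maximal runs of True, optionally merging runs separated by <= gap."""
    runs: list[tuple[int, int]] = []
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        return runs
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev - 1 <= gap:
            prev = i
        else:
            runs.append((start, prev + 1))
            start = prev = i
    runs.append((start, prev + 1))
    return runs


def rank_regions_by_mean_ed(
    regions: Sequence[EDRegion],
    n_bins: int = 5,
    top_percent: float | None = None,
):
    """Rank regions by |mean_ed| (descending; ties broken by coordinate).

    Default mode returns ``n_bins`` quantile bins (list of lists, bin 0 the
    strongest). With ``top_percent`` set, returns the top that percentage of
    regions instead.
    """
    if top_percent is None and len(regions) < n_bins:
        raise ValueError(f"need at least {n_bins} regions to form {n_bins} bins")
    ranked = sorted(
        regions,
        key=lambda r: (-abs(r.mean_ed), r.interval.chrom, r.interval.start),
    )
    if top_percent is not None:
        k = int(round(len(ranked) * top_percent / 100.0))
        return ranked[:k]
    bins: list[list[EDRegion]] = [[] for _ in range(n_bins)]
    edges = np.linspace(0, len(ranked), n_bins + 1).round().astype(int)
    for b in range(n_bins):
        bins[b] = ranked[edges[b] : edges[b + 1]]
    return bins


def correlate_ed_with_annotation(
    profiles: Sequence[EDProfile],
    motif_instances: Sequence,
    annotation_for_instance: Callable,
) -> list[float]:
    """Spearman rho between |ed| and a per-base annotation for each motif
    instance that lies inside a profile. Instances shorter than 3 bp (after
    clipping to the profile) are skipped.

    ``annotation_for_instance(instance)`` must return a vector of the
    instance's full length (e.g. per-position PWM information content).
    """
    by_chrom: dict[str, list[EDProfile]] = {}
    for p in profiles:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    rhos: list[float] = []
    for inst in motif_instances:
        iv = inst.interval
        for p in by_chrom.get(iv.chrom, []):
            s = max(iv.start, p.interval.start)
            e = min(iv.end, p.interval.end)
            if e - s < 3:
                continue
            ann = np.asarray(annotation_for_instance(inst), dtype=float)
            ann = ann[s - iv.start : e - iv.start]
            vals = np.abs(p.ed[s - p.interval.start : e - p.interval.start])
            if np.std(ann) == 0 or np.std(vals) == 0:
                continue
            rhos.append(float(stats.spearmanr(vals, ann).statistic))
            break
    return rhos


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_profile(profile: EDProfile, prefix: str | Path) -> None:
    """Write a profile as bedGraph (per-base ed) plus a JSON sidecar."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".bedgraph"), "w") as fh:
        iv = profile.interval
        for i, v in enumerate(profile.ed):
            fh.write(f"{iv.chrom}\t{iv.start + i}\t{iv.start + i + 1}\t{v:.10g}\n")
    sidecar = {
        "chrom": profile.interval.chrom,
        "start": profile.interval.start,
        "end": profile.interval.end,
        "p_ref": profile.p_ref,
        "mask": profile.mask.nonzero()[0].tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def write_regions_bed(regions: Sequence[EDRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.kind}\t{r.mean_ed:.10g}\t.\n"
            )
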