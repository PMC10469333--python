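"""Per-SNP enhancer-perturbation (IEP) scoring and EDR/ESR annotation.

The composite score is ``iep = max(P_ref, P_alt) * |P_alt - P_ref|``: it
weights the allelic probability shift by the enhancer probability of the
stronger allele, is bounded in [0, 1] and symmetric under allele swap.
This is a declared reimplementation choice, not a published formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enhancer_model import EnhancerOracle, ModelHandle, WINDOW
from .genomic_io import Genome, SNPRecord, one_hot_encode
from .saturated_mutagenesis import EDRegion

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class IEPScore:
    snp: SNPRecord
    p_ref: float
    p_alt: float
    delta: float        # P_alt - P_ref
    iep: float          # max(P_ref, P_alt) * |delta|
    percentile: float | None = None


def _window_pair(genome: Genome, snp: SNPRecord, window: int) -> tuple[str, str]:
    center = snp.pos0
    start = center - window // 2
    end = start + window
    if start < 0 or end > genome.length(snp.chrom):
        raise ValueError(f"SNP {snp.id}: {window} bp window off chromosome")
    ref_seq = genome.fetch(snp.chrom, start, end)
    offset = center - start
    if ref_seq[offset] != snp.ref:
        raise ValueError(
            f"SNP {snp.id}: genome base {ref_seq[offset]} != ref {snp.ref}"
        )
    alt_seq = ref_seq[:offset] + snp.alt + ref_seq[offset + 1 :]
    return ref_seq, alt_seq


def iep_score(
    oracle: EnhancerOracle | ModelHandle,
    genome: Genome,
    snp: SNPRecord,
    phase2_handle: ModelHandle | None = None,
    window: int = WINDOW,
) -> IEPScore:
    """Score one SNP with exactly two oracle calls (ref and alt window,
    both centered on the SNP)."""
    if isinstance(oracle, ModelHandle):
        if phase2_handle is None:
            raise ValueError("phase-2 handle required when passing a phase-1 handle")
        oracle = EnhancerOracle(oracle, phase2_handle)
    ref_seq, alt_seq = _window_pair(genome, snp, window)
    batch = np.stack([one_hot_encode(ref_seq), one_hot_encode(alt_seq)])
    p_ref, p_alt = (float(v) for v in oracle.predict_many(batch))
    delta = p_alt - p_ref
    return IEPScore(
        snp=snp, p_ref=p_ref, p_alt=p_alt, delta=delta,
        iep=max(p_ref, p_alt) * abs(delta),
    )


def score_snp_catalog(
    oracle: EnhancerOracle,
    genome: Genome,
    snps: list[SNPRecord],
    window: int = WINDOW,
) -> pd.DataFrame:
    """Score a SNP catalog; returns a sorted, deduplicated table with
    percentile ranks (rank / N, midrank ties).

    SNPs that cannot be scored (window off chromosome, ref mismatch) are
    logged and skipped. Duplicate (chrom, pos, ref, alt) rows are collapsed
    with a warning.
    """
    seen: set[tuple] = set()
    unique: list[SNPRecord] = []
    n_dup = 0
    for snp in sorted(snps, key=lambda s: (s.chrom, s.pos, s.ref, s.alt)):
        if snp.key in seen:
            n_dup += 1
            continue
        seen.add(snp.key)
        unique.append(snp)
    if n_dup:
        logger.warning("deduplicated %d duplicate SNP rows", n_dup)

    rows = []
    batch_seqs: list[np.ndarray] = []
    kept: list[SNPRecord] = []
    n_skipped = 0
    for snp in unique:
        try:
            ref_seq, alt_seq = _window_pair(genome, snp, window)
        except ValueError as exc:
            n_skipped += 1
            logger.warning("skipping %s: %s", snp.id, exc)
            continue
        batch_seqs.append(one_hot_encode(ref_seq))
        batch_seqs.append(one_hot_encode(alt_seq))
        kept.append(snp)
    if n_skipped:
        logger.info("skipped %d unscorable SNPs", n_skipped)
    if not kept:
        return pd.DataFrame(
            columns=["snp_id", "chrom", "pos", "ref", "alt",
                     "p_ref", "p_alt", "delta", "iep", "percentile"]
        )
    probs = oracle.predict_many(np.stack(batch_seqs))
    for i, snp in enumerate(kept):
        p_ref, p_alt = float(probs[2 * i]), float(probs[2 * i + 1])
        delta = p_alt - p_ref
        rows.append(
            {"snp_id": snp.id, "chrom": snp.chrom, "pos": snp.pos,
             "ref": snp.ref, "alt": snp.alt, "p_ref": p_ref, "p_alt": p_alt,
             "delta": delta, "iep": max(p_ref, p_alt) * abs(delta)}
        )
    table = pd.DataFrame(rows)
    table["percentile"] = table["iep"].rank(method="average") / len(table)
    return table


def annotate_ed_overlap(
    snps: list[SNPRecord],
    ed_regions: list[EDRegion],
) -> pd.DataFrame:
    """Point-in-interval annotation of SNPs against called EDRs/ESRs.

    Returns one row per SNP with the overlapping region's kind and mean ED
    (or kind='none')."""
    by_chrom: dict[str, list[EDRegion]] = {}
    for r in ed_regions:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    rows = []
    for snp in snps:
        kind, mean_ed = "none", np.nan
        for r in by_chrom.get(snp.chrom, []):
            if r.interval.start <= snp.pos0 < r.interval.end:
                kind, mean_ed = r.kind, r.mean_ed
                break
        rows.append(
            {"snp_id": snp.id, "chrom": snp.chrom, "pos": snp.pos,
             "ed_overlap_kind": kind, "region_mean_ed": mean_ed}
        )
    return pd.DataFrame(rows)
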