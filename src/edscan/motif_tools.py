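"""PWM scanning, information content, and allelic motif-disruption scoring."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genomic_io import Genome, SNPRecord, reverse_complement
from .stats_eval import bh_fdr

_PSEUDO = 1e-6
_N_PENALTY = -25.0  # log-odds contribution of an N base: effectively kills a hit
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PWM:
    """Position weight matrix: ``matrix[j, b]`` = probability of base b at
    position j (rows sum to 1); base order A, C, G, T."""

    id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.id}: matrix must be w x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError(f"PWM {self.id}: width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.id}: rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.matrix, axis=1))

    def log_odds(self) -> np.ndarray:
        """w x 5 log2-odds matrix; 5th column is the N penalty."""
        lo = np.log2((self.matrix + _PSEUDO) / self.background[None, :])
        return np.hstack([lo, np.full((self.width, 1), _N_PENALTY)])

    def reverse_complement(self) -> "PWM":
        return PWM(self.id, self.matrix[::-1, ::-1], self.background[::-1])


def information_content(pwm: PWM) -> np.ndarray:
    """Per-position information content in bits (uniform background),
    clamped at zero."""
    p = pwm.matrix + _PSEUDO
    ic = 2.0 + np.sum(pwm.matrix * np.log2(p), axis=1)
    return np.clip(ic, 0.0, None)


@dataclass(frozen=True)
class MotifHit:
    offset: int          # 0-based offset of the hit on the forward strand
    strand: str          # '+' or '-'
    score: float         # log2 odds vs background


def _encode_indices(sequence: str) -> np.ndarray:
    idx = np.empty(len(sequence), dtype=np.int64)
    for i, base in enumerate(sequence.upper()):
        idx[i] = _BASE_INDEX.get(base, 4)
    return idx


def _scan_scores(log_odds: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Score every offset of a single strand; vectorized over offsets."""
    w = log_odds.shape[0]
    n = len(idx) - w + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)  # (n, w)
    return log_odds[np.arange(w)[None, :], windows].sum(axis=1)


def scan_pwm(pwm: PWM, sequence: str, threshold_bits: float) -> list[MotifHit]:
    """Scan both strands; return hits with log-odds >= threshold, sorted by
    forward-strand coordinate (ties: + before -)."""
    if len(sequence) < pwm.width:
        return []
    lo = pwm.log_odds()
    lo_rc = pwm.reverse_complement().log_odds()
    idx = _encode_indices(sequence)
    hits: list[MotifHit] = []
    fwd = _scan_scores(lo, idx)
    for off in np.nonzero(fwd >= threshold_bits)[0]:
        hits.append(MotifHit(int(off), "+", float(fwd[off])))
    # a reverse-strand match at forward offset o is a forward match of the
    # reverse-complement PWM at the same offset
    rev = _scan_scores(lo_rc, idx)
    for off in np.nonzero(rev >= threshold_bits)[0]:
        hits.append(MotifHit(int(off), "-", float(rev[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def best_hit_score(pwm: PWM, sequence: str) -> float:
    """Maximum log-odds over all offsets and strands (-inf if too short)."""
    if len(sequence) < pwm.width:
        return float("-inf")
    idx = _encode_indices(sequence)
    fwd = _scan_scores(pwm.log_odds(), idx)
    rev = _scan_scores(pwm.reverse_complement().log_odds(), idx)
    return float(max(fwd.max(), rev.max()))


@dataclass(frozen=True)
class AllelicDelta:
    snp_id: str
    pwm_id: str
    ref_score: float
    alt_score: float
    delta: float          # alt - ref; negative = alt weakens the motif
    offset: int           # chosen placement (forward-strand start, 0-based)
    strand: str


def allelic_motif_delta(
    pwm: PWM,
    genome: Genome,
    snp: SNPRecord,
    rule: str = "max_either",
) -> AllelicDelta:
    """Best motif log-odds for the ref- and alt-allele context around a SNP.

    All placements (offset, strand) putting the SNP inside the motif are
    scored for both alleles at the same placement; the placement maximizing
    ``max(ref, alt)`` (rule ``max_either``, default) or ``ref`` (rule
    ``max_ref``) is chosen. ``delta = alt - ref``.
    """
    w = pwm.width
    pos0 = snp.pos0
    lo_chr = pos0 - w + 1
    hi_chr = pos0 + w
    if lo_chr < 0 or hi_chr > genome.length(snp.chrom):
        raise ValueError(
            f"SNP {snp.id} within {w} bp of a chromosome end; delta undefined"
        )
    context = genome.fetch(snp.chrom, lo_chr, hi_chr)
    if context[w - 1] != snp.ref:
        raise ValueError(f"SNP {snp.id}: ref allele mismatch with genome")
    alt_context = context[: w - 1] + snp.alt + context[w:]

    lo = pwm.log_odds()
    lo_rc = pwm.reverse_complement().log_odds()
    idx_ref = _encode_indices(context)
    idx_alt = _encode_indices(alt_context)
    # offset i in the context array corresponds to chromosome offset lo_chr+i;
    # every window of width w in the context contains the SNP position
    ref_f, alt_f = _scan_scores(lo, idx_ref), _scan_scores(lo, idx_alt)
    ref_r, alt_r = _scan_scores(lo_rc, idx_ref), _scan_scores(lo_rc, idx_alt)

    best = None
    for strand, ref_s, alt_s in (("+", ref_f, alt_f), ("-", ref_r, alt_r)):
        for i in range(len(ref_s)):
            crit = ref_s[i] if rule == "max_ref" else max(ref_s[i], alt_s[i])
            if best is None or crit > best[0]:
                best = (crit, strand, i, ref_s[i], alt_s[i])
    assert best is not None
    _, strand, i, ref_score, alt_score = best
    return AllelicDelta(
        snp_id=snp.id,
        pwm_id=pwm.id,
        ref_score=float(ref_score),
        alt_score=float(alt_score),
        delta=float(alt_score - ref_score),
        offset=lo_chr + i,
        strand=strand,
    )


def motif_family_enrichment(
    candidate_snps: Sequence[SNPRecord],
    background_snps: Sequence[SNPRecord],
    pwms: Sequence[PWM],
    genome: Genome,
    delta_threshold: float = 3.0,
):
    """Per-PWM Fisher exact test of motif disruption in candidate vs
    background SNPs, with Benjamini-Hochberg correction across PWMs.

    A SNP "disrupts" a PWM if its allelic delta <= -delta_threshold.
    Returns a list of dicts (pwm_id, counts, odds_ratio, p, q).
    """
    if not candidate_snps or not background_snps:
        raise ValueError("candidate and background SNP sets must be nonempty")
    rows = []
    pvals = []
    for pwm in pwms:
        def n_disrupting(snps: Sequence[SNPRecord]) -> int:
            n = 0
            for snp in snps:
                try:
                    d = allelic_motif_delta(pwm, genome, snp)
                except ValueError:
                    continue
                if d.delta <= -delta_threshold:
                    n += 1
            return n

        a = n_disrupting(candidate_snps)
        b = len(candidate_snps) - a
        c = n_disrupting(background_snps)
        d = len(background_snps) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {"pwm_id": pwm.id, "n_cand_disrupt": a, "n_cand_total": len(candidate_snps),
             "n_bg_disrupt": c, "n_bg_total": len(background_snps),
             "odds_ratio": float(odds), "p": float(p)}
        )
        pvals.append(p)
    qvals = bh_fdr(np.asarray(pvals))
    for row, q in zip(rows, qvals):
        row["q"] = float(q)
    return rows


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme(path: str | Path) -> list[PWM]:
    """Read a MEME minimal-format motif file."""
    pwms: list[PWM] = []
    background = np.full(4, 0.25)
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            parts = lines[i].split()
            freq = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            background = np.array([freq.get(b, 0.25) for b in _BASES])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            rows = []
            i += 1
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) != 4:
                    break
                try:
                    rows.append([float(x) for x in parts])
                except ValueError:
                    break
                i += 1
            matrix = np.array(rows)
            matrix /= matrix.sum(axis=1, keepdims=True)
            pwms.append(PWM(motif_id, matrix, background.copy()))
            continue
        i += 1
    return pwms


def write_meme(pwms: Iterable[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        first = True
        for pwm in pwms:
            if first:
                bg = pwm.background
                fh.write(
                    "Background letter frequencies\n"
                    f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
                )
                first = False
            fh.write(f"MOTIF {pwm.id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
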