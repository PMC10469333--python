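"""Synthetic regulome generator.

Produces a multi-chromosome genome in which "enhancers" are regions covered
by both a histone-acetylation-like track and an accessibility-like track,
each enhancer carries planted PWM motif instances, and per-PWM "TF" tracks
cover the planted instances. Decoy single-track peaks ensure that only peak
co-occurrence defines an enhancer. A companion generator emits SNP catalogs
and credible sets with one designated causal SNP per signal.

Everything is driven by one integer seed; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genomic_io import (
    Genome,
    GenomicInterval,
    SNPRecord,
    write_bed,
    write_fasta,
    write_snp_table,
)
from .motif_tools import PWM, information_content

_BASES = "ACGT"

H3K27AC = "H3K27ac"
ACCESSIBILITY = "accessibility"


@dataclass
class RegulomeConfig:
    n_chromosomes: int = 4
    chromosome_length: int = 500_000
    gc_content: float = 0.41
    n_enhancers: int = 200
    motifs_per_enhancer: tuple[int, int] = (2, 4)
    n_tf_tracks: int = 5
    n_signals: int = 60
    snps_per_signal: tuple[int, int] = (3, 8)
    causal_in_motif_fraction: float = 1.0
    seed: int = 1
    enhancer_length_range: tuple[int, int] = (400, 700)
    peak_jitter: tuple[int, int] = (40, 100)
    tf_peak_halfwidth: int = 400
    n_decoys_per_track: int = 60
    margin: int = 2000
    min_enhancer_gap: int = 4000
    ld_window: int = 50_000
    ld_snps_per_signal: tuple[int, int] = (3, 8)

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length < 10_000:
            raise ValueError("need >=1 chromosome of >=10 kb")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0,1]")
        if not 0.0 <= self.causal_in_motif_fraction <= 1.0:
            raise ValueError("causal_in_motif_fraction must be in [0,1]")
        if self.n_enhancers < 1 or self.n_signals < 1 or self.n_tf_tracks < 1:
            raise ValueError("all counts must be positive")


@dataclass
class MotifInstance:
    interval: GenomicInterval
    pwm_id: str
    strand: str
    enhancer_index: int


@dataclass
class Signal:
    signal_id: str
    trait: str
    causal_snp_id: str
    snp_ids: list[str]
    ld_snp_ids: list[str]


@dataclass
class GroundTruth:
    enhancers: list[GenomicInterval]
    motif_instances: list[MotifInstance]
    tracks: dict[str, list[GenomicInterval]]
    signals: list[Signal] = field(default_factory=list)
    snps: list[SNPRecord] = field(default_factory=list)
    ppa: dict[str, dict[str, float]] = field(default_factory=dict)


def default_motif_library(n: int = 5, seed: int = 2024) -> list[PWM]:
    """A library of strong, mutually distinct PWMs of width 10-14.

    Each PWM has mostly high-confidence columns (consensus probability 0.85)
    with a couple of degenerate columns so information content varies by
    position, which the ED/IC correlation analysis relies on.
    """
    rng = np.random.default_rng(seed)
    pwms: list[PWM] = []
    widths = [13, 14, 15, 13, 14, 15, 13, 14, 15, 13]
    for i in range(n):
        w = widths[i % len(widths)]
        consensus = rng.integers(0, 4, size=w)
        matrix = np.full((w, 4), 0.05 / 3)
        matrix[np.arange(w), consensus] = 0.95
        # two interior columns degraded to ~1 bit so information content
        # varies by position (the ED/IC correlation analysis needs this)
        for j in rng.choice(np.arange(1, w - 1), size=2, replace=False):
            matrix[j] = np.array([0.45, 0.45, 0.05, 0.05])[rng.permutation(4)]
        matrix /= matrix.sum(axis=1, keepdims=True)
        pwms.append(PWM(f"PWM{i+1}", matrix))
    return pwms


def _sample_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs)


def _sample_motif(rng: np.random.Generator, pwm: PWM) -> np.ndarray:
    """Sample an instance per-column from the PWM probabilities."""
    return np.array([rng.choice(4, p=row) for row in pwm.matrix])


_RC = np.array([3, 2, 1, 0])


def generate_regulome(
    config: RegulomeConfig,
    motif_library: list[PWM] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[Genome, GroundTruth]:
    """Generate the synthetic genome, enhancers, planted motifs and tracks.

    If ``out_dir`` is given, writes genome.fa, one BED per track, a motif
    BED, and ground_truth.json.
    """
    rng = np.random.default_rng(config.seed)
    if motif_library is None:
        motif_library = default_motif_library(config.n_tf_tracks)
    if len(motif_library) < config.n_tf_tracks:
        raise ValueError("motif library smaller than n_tf_tracks")
    pwms = motif_library[: config.n_tf_tracks]

    chrom_names = [f"chr{i+1}" for i in range(config.n_chromosomes)]
    seqs = {
        name: _sample_background(rng, config.chromosome_length, config.gc_content)
        for name in chrom_names
    }

    # --- place enhancers, non-overlapping with a minimum gap -------------
    enhancers: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    attempts = 0
    max_attempts = config.n_enhancers * 200
    while len(enhancers) < config.n_enhancers:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place all enhancers; lower n_enhancers or "
                "increase chromosome_length"
            )
        chrom = chrom_names[rng.integers(len(chrom_names))]
        length = int(rng.integers(*config.enhancer_length_range))
        start = int(
            rng.integers(config.margin, config.chromosome_length - config.margin - length)
        )
        end = start + length
        gap = config.min_enhancer_gap
        if any(start - gap < e and s - gap < end for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        enhancers.append(GenomicInterval(chrom, start, end))
    enhancers.sort(key=lambda iv: (iv.chrom, iv.start))

    # --- plant motifs inside enhancers -----------------------------------
    motif_instances: list[MotifInstance] = []
    for ei, enh in enumerate(enhancers):
        k = int(rng.integers(config.motifs_per_enhancer[0],
                             config.motifs_per_enhancer[1] + 1))
        # distinct PWMs per enhancer: a duplicated motif is invisible to
        # max-pooled feature detectors (damaging one copy changes nothing),
        # which would make saturated-mutagenesis recovery ill-posed
        k = min(k, len(pwms))
        pwm_choice = rng.choice(len(pwms), size=k, replace=False)
        placed: list[tuple[int, int]] = []
        for pi in pwm_choice:
            pwm = pwms[int(pi)]
            w = pwm.width
            for _try in range(50):
                off = int(rng.integers(0, len(enh) - w))
                s, e = enh.start + off, enh.start + off + w
                if all(e + 2 <= ps or pe + 2 <= s for ps, pe in placed):
                    break
            else:
                continue
            placed.append((s, e))
            strand = "+" if rng.random() < 0.5 else "-"
            inst = _sample_motif(rng, pwm)
            if strand == "-":
                inst = _RC[inst[::-1]]
            seqs[enh.chrom][s:e] = inst
            motif_instances.append(
                MotifInstance(GenomicInterval(enh.chrom, s, e, strand), pwm.id, strand, ei)
            )

    # --- peak tracks ------------------------------------------------------
    jlo, jhi = config.peak_jitter
    tracks: dict[str, list[GenomicInterval]] = {H3K27AC: [], ACCESSIBILITY: []}
    for enh in enhancers:
        for track in (H3K27AC, ACCESSIBILITY):
            s = max(0, enh.start - int(rng.integers(jlo, jhi)))
            e = min(config.chromosome_length, enh.end + int(rng.integers(jlo, jhi)))
            tracks[track].append(GenomicInterval(enh.chrom, s, e))

    # decoy peaks: single-track only, away from enhancers and from the decoys
    # of the other broad track, so co-occurrence happens only at enhancers
    decoy_occupied: list[tuple[str, int, int]] = [
        (iv.chrom, iv.start - jhi - 10, iv.end + jhi + 10) for iv in enhancers
    ]
    for track in (H3K27AC, ACCESSIBILITY):
        n_placed = 0
        attempts = 0
        while n_placed < config.n_decoys_per_track and attempts < 10_000:
            attempts += 1
            chrom = chrom_names[rng.integers(len(chrom_names))]
            length = int(rng.integers(600, 1200))
            start = int(rng.integers(config.margin,
                                     config.chromosome_length - config.margin - length))
            end = start + length
            if any(c == chrom and start < e and s < end for c, s, e in decoy_occupied):
                continue
            decoy_occupied.append((chrom, start, end))
            tracks[track].append(GenomicInterval(chrom, start, end))
            n_placed += 1
        tracks[track].sort(key=lambda iv: (iv.chrom, iv.start))

    # per-PWM "TF" tracks: a peak over every planted instance of that PWM,
    # padded so a peak can plausibly cover a labeling bin
    hw = config.tf_peak_halfwidth
    for pwm in pwms:
        track_name = f"TF_{pwm.id}"
        ivs = []
        for inst in motif_instances:
            if inst.pwm_id != pwm.id:
                continue
            mid = inst.interval.midpoint
            ivs.append(
                GenomicInterval(
                    inst.interval.chrom,
                    max(0, mid - hw),
                    min(config.chromosome_length, mid + hw),
                )
            )
        ivs.sort(key=lambda iv: (iv.chrom, iv.start))
        tracks[track_name] = ivs

    genome = Genome(
        {name: "".join(_BASES[i] for i in arr) for name, arr in seqs.items()}
    )
    truth = GroundTruth(enhancers=enhancers, motif_instances=motif_instances, tracks=tracks)

    if out_dir is not None:
        write_regulome_files(genome, truth, out_dir)
    return genome, truth


def generate_snps_and_credible_sets(
    config: RegulomeConfig,
    genome: Genome,
    truth: GroundTruth,
    motif_library: list[PWM] | None = None,
) -> GroundTruth:
    """Plant per-signal causal SNPs plus LD-companion SNPs and assign PPAs.

    Mutates and returns ``truth`` (fills signals/snps/ppa). The causal SNP
    sits at a high-information-content position of a planted motif (with
    probability ``causal_in_motif_fraction``) and its alt allele is the
    least likely base at that PWM column; companion SNPs are placed within
    +/- ``ld_window`` bp outside any motif instance.
    """
    rng = np.random.default_rng(config.seed + 1)
    if motif_library is None:
        motif_library = default_motif_library(config.n_tf_tracks)
    pwm_by_id = {p.id: p for p in motif_library}

    enhancers_with_motifs = sorted({m.enhancer_index for m in truth.motif_instances})
    if config.n_signals > len(enhancers_with_motifs):
        raise ValueError("more signals requested than enhancers with motifs")
    chosen = rng.choice(enhancers_with_motifs, size=config.n_signals, replace=False)

    # companion SNPs must not fall inside (or within a conv-filter width of)
    # any planted motif, so their true regulatory effect is ~0
    pad = 15
    motif_cover: dict[str, set[int]] = {}
    for m in truth.motif_instances:
        motif_cover.setdefault(m.interval.chrom, set()).update(
            range(m.interval.start - pad, m.interval.end + pad)
        )

    taken_positions: set[tuple[str, int]] = set()
    traits = ["traitA", "traitB", "traitC"]
    snp_counter = 0

    def new_snp(chrom: str, pos0: int, alt_idx: int | None = None) -> SNPRecord:
        nonlocal snp_counter
        snp_counter += 1
        ref = genome[chrom][pos0]
        if alt_idx is None:
            alts = [b for b in _BASES if b != ref]
            alt = alts[rng.integers(3)]
        else:
            alt = _BASES[alt_idx]
        return SNPRecord(f"rs{snp_counter}", chrom, pos0 + 1, ref, alt)

    for si, ei in enumerate(chosen):
        enh = truth.enhancers[int(ei)]
        chrom = enh.chrom
        instances = [m for m in truth.motif_instances if m.enhancer_index == int(ei)]
        in_motif = rng.random() < config.causal_in_motif_fraction

        if in_motif:
            inst = instances[rng.integers(len(instances))]
            pwm = pwm_by_id[inst.pwm_id]
            ic = information_content(pwm)
            # highest-IC column away from the motif edges: edge columns sit
            # at the boundary of any width-limited detector's footprint
            interior = np.arange(2, pwm.width - 2)
            col = int(interior[np.argmax(ic[interior])])
            if inst.strand == "+":
                pos0 = inst.interval.start + col
                column = pwm.matrix[col]
                ref_base = genome[chrom][pos0]
                ref_idx = _BASES.index(ref_base)
                order = np.argsort(column)  # ascending probability
                alt_idx = int(order[0]) if order[0] != ref_idx else int(order[1])
            else:
                pos0 = inst.interval.end - 1 - col
                column = pwm.matrix[col][::-1]  # complement order on - strand
                ref_base = genome[chrom][pos0]
                ref_idx = _BASES.index(ref_base)
                order = np.argsort(column)
                alt_idx = int(order[0]) if order[0] != ref_idx else int(order[1])
        else:
            pos0 = int(rng.integers(enh.start, enh.end))
            while (chrom, pos0) in taken_positions or pos0 in motif_cover.get(chrom, set()):
                pos0 = int(rng.integers(enh.start, enh.end))
            alt_idx = None

        if (chrom, pos0) in taken_positions:
            continue  # extremely unlikely; signal dropped rather than reused
        taken_positions.add((chrom, pos0))
        causal = new_snp(chrom, pos0, alt_idx)

        n_snps = int(rng.integers(config.snps_per_signal[0], config.snps_per_signal[1] + 1))
        members = [causal]
        guard = 0
        while len(members) < n_snps and guard < 1000:
            guard += 1
            offset = int(rng.integers(-config.ld_window, config.ld_window))
            p = causal.pos0 + offset
            if not (1000 <= p < genome.length(chrom) - 1000):
                continue
            if (chrom, p) in taken_positions or p in motif_cover.get(chrom, set()):
                continue
            taken_positions.add((chrom, p))
            members.append(new_snp(chrom, p))

        # LD companions outside the credible set (non-functional neighbors)
        n_ld = int(rng.integers(config.ld_snps_per_signal[0],
                                config.ld_snps_per_signal[1] + 1))
        ld_members: list[SNPRecord] = []
        guard = 0
        while len(ld_members) < n_ld and guard < 1000:
            guard += 1
            offset = int(rng.integers(-config.ld_window, config.ld_window))
            p = causal.pos0 + offset
            if not (1000 <= p < genome.length(chrom) - 1000):
                continue
            if (chrom, p) in taken_positions or p in motif_cover.get(chrom, set()):
                continue
            taken_positions.add((chrom, p))
            ld_members.append(new_snp(chrom, p))

        # PPA: Dirichlet mass scaled into (0.95, 1.0]; shuffled so the causal
        # SNP is not systematically PPA-max
        mass = 0.951 + 0.049 * rng.random()
        ppa = rng.dirichlet(np.ones(len(members))) * mass
        order = rng.permutation(len(members))
        trait = traits[si % len(traits)]
        signal = Signal(
            signal_id=f"signal{si+1}",
            trait=trait,
            causal_snp_id=causal.id,
            snp_ids=[members[j].id for j in order],
            ld_snp_ids=[s.id for s in ld_members],
        )
        truth.signals.append(signal)
        truth.snps.extend(members)
        truth.snps.extend(ld_members)
        truth.ppa[signal.signal_id] = {
            members[j].id: float(ppa[j]) for j in order
        }
    return truth


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_regulome_files(genome: Genome, truth: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(genome, out / "genome.fa")
    tracks_dir = out / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for name, ivs in truth.tracks.items():
        write_bed(ivs, tracks_dir / f"{name}.bed")
    write_bed(truth.enhancers, out / "enhancers.bed")
    motif_ivs = [
        GenomicInterval(
            m.interval.chrom, m.interval.start, m.interval.end,
            strand=m.strand, name=m.pwm_id, score=float(m.enhancer_index),
        )
        for m in truth.motif_instances
    ]
    write_bed(motif_ivs, out / "motif_instances.bed")
    (out / "ground_truth.json").write_text(ground_truth_json(truth))


def write_snp_files(truth: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_snp_table(truth.snps, out / "snps.tsv")
    snp_by_id = {s.id: s for s in truth.snps}
    with open(out / "credible_sets.tsv", "w") as fh:
        fh.write("signal_id\ttrait\tsnp_id\tchrom\tpos\tref\talt\tppa\n")
        for sig in truth.signals:
            for snp_id in sig.snp_ids:
                snp = snp_by_id[snp_id]
                ppa = truth.ppa[sig.signal_id][snp_id]
                fh.write(
                    f"{sig.signal_id}\t{sig.trait}\t{snp_id}\t{snp.chrom}\t"
                    f"{snp.pos}\t{snp.ref}\t{snp.alt}\t{ppa:.6f}\n"
                )


def ground_truth_json(truth: GroundTruth) -> str:
    def iv(v: GenomicInterval) -> dict:
        return {"chrom": v.chrom, "start": v.start, "end": v.end}

    payload = {
        "enhancers": [iv(e) for e in truth.enhancers],
        "motif_instances": [
            {**iv(m.interval), "pwm_id": m.pwm_id, "strand": m.strand,
             "enhancer_index": m.enhancer_index}
            for m in truth.motif_instances
        ],
        "tracks": {name: [iv(v) for v in ivs] for name, ivs in truth.tracks.items()},
        "signals": [asdict(s) for s in truth.signals],
        "causal_snps": {s.signal_id: s.causal_snp_id for s in truth.signals},
        "ppa": truth.ppa,
    }
    return json.dumps(payload, indent=1, sort_keys=True)
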