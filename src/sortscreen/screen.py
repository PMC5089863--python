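"""Forward model of the surface-display / FACS / deep-sequencing screen.

The simulator provides ground truth for every downstream stage. Each library
variant ``v`` carries a hidden relative phosphorylation rate ``k_v``. A
first-order reaction stopped early (bulk completion capped at 30% by default)
gives a per-cell phosphorylation level ``p_v = 1 - exp(-k_v * tau)``, with
``tau`` solved so the pool-averaged completion matches the configured cap —
mirroring a quenched kinase reaction sampled in its initial-rate regime.
Cell fluorescence is ``p_v`` times a lognormal per-cell display factor; a FACS
gate keeps the brightest ``gate_fraction`` of the pool; sorted and unsorted
populations are sequenced.

Specificity presets encode the qualitative substrate rules of the two T cell
kinases this assay was built around: ZAP-70 (lysine/arginine excluded within
seven residues of the tyrosine, strong -1 aspartate preference, +1 Glu or
hydrophobic and +3 hydrophobic bonuses) and Lck (-1 bulky-hydrophobic
preference, -1 Asp penalty, substrate discrimination mostly downstream of the
tyrosine).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .library import (
    STOP,
    PeptideSpec,
    ScanningLibrary,
    parse_variant_key,
)

HYDROPHOBIC = set("LIVMF")
BULKY_HYDROPHOBIC = set("LIFMV")


@dataclass(frozen=True)
class PresetMagnitudes:
    """Effect sizes (natural-log units on the relative *rate*) for presets.

    Magnitudes are on the kinetic scale measured with purified peptides,
    where single charge-altering substitutions change rates modestly (tens of
    percent, e.g. a single Glu-to-Lys change costs ~30-40%); the screen's
    narrow fluorescence gate then amplifies these modest rate effects into
    order-of-magnitude enrichment effects, which is why K/R substitutions
    read out as severe in the screen yet stay above the tyrosine-null floor.
    """

    kr_penalty: float = 0.5
    his_penalty: float = 0.25
    acidic_bonus: float = 0.12
    minus1_asp: float = 0.35
    plus1_bonus: float = 0.15
    plus3_hydrophobic: float = 0.25
    minus1_hydrophobic: float = 0.35
    minus1_asp_penalty: float = 0.45
    downstream_kr_penalty: float = 0.45
    downstream_kr_bonus: float = 0.25
    downstream_acid_penalty: float = 0.15
    upstream_acid_penalty: float = 0.06
    jitter_sigma: float = 0.05


@dataclass(frozen=True)
class SpecificityModel:
    """Additive log-rate substrate model around a focal tyrosine.

    ``prefs`` maps (offset relative to the focal tyrosine, amino acid) to a raw
    log-preference. The *effect* of a substitution is the preference difference
    to the wild-type residue at that offset, so wild-type effects are exactly 0
    by construction. Focal-tyrosine substitutions and stop variants are
    phosphorylation-null (rate 0).
    """

    base_log_rate: float = 0.0
    prefs: dict[tuple[int, str], float] = field(default_factory=dict)
    kind: str = "custom"

    def pref(self, offset: int, aa: str) -> float:
        return self.prefs.get((offset, aa), 0.0)

    def effect(self, offset: int, aa: str, wt_aa: str) -> float:
        """Log-rate effect of placing ``aa`` where the parent has ``wt_aa``."""
        return self.pref(offset, aa) - self.pref(offset, wt_aa)


def preset_model(
    kind: str,
    magnitudes: PresetMagnitudes | None = None,
    rng_seed: int = 0,
    flank: int = 7,
) -> SpecificityModel:
    """Build a named specificity preset.

    ``zap70-like``: K/R penalised at every offset in [-flank, +flank], milder
    histidine penalty, acidic residues mildly favoured, a strong -1 Asp bonus,
    +1 Glu/hydrophobic and +3 hydrophobic bonuses.

    ``lck-like``: -1 bulky-hydrophobic bonus and -1 Asp penalty; K/R penalised
    only at +1..+3 but favoured at +4..+7; acidic residues mildly penalised,
    more downstream than upstream.

    ``flat``: all preferences zero (no selection).

    A small seeded Gaussian jitter (``jitter_sigma``) is added to every
    preference so no two cells of the preference table tie exactly;
    deterministic for a fixed seed.
    """
    mags = magnitudes or PresetMagnitudes()
    if kind not in {"zap70-like", "lck-like", "flat"}:
        raise ValueError(f"unknown preset kind: {kind!r}")
    prefs: dict[tuple[int, str], float] = {}
    if kind != "flat":
        rng = np.random.default_rng(rng_seed)
        offsets = [o for o in range(-flank, flank + 1) if o != 0]
        for o in offsets:
            for aa in "ACDEFGHIKLMNPQRSTVWY":
                p = 0.0
                if kind == "zap70-like":
                    if aa in "KR":
                        p -= mags.kr_penalty
                    elif aa == "H":
                        p -= mags.his_penalty
                    elif aa in "DE":
                        p += mags.acidic_bonus
                    if o == -1 and aa == "D":
                        p += mags.minus1_asp
                    if o == 1 and (aa == "E" or aa in HYDROPHOBIC):
                        p += mags.plus1_bonus
                    if o == 3 and aa in HYDROPHOBIC:
                        p += mags.plus3_hydrophobic
                else:  # lck-like
                    if aa in "KR":
                        if 1 <= o <= 3:
                            p -= mags.downstream_kr_penalty
                        elif o >= 4:
                            p += mags.downstream_kr_bonus
                    elif aa in "DE":
                        p -= (mags.downstream_acid_penalty if o > 0
                              else mags.upstream_acid_penalty)
                    if o == -1:
                        if aa in BULKY_HYDROPHOBIC:
                            p += mags.minus1_hydrophobic
                        elif aa == "D":
                            p -= mags.minus1_asp_penalty
                p += rng.normal(0.0, mags.jitter_sigma)
                prefs[(o, aa)] = p
    return SpecificityModel(base_log_rate=0.0, prefs=prefs, kind=kind)


def variant_rate(model: SpecificityModel, variant_key: str, spec: PeptideSpec) -> float:
    """Relative phosphorylation rate of an amino-acid-level variant.

    WT maps to ``exp(base_log_rate)``; focal-tyrosine substitutions and stop
    variants are null (rate 0); single mutants get the exponential of the
    base log rate plus the substitution's effect.
    """
    if variant_key == "WT":
        return math.exp(model.base_log_rate)
    wt, pos, mut = parse_variant_key(variant_key)
    i = pos - spec.numbering_offset
    if not 0 <= i < len(spec.sequence) or spec.sequence[i] != wt:
        raise ValueError(f"variant {variant_key} outside the model's peptide frame")
    if mut == STOP or pos == spec.focal_tyr:
        return 0.0
    offset = spec.offset_of(pos)
    return math.exp(model.base_log_rate + model.effect(offset, mut, wt))


@dataclass
class ScreenConfig:
    """Screen parameters, defaulting to the assay's stated conditions.

    ``n_cells`` cells are collected for each population; the FACS gate keeps
    the brightest 15-25% (default 20%); the kinase reaction is quenched at 30%
    bulk completion; sequencing targets >= 500 reads per variant on average.
    """

    n_cells: int = 1_000_000
    gate_fraction: float = 0.20
    max_bulk_completion: float = 0.30
    display_noise_sigma: float = 0.3
    reads_per_variant: int = 500
    seq_error_rate: float = 0.001
    adapter5: str = "ACACTCTTTCCCTACACGACGC"
    adapter3: str = "AGATCGGAAGAGCACACGTCTG"
    read_length: int = 75
    rng_seed: int = 0
    allow_gate_override: bool = False

    def __post_init__(self) -> None:
        for name in ("gate_fraction", "max_bulk_completion", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.gate_fraction <= 0:
            raise ValueError("gate_fraction must be positive")
        if not 0.15 <= self.gate_fraction <= 0.25 and not self.allow_gate_override:
            raise ValueError(
                f"gate_fraction {self.gate_fraction} outside the assay's stated "
                "15-25% range; pass allow_gate_override=True to force it"
            )
        if self.display_noise_sigma < 0:
            raise ValueError("display_noise_sigma must be >= 0")
        if self.n_cells <= 0 or self.reads_per_variant <= 0:
            raise ValueError("n_cells and reads_per_variant must be positive")


@dataclass
class ScreenResult:
    """Sorted/unsorted count tables plus the hidden truth table."""

    unsorted_counts: dict[str, int]
    sorted_counts: dict[str, int]
    truth: dict[str, float]
    realized_completion: float
    tau: float

    def truth_to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "variant_key": list(self.truth),
                "rate": list(self.truth.values()),
                "unsorted": [self.unsorted_counts[k] for k in self.truth],
                "sorted": [self.sorted_counts[k] for k in self.truth],
            }
        ).to_csv(path, sep="\t", index=False)


def solve_reaction_time(
    freqs: np.ndarray, rates: np.ndarray, target_completion: float
) -> tuple[float, float]:
    """Reaction time tau with pool-averaged completion at the target.

    Bulk completion ``sum_v f_v (1 - exp(-k_v tau))`` increases monotonically
    in tau towards the attainable maximum (the input mass with nonzero rate);
    if the target exceeds it, phosphorylatable variants are run to completion.
    Returns (tau, realized completion).
    """
    attainable = float(freqs[rates > 0].sum())
    if attainable == 0.0:
        raise ValueError("degenerate screen: every variant has rate 0")

    def completion(tau: float) -> float:
        return float((freqs * -np.expm1(-rates * tau)).sum())

    if target_completion >= attainable * (1 - 1e-12):
        tau = -math.log(1e-12) / rates[rates > 0].min()
        return tau, completion(tau)
    hi = 1.0
    while completion(hi) < target_completion:
        hi *= 2.0
    tau = brentq(lambda t: completion(t) - target_completion, 0.0, hi, xtol=1e-12)
    return float(tau), completion(float(tau))


def simulate_screen(
    library: ScanningLibrary,
    model: SpecificityModel,
    config: ScreenConfig,
    input_freq: dict[str, float] | None = None,
) -> ScreenResult:
    """Simulate one screen: reaction, FACS gate, population sampling.

    The cell pool is drawn multinomially from the library's expected pooled
    composition (or ``input_freq`` if given); per-cell fluorescence is the
    variant's phospho fraction times a lognormal display factor (unit mean);
    the gate keeps the brightest ``gate_fraction`` of the pool with random
    tie-breaking; both collected populations hold ``n_cells`` cells.
    Bit-for-bit reproducible for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    keys = library.variant_keys
    comp = input_freq or library.expected_freq
    freqs = np.array([comp.get(k, 0.0) for k in keys])
    freqs = freqs / freqs.sum()
    rates = np.array([variant_rate(model, k, library.spec) for k in keys])

    tau, realized = solve_reaction_time(freqs, rates, config.max_bulk_completion)
    p = -np.expm1(-rates * tau)

    n = config.n_cells
    unsorted_counts = rng.multinomial(n, freqs)

    # independent pool passing through the sorter
    pool_counts = rng.multinomial(n, freqs)
    cell_variant = np.repeat(np.arange(len(keys)), pool_counts)
    sigma = config.display_noise_sigma
    if sigma > 0:
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
    else:
        noise = np.ones(n)
    fluor = p[cell_variant] * noise

    k_gate = max(1, int(round(config.gate_fraction * n)))
    perm = rng.permutation(n)  # random tie-break among equal fluorescences
    order = np.argsort(fluor[perm], kind="stable")
    gated = perm[order[-k_gate:]]
    gated_counts = np.bincount(cell_variant[gated], minlength=len(keys))
    sorted_counts = rng.multinomial(n, gated_counts / gated_counts.sum())

    return ScreenResult(
        unsorted_counts=dict(zip(keys, unsorted_counts.tolist())),
        sorted_counts=dict(zip(keys, sorted_counts.tolist())),
        truth=dict(zip(keys, rates.tolist())),
        realized_completion=realized,
        tau=tau,
    )


def sequence_counts(
    population_counts: dict[str, int],
    total_reads: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Count-level sequencing model: multinomial sampling of ``total_reads``
    reads from a population's composition (the FASTQ path without the FASTQ)."""
    keys = list(population_counts)
    c = np.array([population_counts[k] for k in keys], dtype=float)
    reads = rng.multinomial(total_reads, c / c.sum())
    return dict(zip(keys, reads.tolist()))


def _allocate_reads(counts: dict[str, int], total: int) -> dict[str, int]:
    """Deterministic largest-remainder allocation of ``total`` reads
    proportional to ``counts``."""
    keys = list(counts)
    c = np.array([counts[k] for k in keys], dtype=float)
    if c.sum() == 0:
        raise ValueError("cannot allocate reads: population is empty")
    exact = total * c / c.sum()
    base = np.floor(exact).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return dict(zip(keys, base.tolist()))


def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, int(round(-10 * math.log10(error_rate))))
    return chr(33 + q)


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_fastq(
    result: ScreenResult,
    library: ScanningLibrary,
    config: ScreenConfig,
    r1_path,
    r2_path,
    population: str = "sorted",
) -> dict[str, int]:
    """Write adapter-flanked paired-end reads for one population.

    Reads per amino-acid variant follow a deterministic largest-remainder
    allocation of ``reads_per_variant * n_dna_members`` total pairs (the
    per-variant depth target applies to the DNA-level pool, e.g. 500 x 640 for
    a 20-position library) proportional to the population counts; synonymous
    codon members of a key are cycled round-robin. Substitution errors at ``seq_error_rate`` per base; Phred+33
    qualities consistent with the error model. Returns the per-variant read
    allocation (the exact oracle for downstream counting when the error rate
    is zero).
    """
    counts = result.sorted_counts if population == "sorted" else result.unsorted_counts
    keys = library.variant_keys
    alloc = _allocate_reads({k: counts[k] for k in keys},
                            config.reads_per_variant * len(library.members))
    by_key: dict[str, list[str]] = {}
    for m in library.members:
        by_key.setdefault(m.variant_key, []).append(m.dna_seq)

    frag_len = len(config.adapter5) + len(library.members[0].dna_seq) + len(config.adapter3)
    if config.read_length > frag_len:
        raise ValueError(
            f"read_length {config.read_length} exceeds fragment length {frag_len}"
        )
    if 2 * config.read_length < frag_len:
        raise ValueError("mates would not overlap; increase read_length")

    rng = np.random.default_rng([config.rng_seed, 1 if population == "sorted" else 2])
    err = config.seq_error_rate
    qual = _phred_char(err) * config.read_length
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def corrupt(read: str) -> str:
        if err <= 0:
            return read
        arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
        hits = np.nonzero(rng.random(arr.size) < err)[0]
        if hits.size:
            # substitute with a uniformly chosen *different* base
            subs = bases[rng.integers(0, 3, size=hits.size)]
            subs[subs == arr[hits]] = bases[3]
            arr[hits] = subs
        return arr.tobytes().decode()

    serial = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for key in keys:
            dnas = by_key[key]
            for j in range(alloc[key]):
                frag = config.adapter5 + dnas[j % len(dnas)] + config.adapter3
                r1 = corrupt(frag[: config.read_length])
                r2 = corrupt(revcomp(frag)[: config.read_length])
                rid = f"{population}.{serial}"
                f1.write(f"@{rid}/1\n{r1}\n+\n{qual}\n")
                f2.write(f"@{rid}/2\n{r2}\n+\n{qual}\n")
                serial += 1
    return alloc
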