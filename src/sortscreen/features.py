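"""Phosphosite electrostatic feature analytics.

Operates on 15-residue phosphosite windows (seven residues on each side of
the acceptor tyrosine, X-padded at protein termini). Net charge is the simple
count (#K + #R) - (#D + #E): histidine and everything else contribute zero.
Substrate tables are binned on (net charge, -1 residue), with the -1 axis
ordered by BLOSUM62 similarity to aspartate — the two determinants that set
ZAP-70 substrates (acidic, -1 Asp) apart from typical tyrosine-kinase
substrates (near-neutral, -1 bulky-hydrophobic or polar). Sequence logos are
computed from user-provided gap-free alignments as per-column frequencies
scaled by information content in bits.

A synthetic substrate-table generator stands in for curated phosphosite lists
(download out of scope): LAT-like windows (acidic, -1 Asp, no K/R), ITAM-like
windows (-1 Leu/Ile, near-neutral, downstream K/R allowed), and a broad
generic class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices
from scipy.ndimage import gaussian_filter

from .library import AMINO_ACIDS

PAD = "X"
_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}


def net_charge(sequence: str) -> int:
    """(#K + #R) - (#D + #E); histidine and all other residues count 0.

    X (terminal padding) is ignored; any other non-standard letter is an
    error. Applies equally to 15-mer windows and whole kinase domains.
    """
    bad = set(sequence) - set(AMINO_ACIDS) - {PAD}
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    return sum(_CHARGE.get(aa, 0) for aa in sequence)


@dataclass(frozen=True)
class SubstrateWindow:
    """A phosphosite window: 7 residues + Y + 7 residues, X-padded."""

    protein_id: str
    site_pos: int  # 1-based tyrosine position in the source protein
    window: str

    def __post_init__(self) -> None:
        if len(self.window) != 15:
            raise ValueError("window must be exactly 15 residues")
        if self.window[7] != "Y":
            raise ValueError("window center must be the phospho-acceptor Y")

    @property
    def net_charge(self) -> int:
        return net_charge(self.window)

    @property
    def minus1(self) -> str:
        return self.window[6]


def extract_window(sequence: str, site_pos: int, protein_id: str = "",
                   flank: int = 7) -> SubstrateWindow:
    """Cut the +/-flank window around a tyrosine at 1-based ``site_pos``."""
    if not 1 <= site_pos <= len(sequence):
        raise ValueError(f"site position {site_pos} outside sequence")
    if sequence[site_pos - 1] != "Y":
        raise ValueError(
            f"residue at {site_pos} is {sequence[site_pos - 1]!r}, expected Y"
        )
    lo, hi = site_pos - 1 - flank, site_pos + flank
    left = PAD * max(0, -lo)
    right = PAD * max(0, hi - len(sequence))
    window = left + sequence[max(0, lo):hi] + right
    return SubstrateWindow(protein_id=protein_id, site_pos=site_pos, window=window)


def minus1_axis(matrix_name: str = "BLOSUM62") -> list[str]:
    """The 20 residues ordered by descending substitution score against
    aspartate (ties alphabetical); D first, E adjacent."""
    mat = substitution_matrices.load(matrix_name)
    return sorted(AMINO_ACIDS, key=lambda aa: (-mat[aa, "D"], aa))


@dataclass
class ChargeBinning2D:
    """2D histogram of windows over (net charge, -1 residue)."""

    x_axis: list[int]            # integer net-charge bins
    y_axis: list[str]            # residues, D-similarity order
    grid: pd.DataFrame           # counts, rows = y_axis, cols = x_axis
    density: pd.DataFrame        # kernel-smoothed grid for contour rendering
    bandwidth: float

    def to_tsv(self, path) -> None:
        self.grid.rename_axis("minus1").to_csv(path, sep="\t")


def bin_substrates(
    windows: list[SubstrateWindow],
    bandwidth: float = 1.0,
    matrix_name: str = "BLOSUM62",
) -> ChargeBinning2D:
    """Bin substrate windows on net charge and -1-residue identity.

    Counts are exact (the grid sums to the number of inputs); the density is a
    Gaussian-smoothed copy (default bandwidth: 1 charge unit x 1 rank unit)
    used only for contour rendering. Windows whose -1 position is terminal
    padding cannot be binned and are an error; filter them upstream.
    """
    if not windows:
        raise ValueError("no substrate windows supplied")
    if any(w.minus1 == PAD for w in windows):
        raise ValueError("window with padded -1 residue cannot be binned")
    y_axis = minus1_axis(matrix_name)
    charges = [w.net_charge for w in windows]
    x_axis = list(range(min(charges), max(charges) + 1))
    grid = pd.DataFrame(0, index=y_axis, columns=x_axis)
    for w, c in zip(windows, charges):
        grid.loc[w.minus1, c] += 1
    density = pd.DataFrame(
        gaussian_filter(grid.to_numpy(dtype=float), sigma=bandwidth),
        index=y_axis, columns=x_axis,
    )
    return ChargeBinning2D(x_axis=x_axis, y_axis=y_axis, grid=grid,
                           density=density, bandwidth=bandwidth)


@dataclass
class LogoMatrix:
    """Per-position letter frequencies and information content (bits)."""

    freq: pd.DataFrame        # rows = positions (0-based), cols = 20 residues
    info_bits: pd.Series      # 0 .. log2(20)
    n_sequences: int

    @property
    def heights(self) -> pd.DataFrame:
        """Letter heights: frequency x column information content."""
        return self.freq.mul(self.info_bits, axis=0)

    def to_tsv(self, path) -> None:
        out = self.freq.copy()
        out["info_bits"] = self.info_bits
        out.rename_axis("position").to_csv(path, sep="\t")


def make_logo(sequences: list[str], small_sample_correction: bool = False) -> LogoMatrix:
    """Column frequencies and information content of a gap-free alignment.

    IC(col) = log2(20) - H(col), optionally minus the small-sample correction
    (20-1)/(2 ln2 n), clipped at zero. X padding is excluded from the counts
    (and from n for the correction).
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    (width,) = lengths
    aas = list(AMINO_ACIDS)
    freq = pd.DataFrame(0.0, index=range(width), columns=aas)
    info = pd.Series(0.0, index=range(width))
    for j in range(width):
        col = [s[j] for s in sequences]
        bad = set(col) - set(AMINO_ACIDS) - {PAD}
        if bad:
            raise ValueError(f"non-amino-acid characters in column {j}: {sorted(bad)}")
        letters = [c for c in col if c != PAD]
        n = len(letters)
        if n == 0:
            continue
        counts = pd.Series(letters).value_counts()
        p = counts.reindex(aas, fill_value=0) / n
        freq.loc[j] = p
        entropy = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
        ic = math.log2(20) - entropy
        if small_sample_correction:
            ic -= (20 - 1) / (2 * math.log(2) * n)
        info[j] = max(0.0, ic)
    return LogoMatrix(freq=freq, info_bits=info, n_sequences=len(sequences))


def plot_logo(logo: LogoMatrix, path) -> None:
    """Render a stacked-letter sequence logo with matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    heights = logo.heights
    fig, ax = plt.subplots(figsize=(0.5 * len(heights) + 1, 3))
    colors = {aa: ("#d62728" if aa in "DE" else "#1f77b4" if aa in "KRH"
                   else "#2ca02c" if aa in "STNQ" else "#333333")
              for aa in AMINO_ACIDS}
    for j in heights.index:
        y = 0.0
        for aa, h in heights.loc[j].sort_values().items():
            if h <= 0:
                continue
            ax.text(j, y + h / 2, aa, ha="center", va="center",
                    fontsize=14, color=colors[aa],
                    fontweight="bold", clip_on=True)
            y += h
    ax.set_xlim(-0.5, len(heights) - 0.5)
    ax.set_ylim(0, math.log2(20))
    ax.set_xlabel("alignment position")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_contour(binning: ChargeBinning2D, path) -> None:
    """Contour plot of the smoothed (net charge, -1 residue) density."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.contourf(binning.x_axis, range(len(binning.y_axis)),
                binning.density.to_numpy(), levels=12, cmap="Greys")
    ax.set_yticks(range(len(binning.y_axis)), binning.y_axis)
    ax.set_xlabel("net charge of +/-7 window")
    ax.set_ylabel("-1 residue (BLOSUM62 similarity to D)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# -- synthetic substrate tables ------------------------------------------------

_NEUTRAL = "AGSTNQPVLIMFWCH"  # zero-charge residues under the housed formula


def _fill_window(rng: np.random.Generator, minus1: str, target_charge: int,
                 allow_kr: bool, kr_downstream_only: bool = False) -> str:
    """Draw a 15-mer window with the requested -1 residue and net charge."""
    slots = [i for i in range(15) if i not in (6, 7)]  # 13 free positions
    window = [""] * 15
    window[7] = "Y"
    window[6] = minus1
    charge = _CHARGE.get(minus1, 0)
    need = target_charge - charge
    pos_slots = []
    if need > 0:
        if not allow_kr:
            raise ValueError("positive target charge requires K/R")
        candidates = [i for i in slots if (i > 7 or not kr_downstream_only)]
        pos_slots = list(rng.choice(candidates, size=need, replace=False))
    neg_slots: list[int] = []
    if need < 0:
        free = [i for i in slots if i not in pos_slots]
        neg_slots = list(rng.choice(free, size=-need, replace=False))
    for i in slots:
        if i in pos_slots:
            window[i] = "KR"[rng.integers(2)]
        elif i in neg_slots:
            window[i] = "DE"[rng.integers(2)]
        else:
            window[i] = _NEUTRAL[rng.integers(len(_NEUTRAL))]
    return "".join(window)


def synthetic_substrate_table(
    n: int,
    class_mix: dict[str, float] | None = None,
    rng_seed: int = 0,
) -> list[SubstrateWindow]:
    """Generate a synthetic stand-in for a curated phosphosite table.

    Classes: ``lat-like`` (-1 Asp, net charge uniform in [-8, -4], no K/R),
    ``itam-like`` (-1 Leu/Ile, net charge in [-1, +1], K/R only downstream),
    ``generic`` (-1 drawn from all residues, net charge ~ binomial centred on
    0, clipped to [-4, +4]). The default mix (10% LAT-like, 20% ITAM-like,
    70% generic) mirrors a kinome-wide substrate list in which acidic ZAP-70
    substrates are rare outliers. Seeded and reproducible.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mix = class_mix or {"lat-like": 0.1, "itam-like": 0.2, "generic": 0.7}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    rng = np.random.default_rng(rng_seed)
    classes = list(mix)
    draws = rng.choice(len(classes), size=n, p=[mix[c] for c in classes])
    out: list[SubstrateWindow] = []
    for i, ci in enumerate(draws):
        cls = classes[ci]
        if cls == "lat-like":
            w = _fill_window(rng, "D", int(rng.integers(-8, -3)), allow_kr=False)
        elif cls == "itam-like":
            w = _fill_window(rng, "LI"[rng.integers(2)], int(rng.integers(-1, 2)),
                             allow_kr=True, kr_downstream_only=True)
        elif cls == "generic":
            minus1 = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
            target = int(np.clip(rng.binomial(8, 0.5) - 4, -4, 4))
            base = _CHARGE.get(minus1, 0)
            target = max(target, base - 13) if target < 0 else target
            w = _fill_window(rng, minus1, target, allow_kr=True)
        else:
            raise ValueError(f"unknown substrate class: {cls!r}")
        out.append(SubstrateWindow(protein_id=f"synthetic_{cls}_{i}",
                                   site_pos=8, window=w))
    return out


def windows_to_tsv(windows: list[SubstrateWindow], path) -> None:
    pd.DataFrame(
        [
            {"protein_id": w.protein_id, "site_pos": w.site_pos,
             "window": w.window, "net_charge": w.net_charge, "minus1": w.minus1}
            for w in windows
        ]
    ).to_csv(path, sep="\t", index=False)


def windows_from_tsv(path) -> list[SubstrateWindow]:
    df = pd.read_csv(path, sep="\t")
    return [
        SubstrateWindow(protein_id=str(r.protein_id), site_pos=int(r.site_pos),
                        window=r.window)
        for r in df.itertuples()
    ]


def windows_from_sites(fasta_path, sites: pd.DataFrame, flank: int = 7) -> list[SubstrateWindow]:
    """Extract windows from protein FASTA + a (protein_id, site_pos) table."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    out = []
    for r in sites.itertuples():
        if r.protein_id not in seqs:
            raise ValueError(f"protein {r.protein_id!r} not in FASTA")
        out.append(extract_window(seqs[r.protein_id], int(r.site_pos),
                                  protein_id=str(r.protein_id), flank=flank))
    return out
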