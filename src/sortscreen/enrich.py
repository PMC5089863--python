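"""Normalized enrichment scoring, replicate aggregation, detection floor.

The statistic: for variant x with frequency f_x in the sorted and unsorted
populations,

    normalized enrichment = (f_x^sorted / f_x^unsorted)
                            / (f_ref^sorted / f_ref^unsorted)

reported on a log10 scale, with the wild-type peptide as the reference for
scanning libraries (so the reference is exactly 0 on the log scale: positive
values mean a substitution enhanced phosphorylation, negative values mean it
diminished it). Replicates are combined as the mean of per-replicate log10
enrichments with the sample standard deviation as the error estimate.
Substituting the focal tyrosine abolishes phosphorylation entirely, so the
mean enrichment of focal-tyrosine substitutions marks the assay's detection
floor: values at or below it are indistinguishable from "not phosphorylated".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import AMINO_ACIDS, STOP, PeptideSpec, parse_variant_key

AA_ORDER = list(AMINO_ACIDS)  # fixed column order for all matrix exports


@dataclass
class FrequencyTable:
    freqs: pd.Series
    pseudocount: float
    population: str  # "sorted" | "unsorted"


def frequencies(
    counts: dict[str, int] | pd.Series,
    pseudocount: float = 0.5,
    population: str = "unsorted",
) -> FrequencyTable:
    """Variant frequencies f_x = (count_x + pc) / sum_y (count_y + pc).

    The default pseudocount of 0.5 keeps log enrichments finite for variants
    that drop out of the sorted pool, with negligible bias at 500x depth.
    """
    c = pd.Series(counts, dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    total = (c + pseudocount).sum()
    if total <= 0:
        raise ValueError("cannot compute frequencies of an all-zero count table")
    return FrequencyTable(freqs=(c + pseudocount) / total,
                          pseudocount=pseudocount, population=population)


@dataclass
class EnrichmentTable:
    values: pd.Series
    log10_values: pd.Series
    reference_key: str
    masked: list[str] = field(default_factory=list)


def normalized_enrichment(
    f_sorted: FrequencyTable,
    f_unsorted: FrequencyTable,
    reference_key: str = "WT",
) -> EnrichmentTable:
    """Per-variant enrichment ratio normalized to a reference member.

    Variants with zero unsorted frequency (possible only with a zero
    pseudocount) are flagged and masked rather than silently dropped. The
    reference maps to exactly 1 (log10 exactly 0).
    """
    fs, fu = f_sorted.freqs, f_unsorted.freqs
    if reference_key not in fs.index or reference_key not in fu.index:
        raise ValueError(f"reference {reference_key!r} absent from a frequency table")
    if fs[reference_key] == 0 or fu[reference_key] == 0:
        raise ValueError(f"reference {reference_key!r} has zero frequency")
    common = fs.index.intersection(fu.index)
    fs, fu = fs[common], fu[common]
    masked = list(common[(fu == 0) | (fs == 0)])
    ref_ratio = fs[reference_key] / fu[reference_key]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (fs / fu) / ref_ratio
        log10_values = np.log10(values)
    values[masked] = np.nan
    log10_values[masked] = np.nan
    values[reference_key] = 1.0
    log10_values[reference_key] = 0.0
    return EnrichmentTable(values=values, log10_values=log10_values,
                           reference_key=reference_key, masked=masked)


@dataclass
class EnrichmentMatrix:
    """Position x amino-acid grid of replicate-averaged log10 enrichments."""

    spec: PeptideSpec
    mean_log10: pd.DataFrame   # rows: positions (source numbering), cols: residues
    sd_log10: pd.DataFrame
    n_replicates: pd.DataFrame
    floor: float | None = None

    @property
    def mask(self) -> pd.DataFrame:
        return self.mean_log10.isna()

    @property
    def below_floor(self) -> pd.DataFrame:
        if self.floor is None:
            raise ValueError("detection floor not computed yet")
        return self.mean_log10 <= self.floor

    def wt_residue(self, position: int) -> str:
        return self.spec.sequence[position - self.spec.numbering_offset]

    def cell(self, variant_key: str) -> float:
        wt, pos, mut = parse_variant_key(variant_key)
        return float(self.mean_log10.loc[pos, mut])

    def to_tsv(self, path) -> None:
        self.mean_log10.rename_axis("position").to_csv(path, sep="\t")

    def variant_table(self) -> pd.DataFrame:
        """Long-format per-variant export: mean, sd, n, below-floor flag."""
        rows = []
        for pos in self.mean_log10.index:
            for aa in self.mean_log10.columns:
                mean = self.mean_log10.loc[pos, aa]
                if np.isnan(mean):
                    continue
                wt = self.wt_residue(pos)
                rows.append({
                    "variant_key": "WT" if aa == wt else f"{wt}{pos}{aa}",
                    "position": pos,
                    "amino_acid": aa,
                    "mean_log10": mean,
                    "sd_log10": self.sd_log10.loc[pos, aa],
                    "n_replicates": int(self.n_replicates.loc[pos, aa]),
                    "below_floor": (bool(mean <= self.floor)
                                    if self.floor is not None else None),
                })
        return pd.DataFrame(rows)


def aggregate_replicates(
    tables: list[EnrichmentTable],
    spec: PeptideSpec,
    include_stop: bool = False,
) -> EnrichmentMatrix:
    """Combine replicate enrichment tables into a heatmap matrix.

    Per cell: mean and sample standard deviation (ddof=1; 0 when n=1) of the
    replicate log10 values. Wild-type cells are 0 by construction (the
    reference convention), stop-variant cells are excluded unless requested,
    and cells measured in no replicate are left masked (NaN).
    """
    if not tables:
        raise ValueError("need at least one replicate")
    positions = [spec.position(i) for i in range(len(spec.sequence))]
    columns = AA_ORDER + ([STOP] if include_stop else [])
    shape = (len(positions), len(columns))
    acc: dict[tuple[int, str], list[float]] = {}
    for t in tables:
        for key, val in t.log10_values.items():
            if key == "WT" or math.isnan(val):
                continue
            wt, pos, mut = parse_variant_key(key)
            if pos not in positions:
                raise ValueError(f"variant {key} outside peptide frame of {spec.name}")
            if spec.sequence[pos - spec.numbering_offset] != wt:
                raise ValueError(f"variant {key} disagrees with parent sequence")
            if mut == STOP and not include_stop:
                continue
            acc.setdefault((pos, mut), []).append(float(val))
    mean = pd.DataFrame(np.full(shape, np.nan), index=positions, columns=columns)
    sd = pd.DataFrame(np.full(shape, np.nan), index=positions, columns=columns)
    n = pd.DataFrame(np.zeros(shape, dtype=int), index=positions, columns=columns)
    for (pos, mut), vals in acc.items():
        mean.loc[pos, mut] = float(np.mean(vals))
        sd.loc[pos, mut] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        n.loc[pos, mut] = len(vals)
    for i, wt in enumerate(spec.sequence):
        pos = spec.position(i)
        mean.loc[pos, wt] = 0.0
        sd.loc[pos, wt] = 0.0
        n.loc[pos, wt] = len(tables)
    return EnrichmentMatrix(spec=spec, mean_log10=mean, sd_log10=sd, n_replicates=n)


def detection_floor(matrix: EnrichmentMatrix, spec: PeptideSpec) -> float:
    """Mean log10 enrichment of focal-tyrosine substitutions.

    These variants cannot be phosphorylated, so their depletion level is the
    assay's lower detection limit; the value is stored on the matrix and
    ``below_floor`` annotates (never censors) cells at or beneath it.
    """
    row = matrix.mean_log10.loc[spec.focal_tyr]
    drop = ["Y"] + ([STOP] if STOP in row.index else [])
    vals = row.drop(labels=drop).dropna()
    if vals.empty:
        raise ValueError("no focal-tyrosine substitutions measured")
    matrix.floor = float(vals.mean())
    return matrix.floor


def plot_heatmap(matrix: EnrichmentMatrix, path, title: str | None = None) -> None:
    """Render the mutational heatmap (positions x residues) to an image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.mean_log10.T  # residues as rows, positions as columns
    fig, ax = plt.subplots(figsize=(0.45 * len(data.columns) + 2, 7))
    lim = np.nanmax(np.abs(data.values)) or 1.0
    im = ax.imshow(data.values, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    ax.set_xticks(range(len(data.columns)), [str(p) for p in data.columns], rotation=90)
    ax.set_yticks(range(len(data.index)), data.index)
    ax.set_xlabel("position")
    ax.set_ylabel("substituted residue")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="mean log10 normalized enrichment")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
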