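"""Paired-end read processing: merge, trim, translate, count.

Simplified, self-contained equivalents of the merge/trim tools commonly used
for amplicon screens: mates are merged at the maximal-score overlap with
higher-quality-base conflict resolution and a mean-quality filter (Q30 by
default); adapters are located by substitution-only matching. Counting is at
the amino-acid level with synonymous codons pooled; reads differing from the
parent at two or more residues are discarded, since a scanning library
contains only single mutants (a sequencing error inside the randomized codon
is therefore accepted as a miscall — a documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import STOP, ScanningLibrary, make_variant_key
from .screen import revcomp

REJECT_REASONS = (
    "merge_fail",
    "adapter_fail",
    "frame_fail",
    "stop_codon",
    "multi_mutant",
    "unmatched",
)


class Reject(NamedTuple):
    reason: str


@dataclass(frozen=True)
class ReadPair:
    r1_seq: str
    r2_seq: str
    r1_qual: str
    r2_qual: str

    def __post_init__(self) -> None:
        for seq, qual in ((self.r1_seq, self.r1_qual), (self.r2_seq, self.r2_qual)):
            if len(seq) != len(qual):
                raise ValueError("sequence and quality lengths disagree")
            if set(seq) - set("ACGTN"):
                raise ValueError("sequence alphabet must be {A,C,G,T,N}")
            for ch in qual:
                if not 33 <= ord(ch) <= 75:
                    raise ValueError(
                        "quality characters outside the Phred+33 range "
                        "(Phred+64 input is not supported)"
                    )


class Merged(NamedTuple):
    seq: str
    qual: str


@dataclass
class CountTable:
    """Per-variant counts plus an accounting of every rejected read."""

    counts: dict[str, int]
    rejected: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REJECT_REASONS}
    )
    total_reads: int = 0

    def check(self) -> None:
        assigned = sum(self.counts.values()) + sum(self.rejected.values())
        if assigned != self.total_reads:
            raise AssertionError(
                f"accounting identity violated: {assigned} != {self.total_reads}"
            )

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"variant_key": list(self.counts), "count": list(self.counts.values())}
        ).to_csv(path, sep="\t", index=False)

    @staticmethod
    def counts_from_tsv(path) -> dict[str, int]:
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return dict(zip(df["variant_key"], df["count"].astype(int)))


def merge_pair(pair: ReadPair, min_overlap: int = 10, q_threshold: int = 30) -> Merged | Reject:
    """Merge mates at the maximal-score overlap.

    The reverse mate is reverse-complemented and slid against the forward mate;
    each candidate overlap is scored matches-minus-mismatches and the best
    (ties to the longer overlap) is kept, provided the overlap spans at least
    ``min_overlap`` bases and the score is positive. Conflicting overlap
    positions take the higher-quality base; agreeing positions take the higher
    of the two qualities. Pairs whose merged mean quality falls below
    ``q_threshold`` are rejected.
    """
    r1 = pair.r1_seq
    rc2 = revcomp(pair.r2_seq)
    rq2 = pair.r2_qual[::-1]
    n1, n2 = len(r1), len(rc2)
    a1 = np.frombuffer(r1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(rc2.encode(), dtype=np.uint8)

    best: tuple[int, int, int] | None = None  # (score, overlap, offset)
    for off in range(-(n2 - min_overlap), n1 - min_overlap + 1):
        lo1, hi1 = max(0, off), min(n1, off + n2)
        ov = hi1 - lo1
        if ov < min_overlap:
            continue
        s1 = a1[lo1:hi1]
        s2 = a2[lo1 - off: hi1 - off]
        score = 2 * int((s1 == s2).sum()) - ov
        if best is None or (score, ov) > (best[0], best[1]):
            best = (score, ov, off)
    if best is None or best[0] <= 0:
        return Reject("merge_fail")
    _, _, off = best

    q1 = np.frombuffer(pair.r1_qual.encode(), dtype=np.uint8)
    q2 = np.frombuffer(rq2.encode(), dtype=np.uint8)
    start, end = min(0, off), max(n1, off + n2)
    seq = np.zeros(end - start, dtype=np.uint8)
    qual = np.zeros(end - start, dtype=np.uint8)
    # lay down mate 2, then resolve mate 1's span against it
    seq[off - start: off - start + n2] = a2
    qual[off - start: off - start + n2] = q2
    span1 = slice(-start, -start + n1)
    other_s = seq[span1].copy()
    other_q = qual[span1].copy()
    covered = other_s != 0
    win1 = ~covered | (q1 >= other_q)  # conflicts: higher quality wins, ties to r1
    agree = covered & (a1 == other_s)
    seq[span1] = np.where(win1, a1, other_s)
    new_q = np.where(win1, q1, other_q)
    new_q[agree] = np.maximum(q1, other_q)[agree]
    qual[span1] = new_q

    merged_qual = qual - 33
    if merged_qual.mean() < q_threshold:
        return Reject("merge_fail")
    return Merged(seq.tobytes().decode(), qual.tobytes().decode())


def _best_match(read: str, adapter: str, max_mismatch: int, from_right: bool) -> int | None:
    """Start index of the best full-length adapter occurrence, or None.

    Scans all alignments; accepts the occurrence with the fewest mismatches
    (<= ``max_mismatch``), preferring the leftmost (5' adapter) or rightmost
    (3' adapter) on ties.
    """
    la = len(adapter)
    if la == 0:
        raise ValueError("adapters must be non-empty")
    if la > len(read):
        return None
    a = np.frombuffer(adapter.encode(), dtype=np.uint8)
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    positions = range(len(read) - la + 1)
    if from_right:
        positions = reversed(positions)
    best_pos, best_mm = None, max_mismatch + 1
    for p in positions:
        mm = int((r[p: p + la] != a).sum())
        if mm < best_mm:
            best_pos, best_mm = p, mm
            if mm == 0:
                break
    return best_pos if best_mm <= max_mismatch else None


def trim_adapters(
    merged: Merged | str, adapter5: str, adapter3: str, max_mismatch: int = 2
) -> str | Reject:
    """Excise the insert between the 5' and 3' adapters.

    Substitution-only matching with at most ``max_mismatch`` mismatches per
    adapter; any bases outside the adapters are discarded with them.
    """
    seq = merged.seq if isinstance(merged, Merged) else merged
    p5 = _best_match(seq, adapter5, max_mismatch, from_right=False)
    if p5 is None:
        return Reject("adapter_fail")
    p3 = _best_match(seq, adapter3, max_mismatch, from_right=True)
    if p3 is None or p3 < p5 + len(adapter5):
        return Reject("adapter_fail")
    return seq[p5 + len(adapter5): p3]


def translate_and_match(insert: str, library: ScanningLibrary) -> str | Reject:
    """Map an insert's translation onto a library variant key.

    The insert must span the full displayed region in frame. Zero differences
    from the parent protein map to ``"WT"``; exactly one difference maps to
    that substitution's key (a stop at the randomized position included, as
    every sub-library carries one stop member); two or more differences are
    rejected as ``multi_mutant`` (``stop_codon`` when a stop is involved).
    """
    region_nt = 3 * len(library.parent_protein)
    if len(insert) != region_nt or len(insert) % 3:
        return Reject("frame_fail")
    if set(insert) - set("ACGT"):
        return Reject("unmatched")
    protein = str(Seq(insert).translate())
    parent = library.parent_protein
    diffs = [i for i, (a, b) in enumerate(zip(protein, parent)) if a != b]
    if not diffs:
        return "WT"
    if len(diffs) == 1:
        i = diffs[0]
        return make_variant_key(parent[i], library.spec.position(i), protein[i])
    if any(protein[i] == STOP for i in diffs):
        return Reject("stop_codon")
    return Reject("multi_mutant")


@dataclass(frozen=True)
class ProcessingParams:
    adapter5: str
    adapter3: str
    min_overlap: int = 10
    q_threshold: int = 30
    max_mismatch: int = 2


def count_reads(
    r1_path, r2_path, library: ScanningLibrary, params: ProcessingParams
) -> CountTable:
    """Stream a FASTQ pair through merge -> trim -> match and tally.

    Every read pair lands either in a variant count or in a reject tally, so
    the accounting identity ``sum(counts) + sum(rejected) == total_reads``
    holds on every run. Identical (r1, r2) pairs are memoized, which makes
    deep counting of low-diversity amplicon pools fast.
    """
    table = CountTable(counts={k: 0 for k in library.variant_keys})
    cache: dict[tuple[str, str], str | Reject] = {}

    def classify(s1: str, q1: str, s2: str, q2: str) -> str | Reject:
        pair = ReadPair(s1, s2, q1, q2)
        merged = merge_pair(pair, params.min_overlap, params.q_threshold)
        if isinstance(merged, Reject):
            return merged
        insert = trim_adapters(merged, params.adapter5, params.adapter3, params.max_mismatch)
        if isinstance(insert, Reject):
            return insert
        return translate_and_match(insert, library)

    with open(r1_path) as f1, open(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for i, ((t1, s1, q1), (t2, s2, q2)) in enumerate(zip(it1, it2, strict=True)):
            key = (s1 + "\0" + q1, s2 + "\0" + q2)
            outcome = cache.get(key)
            if outcome is None:
                try:
                    outcome = classify(s1, q1, s2, q2)
                except ValueError as exc:
                    raise ValueError(f"malformed record {i} ({t1}): {exc}") from exc
                cache[key] = outcome
            table.total_reads += 1
            if isinstance(outcome, Reject):
                table.rejected[outcome.reason] += 1
            else:
                table.counts[outcome] = table.counts.get(outcome, 0) + 1
    table.check()
    return table
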