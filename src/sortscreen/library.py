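"""NNS scanning point-mutagenesis library design.

A scanning library covers every single amino-acid substitution across a
displayed peptide. One sub-library is built per residue position by replacing
that position's codon with the degenerate NNS codon (N = A/C/G/T, S = G/C),
giving 32 codons that encode all 20 amino acids plus a single stop (TAG).
Sub-libraries are pooled with equal stoichiometry, so the wild-type protein —
encoded once (or more, for amino acids with several NNS codons) in *every*
sub-library — is strongly over-represented relative to any individual point
mutant.

Coordinates: user-facing residue numbers follow the source protein's numbering
(e.g. LAT residues 214-233 around Tyr 226) via an explicit offset; internal
indices are 0-based.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

#: Fixed reverse-translation table. Every codon is NNS-compatible (third base
#: G or C) so the parent DNA sequence is itself a member of the sub-library
#: randomizing any of its positions.
DEFAULT_CODON_TABLE: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

_KEY_RE = re.compile(r"^([A-Y])(\d+)([A-Y*])$")


@dataclass(frozen=True)
class PeptideSpec:
    """A displayed peptide region with source-protein residue numbering.

    Parameters
    ----------
    name:
        Text label for the library (e.g. ``"LAT-Y226"``).
    aa_sequence:
        One-letter amino-acid sequence of the displayed region, before any
        background substitutions.
    numbering_offset:
        Residue number (in the source protein) of the first character of
        ``aa_sequence``; e.g. 214 for a library spanning LAT residues 214-233.
    focal_tyr:
        Residue number of the phospho-acceptor tyrosine.
    background_subs:
        Fixed substitutions applied before library construction, written in
        source numbering (e.g. ``["Y132F"]``).
    """

    name: str
    aa_sequence: str
    numbering_offset: int
    focal_tyr: int
    background_subs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.aa_sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residues in peptide: {sorted(bad)}")
        if not 1 <= len(self.aa_sequence):
            raise ValueError("empty peptide")
        if not self.numbering_offset <= self.focal_tyr < self.numbering_offset + len(self.aa_sequence):
            raise ValueError("focal tyrosine outside the peptide region")
        if self.sequence[self.focal_index] != "Y":
            raise ValueError(
                f"residue at position {self.focal_tyr} is "
                f"{self.sequence[self.focal_index]!r}, expected Y"
            )

    @property
    def sequence(self) -> str:
        """Parent amino-acid sequence with background substitutions applied."""
        seq = list(self.aa_sequence)
        for sub in self.background_subs:
            wt, pos, mut = parse_variant_key(sub)
            i = pos - self.numbering_offset
            if not 0 <= i < len(seq):
                raise ValueError(f"background substitution {sub} outside peptide")
            if seq[i] != wt:
                raise ValueError(f"background substitution {sub}: parent has {seq[i]}")
            if mut == STOP:
                raise ValueError("background substitution may not introduce a stop")
            seq[i] = mut
        return "".join(seq)

    @property
    def focal_index(self) -> int:
        """0-based index of the focal tyrosine within the peptide."""
        return self.focal_tyr - self.numbering_offset

    def position(self, index: int) -> int:
        """Source-protein residue number of 0-based ``index``."""
        return self.numbering_offset + index

    def offset_of(self, position: int) -> int:
        """Offset of a residue number relative to the focal tyrosine."""
        return position - self.focal_tyr


def parse_variant_key(key: str) -> tuple[str, int, str]:
    """Split a variant key like ``"D225K"`` into (wt, position, mutant).

    ``"*"`` as the mutant denotes a stop codon. ``"WT"`` is not parseable here;
    callers handle it explicitly.
    """
    m = _KEY_RE.match(key)
    if m is None:
        raise ValueError(f"malformed variant key: {key!r}")
    wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    return wt, pos, mut


def make_variant_key(wt: str, position: int, mut: str) -> str:
    return "WT" if wt == mut else f"{wt}{position}{mut}"


def enumerate_nns() -> pd.DataFrame:
    """Enumerate the 32 NNS codons and their translation products.

    Returns a DataFrame with columns ``codon`` and ``product`` ('*' for the
    single stop, TAG). Deterministic; covers all 20 amino acids.
    """
    rows = []
    for b1, b2, b3 in itertools.product("ACGT", "ACGT", "GC"):
        codon = b1 + b2 + b3
        rows.append({"codon": codon, "product": str(Seq(codon).translate())})
    return pd.DataFrame(rows)


def nns_multiplicity() -> dict[str, int]:
    """Number of NNS codons encoding each amino acid (and '*')."""
    table = enumerate_nns()
    return table["product"].value_counts().to_dict()


def reverse_translate(spec: PeptideSpec | str, codon_table: dict[str, str] | None = None) -> str:
    """Back-translate a peptide to DNA with a fixed, documented codon table.

    The returned DNA translates exactly to the input (with background
    substitutions applied when a :class:`PeptideSpec` is given).
    """
    if codon_table is None:
        codon_table = DEFAULT_CODON_TABLE
    seq = spec.sequence if isinstance(spec, PeptideSpec) else spec
    try:
        return "".join(codon_table[aa] for aa in seq)
    except KeyError as exc:
        raise ValueError(f"no codon for amino acid {exc.args[0]!r}") from None


@dataclass(frozen=True)
class LibraryMember:
    """One DNA-level member of a scanning library."""

    sublibrary_position: int  # source-protein residue number of the NNS codon
    codon: str
    dna_seq: str
    protein_seq: str
    variant_key: str

    @property
    def is_stop(self) -> bool:
        return self.variant_key.endswith(STOP)


@dataclass
class ScanningLibrary:
    """Full NNS scanning library: one 32-codon sub-library per position."""

    spec: PeptideSpec
    members: list[LibraryMember]
    expected_freq: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.expected_freq:
            self.expected_freq = expected_composition(self)

    @property
    def parent_protein(self) -> str:
        return self.spec.sequence

    @property
    def variant_keys(self) -> list[str]:
        """Amino-acid-level keys, synonymous codons pooled; WT first."""
        seen: dict[str, None] = {"WT": None}
        for m in self.members:
            seen.setdefault(m.variant_key, None)
        return list(seen)

    def single_mutant_keys(self, include_stop: bool = False) -> list[str]:
        keys = [k for k in self.variant_keys if k != "WT"]
        if not include_stop:
            keys = [k for k in keys if not k.endswith(STOP)]
        return keys

    def to_tsv(self, path) -> None:
        rows = [
            {
                "variant_key": m.variant_key,
                "position": m.sublibrary_position,
                "codon": m.codon,
                "dna_seq": m.dna_seq,
                "protein_seq": m.protein_seq,
                "expected_freq": self.expected_freq[m.variant_key],
            }
            for m in self.members
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_scanning_library(
    spec: PeptideSpec, codon_table: dict[str, str] | None = None
) -> ScanningLibrary:
    """Enumerate all NNS point mutants of the parent peptide.

    One sub-library per residue position, each with all 32 NNS codons at that
    position; DNA-level size is ``len(peptide) * 32``. Variant identity is at
    the amino-acid level: synonymous NNS codons share a key, and codons
    re-encoding the wild-type residue map to ``"WT"``.
    """
    parent_dna = reverse_translate(spec, codon_table)
    parent_aa = spec.sequence
    nns = enumerate_nns()
    members: list[LibraryMember] = []
    for i, wt_aa in enumerate(parent_aa):
        pos = spec.position(i)
        for codon, product in zip(nns["codon"], nns["product"]):
            dna = parent_dna[: 3 * i] + codon + parent_dna[3 * i + 3:]
            protein = parent_aa[:i] + product + parent_aa[i + 1:]
            members.append(
                LibraryMember(
                    sublibrary_position=pos,
                    codon=codon,
                    dna_seq=dna,
                    protein_seq=protein,
                    variant_key=make_variant_key(wt_aa, pos, product),
                )
            )
    return ScanningLibrary(spec=spec, members=members)


def expected_composition(library: ScanningLibrary) -> dict[str, float]:
    """Expected pooled frequency of each amino-acid-level variant key.

    With equimolar sub-library pooling every DNA-level member has frequency
    ``1 / (n_positions * 32)``; a key's frequency is the number of codons that
    yield it, summed over sub-libraries. The WT key aggregates the wild-type
    codon multiplicities of every sub-library, which is why the parent protein
    is over-represented roughly ``n_positions``-fold relative to a typical
    point mutant.
    """
    n = len(library.members)
    freq: dict[str, float] = {}
    for m in library.members:
        freq[m.variant_key] = freq.get(m.variant_key, 0.0) + 1.0 / n
    return freq


def spec_from_fasta(path, numbering_offset: int, focal_tyr: int,
                    background_subs: tuple[str, ...] = ()) -> PeptideSpec:
    """Load a peptide spec from the first record of a FASTA file."""
    record = next(SeqIO.parse(path, "fasta"))
    return PeptideSpec(
        name=record.id,
        aa_sequence=str(record.seq),
        numbering_offset=numbering_offset,
        focal_tyr=focal_tyr,
        background_subs=background_subs,
    )


def library_from_tsv(path, spec: PeptideSpec) -> ScanningLibrary:
    """Re-load a library exported with :meth:`ScanningLibrary.to_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"codon": str})
    members = [
        LibraryMember(
            sublibrary_position=int(r.position),
            codon=r.codon,
            dna_seq=r.dna_seq,
            protein_seq=r.protein_seq,
            variant_key=r.variant_key,
        )
        for r in df.itertuples()
    ]
    return ScanningLibrary(spec=spec, members=members)
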