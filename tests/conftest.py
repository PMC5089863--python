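import pytest

from sortscreen import PeptideSpec, build_scanning_library


@pytest.fixture(scope="session")
def lat_y226_spec() -> PeptideSpec:
    """The printed LAT 219-233 peptide around Tyr 226."""
    return PeptideSpec(
        name="LAT-Y226",
        aa_sequence="EEEGAPDYENLGELN",
        numbering_offset=219,
        focal_tyr=226,
    )


@pytest.fixture(scope="session")
def lat_y226_library(lat_y226_spec):
    return build_scanning_library(lat_y226_spec)


@pytest.fixture(scope="session")
def demo20_spec() -> PeptideSpec:
    """A 20-residue scanning-library parent in the LAT Tyr 226 format.

    The five N-terminal residues are a synthetic extension of the printed
    15-mer; numbering runs 214-233 with the focal tyrosine at 226.
    """
    return PeptideSpec(
        name="LAT-Y226-20mer",
        aa_sequence="ASNLSEEEGAPDYENLGELN",
        numbering_offset=214,
        focal_tyr=226,
    )


@pytest.fixture(scope="session")
def demo20_library(demo20_spec):
    return build_scanning_library(demo20_spec)
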