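"""Shared fixtures: the worked 9-mer query, noise-free scans, small proteomes."""

from __future__ import annotations

import pytest

import xreact as x

CONTACTS = frozenset({3, 4, 5, 8})
ANCHORS = frozenset({2, 9})


@pytest.fixture(scope="session")
def query() -> x.EpitopePeptide:
    """The CD22-derived HLA-A*02:01 9-mer used as the worked example."""
    return x.validate_peptide("FLSNDTVQL")


@pytest.fixture(scope="session")
def blosum62() -> x.SubstitutionMatrix:
    return x.SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def noise_free_scan(query) -> x.PositionalScanTable:
    """Scan table with contacts {3,4,5,8} and anchors {2,9} planted, no noise."""
    spec = x.SyntheticScanSpec(
        wild_type=query,
        contact_positions=CONTACTS,
        anchor_positions=ANCHORS,
        noise_sd=0.0,
    )
    return x.generate_scan_table(spec)


@pytest.fixture(scope="session")
def classification(noise_free_scan) -> x.PositionClassification:
    return x.classify_positions(noise_free_scan)


@pytest.fixture(scope="session")
def motif(classification, query) -> x.RecognitionMotif:
    return x.build_motif(classification, query)


@pytest.fixture()
def small_proteome():
    """~10^4-residue background proteome without plants, fixed seed."""
    spec = x.SyntheticProteomeSpec(seed=11)
    records, _ = x.generate_proteome(spec)
    return records
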