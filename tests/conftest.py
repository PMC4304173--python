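"""Shared fixtures: one small simulated study, fitted once per session."""

import pytest

import txmap


@pytest.fixture(scope="session")
def small_study():
    """Compact study with all three effect kinds (cluster, dosage, sex)."""
    return txmap.simulate_study(
        7, loci_per_chromosome=400, dosage_loci=100,
        chromosome_extent=12_000_000, dosage_extent=4_000_000,
        pool_sizes={"A": 6, "B": 5},
    )


@pytest.fixture(scope="session")
def small_results(small_study):
    model = txmap.DifferentialTranscriptomeMap.from_study(small_study, "A", "B")
    return model.fit()


@pytest.fixture()
def tiny_annotation():
    return [
        txmap.LocusAnnotation("PF4", "chr4", 74_846_794, 74_847_841),
        txmap.LocusAnnotation("Hs.355689", "chr4", 74_000_000, 74_020_000),
        txmap.LocusAnnotation("XIST", "chrX", 73_040_486, 73_072_588),
    ]
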