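import pytest
from hypothesis import settings

from haplodose.catalog import RegionAlignment

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_alignment() -> RegionAlignment:
    """Four 12-mers with one SNP, one multibase substitution and one deletion."""
    return RegionAlignment(
        region_id="toy",
        haplotypes=(
            ("hapA", "ACGTACGGTACG"),
            ("hapB", "ACCTACGGTACG"),  # SNP at column 3 (G -> C)
            ("hapC", "ACGTACTTTACG"),  # GG -> TT at columns 7-8
            ("hapD", "ACGTACGGT--G"),  # 2-col deletion
        ),
        reference_id="hapA",
    )
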