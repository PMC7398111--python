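from __future__ import annotations

import numpy as np
import pytest

from ssrmine.fasta_io import SequenceRecord
from ssrmine.polymorphism_pipeline import discover_polymorphic
from ssrmine.synthetic_fixtures import FixtureSpec, generate_pair


@pytest.fixture(scope="session")
def clean_fixture():
    """No-confounder assembly pair: 50 planted markers, 40% polymorphic,
    flank SNP rate well below the conservation threshold."""
    spec = FixtureSpec(seed=20240, n_ssrs=50, fraction_polymorphic=0.4,
                       flank_snp_rate=0.01)
    records_a, records_b, truth = generate_pair(spec)
    return spec, records_a, records_b, truth


@pytest.fixture(scope="session")
def confounder_fixture():
    """Pair with all three confounder classes planted (10% each)."""
    spec = FixtureSpec(seed=777, n_ssrs=50, fraction_polymorphic=0.4,
                       flank_snp_rate=0.01,
                       fraction_duplicated_flanks=0.1,
                       fraction_over_divergence=0.1,
                       fraction_near_ssr_heavy_mismatch=0.1)
    records_a, records_b, truth = generate_pair(spec)
    return spec, records_a, records_b, truth


@pytest.fixture(scope="session")
def clean_pipeline_result(clean_fixture):
    spec, records_a, records_b, truth = clean_fixture
    markers, summary = discover_polymorphic(records_a, records_b, spec.config)
    return markers, summary


@pytest.fixture(scope="session")
def boundary_record():
    """1.2-Mb sequence with SSRs planted to straddle the 500-kb fragment
    boundaries (and elsewhere), for fragmentation-invariance checks."""
    rng = np.random.default_rng(4242)
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, size=1_200_000)]

    def plant(pos0: int, motif: str, reps: int) -> None:
        unit = np.array(list(motif))
        block = np.tile(unit, reps)
        seq[pos0:pos0 + len(block)] = block
        # break the repeat at both borders so planted coordinates are exact
        left, right = pos0 - 1, pos0 + len(block)
        if seq[left] == motif[-1]:
            seq[left] = "C" if motif[-1] != "C" else "G"
        if seq[right] == motif[0]:
            seq[right] = "C" if motif[0] != "C" else "G"

    plant(499_990, "AG", 12)          # straddles the 500-kb boundary
    plant(999_988, "ACT", 9)          # straddles the 1-Mb boundary
    plant(504_980, "AAC", 10)         # inside the first overlap zone
    plant(500_050, "T", 14)           # just after the boundary
    plant(250_000, "ACGT", 8)
    plant(750_000, "AATGC", 6)
    plant(1_100_000, "GATCAC", 7)
    return SequenceRecord(id="chr1", sequence="".join(seq))
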