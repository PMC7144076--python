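import pytest

from rxsex import (
    Call,
    ChromosomeRecord,
    IdxstatsTable,
    Karyotype,
    Role,
    elephant_like_karyotype,
)
from rxsex.karyo_io import IdxstatsRow


@pytest.fixture(scope="session")
def elephant_karyotype():
    """27 autosomes + X, the paper-scale validation karyotype."""
    return elephant_like_karyotype()


@pytest.fixture
def small_karyotype():
    """Minimal valid karyotype: 3 autosomes + X."""
    return Karyotype(
        chromosomes=(
            ChromosomeRecord("chr1", 100, Role.AUTOSOME),
            ChromosomeRecord("chr2", 80, Role.AUTOSOME),
            ChromosomeRecord("chr3", 60, Role.AUTOSOME),
            ChromosomeRecord("chrX", 50, Role.SHARED_SEX),
        ),
        system="XY",
    )


def make_table(counts, karyotype, sample_id="s1"):
    """Build an IdxstatsTable with given per-name mapped counts."""
    rows = [
        IdxstatsRow(c.name, c.length, counts.get(c.name, 0), 0)
        for c in karyotype.chromosomes
        if c.name in counts
    ]
    return IdxstatsTable(rows=rows, sample_id=sample_id)


@pytest.fixture
def make_table_fn():
    return make_table
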