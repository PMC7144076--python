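"""Synthetic count tables, count-level subsampling and depth sweeps.

The simulator generates idxstats tables for an individual of known
chromosomal sex: each chromosome's expected read share is proportional to
copy number x length x an optional per-chromosome bias factor. ``noise_free``
mode emits the exact expected (real-valued) counts, so the analytic limits
(ratio exactly 1.0 for two copies, 0.5 for one) hold to machine precision;
``multinomial`` mode draws integer counts from a multinomial with those
probabilities under a seeded generator.

Subsampling draws without replacement across chromosomes (multivariate
hypergeometric), so the output total equals the target exactly — unlike
per-read Bernoulli thinning, whose realized total is only approximate.

The depth sweep repeatedly subsamples (or simulates) at a grid of depths
and records how the confidence interval degrades.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from rxsex.errors import ConfigurationError, ValidationError
from rxsex.karyo_io import (
    ChromosomeRecord,
    IdxstatsRow,
    IdxstatsTable,
    Karyotype,
    Role,
    join_counts,
)
from rxsex.rx_core import Call, ClassifierConfig, compute_rx

#: Copy number of each role for the two true sexes.
_COPY_NUMBER = {
    Call.HOMOGAMETIC: {Role.AUTOSOME: 2, Role.SHARED_SEX: 2, Role.LIMITED_SEX: 0, Role.EXCLUDED: 0},
    Call.HETEROGAMETIC: {Role.AUTOSOME: 2, Role.SHARED_SEX: 1, Role.LIMITED_SEX: 1, Role.EXCLUDED: 0},
}


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic count generator."""

    karyotype: Karyotype
    true_sex: Call
    total_reads: int
    mode: str = "multinomial"  # or "noise_free"
    bias: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_sex not in (Call.HOMOGAMETIC, Call.HETEROGAMETIC):
            raise ConfigurationError("true_sex must be homogametic or heterogametic")
        if self.total_reads < 1:
            raise ConfigurationError(
                f"total_reads must be >=1, got {self.total_reads}"
            )
        if self.mode not in ("noise_free", "multinomial"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.bias:
            unknown = set(self.bias) - set(self.karyotype.names)
            if unknown:
                raise ConfigurationError(
                    f"bias names not in karyotype: {sorted(unknown)}"
                )
            if any(b <= 0 for b in self.bias.values()):
                raise ConfigurationError("bias factors must be positive")


@dataclass(frozen=True)
class SweepResult:
    """Per-replicate results of a depth sweep plus a per-depth summary."""

    rows: pd.DataFrame  # sample_id, target_depth, replicate, rx, ci_low, ci_high, call, ci_width

    def summary(self) -> pd.DataFrame:
        """Mean CI width and unassignment rate per target depth."""
        g = self.rows.groupby("target_depth")
        out = g.agg(
            mean_ci_width=("ci_width", "mean"),
            mean_rx=("rx", "mean"),
            n=("rx", "size"),
        )
        out["unassigned_rate"] = (
            self.rows.assign(un=self.rows["call"] == Call.UNASSIGNED.value)
            .groupby("target_depth")["un"]
            .mean()
        )
        return out.reset_index()


def _expected_weights(spec: SimSpec) -> np.ndarray:
    copy = _COPY_NUMBER[spec.true_sex]
    bias = spec.bias or {}
    w = np.array(
        [
            copy[c.role] * c.length * bias.get(c.name, 1.0)
            for c in spec.karyotype.chromosomes
        ],
        dtype=float,
    )
    if w.sum() <= 0:
        raise ValidationError("all chromosome weights are zero")
    return w / w.sum()


def simulate_idxstats(spec: SimSpec) -> IdxstatsTable:
    """Generate a synthetic idxstats table for a known-sex individual.

    Rows cover every karyotype chromosome in order; excluded chromosomes
    (and the sex-limited chromosome in a homogametic individual) receive
    zero reads.
    """
    p = _expected_weights(spec)
    if spec.mode == "noise_free":
        counts = spec.total_reads * p
    else:
        rng = np.random.default_rng(spec.seed)
        counts = rng.multinomial(spec.total_reads, p).astype(float)
    rows = [
        IdxstatsRow(c.name, c.length, float(m), 0)
        for c, m in zip(spec.karyotype.chromosomes, counts)
    ]
    sex = "homo" if spec.true_sex is Call.HOMOGAMETIC else "hetero"
    return IdxstatsTable(rows=rows, sample_id=f"sim_{sex}_{spec.seed}")


def subsample_idxstats(
    table: IdxstatsTable, target_reads: int, seed: int = 0
) -> IdxstatsTable:
    """Downsample a count table to exactly ``target_reads`` mapped reads.

    Reads are removed without replacement across chromosomes (multivariate
    hypergeometric), so per-chromosome expectations scale by
    ``target/total`` while the output total is exact. Deterministic for a
    fixed seed. Requires integer counts.
    """
    if target_reads < 1:
        raise ValidationError(f"target_reads must be >=1, got {target_reads}")
    counts = np.array([r.mapped for r in table.rows])
    if not np.all(counts == np.floor(counts)):
        raise ValidationError("subsampling requires integer mapped counts")
    counts = counts.astype(np.int64)
    total = int(counts.sum())
    if target_reads > total:
        raise ValidationError(
            f"target_reads {target_reads} exceeds total mapped reads {total}"
        )
    if target_reads == total:
        new = counts
    else:
        rng = np.random.default_rng(seed)
        new = rng.multivariate_hypergeometric(counts, target_reads)
    rows = [
        IdxstatsRow(r.name, r.length, int(m), 0)
        for r, m in zip(table.rows, new)
    ]
    return IdxstatsTable(rows=rows, sample_id=table.sample_id)


def depth_sweep(
    source: Union[IdxstatsTable, SimSpec],
    depths: Sequence[int],
    replicates: int,
    seed: int = 0,
    config: ClassifierConfig | None = None,
    karyotype: Karyotype | None = None,
) -> SweepResult:
    """Measure CI degradation over a grid of read depths.

    ``source`` is either a real count table (subsampled to each depth) or a
    :class:`SimSpec` (simulated afresh at each depth). One statistic is
    computed per depth x replicate; the single seed is expanded into
    independent per-replicate streams via :class:`numpy.random.SeedSequence`.
    For a table source, ``karyotype`` is required to join the counts.
    """
    if replicates < 1:
        raise ValidationError(f"replicates must be >=1, got {replicates}")
    if not depths or any(d < 1 for d in depths):
        raise ValidationError("depths must be a nonempty list of positive integers")
    if isinstance(source, IdxstatsTable):
        if karyotype is None:
            raise ConfigurationError("karyotype is required when sweeping a table")
        total = int(source.total_mapped)
        if any(d > total for d in depths):
            raise ValidationError(
                f"depths exceed available mapped reads ({total})"
            )
    else:
        karyotype = source.karyotype

    config = config or ClassifierConfig()
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(depths) * replicates
    )
    records = []
    i = 0
    for depth in depths:
        for rep in range(replicates):
            sub_seed = int(child_seeds[i])
            i += 1
            if isinstance(source, IdxstatsTable):
                table = subsample_idxstats(source, depth, seed=sub_seed)
            else:
                table = simulate_idxstats(
                    replace(source, total_reads=depth, seed=sub_seed)
                )
            res = compute_rx(join_counts(table, karyotype), config)
            records.append(
                {
                    "sample_id": res.sample_id,
                    "target_depth": depth,
                    "replicate": rep,
                    "rx": res.rx,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "call": res.call.value,
                    "ci_width": res.ci_width,
                }
            )
    return SweepResult(rows=pd.DataFrame.from_records(records))


def elephant_like_karyotype(
    n_autosomes: int = 27,
    x_length: int = 121_000_000,
    system: str = "XY",
) -> Karyotype:
    """A chromosome-level karyotype with the elephant's 27 autosomes plus X.

    Autosome lengths decline smoothly from ~230 Mb, mimicking a typical
    mammalian chromosome-level assembly; exact lengths are synthetic. Useful
    as a default config and as the validation fixture.
    """
    records = []
    for i in range(1, n_autosomes + 1):
        length = int(230_000_000 * (0.93 ** (i - 1))) + 1
        records.append(ChromosomeRecord(f"chr{i}", length, Role.AUTOSOME))
    shared = "chrX" if system == "XY" else "chrZ"
    records.append(ChromosomeRecord(shared, x_length, Role.SHARED_SEX))
    return Karyotype(chromosomes=tuple(records), system=system)
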