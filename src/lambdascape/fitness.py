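"""Selection rates from pre/post-competition genotype counts.

The fitness of genotype ``G`` over a competition of duration ``T`` is the
selection rate relative to the ancestral generalist EvoC::

    S = ( ln(G_T / G_0) - ln(EvoC_T / EvoC_0) ) / T

where ``G_t`` is the genotype's frequency among kept unique barcodes at
time ``t``.  One competition unit is the 4-hour experiment, so ``T = 1``
by default; pass ``T = 4`` for per-hour rates.  EvoC's rate is identically
zero, and a genotype unobserved at either time point has no quantifiable
rate (missing, never imputed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    N_GENOTYPES,
    Environment,
    FitnessLandscape,
    ValidationError,
    all_genotypes,
    merge_replicates,
)
from .counting import GenotypeCounts

REFERENCE_INDEX = 0  # EvoC = all-zero genotype


@dataclass
class SelectionRateTable:
    """Per-genotype counts, frequencies and selection rates for one sample."""

    sample_id: str
    count_t0: np.ndarray
    count_T: np.ndarray
    frequency_t0: np.ndarray
    frequency_T: np.ndarray
    S: np.ndarray  # NaN where unquantifiable
    T: float = 1.0
    environment: Environment | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype": all_genotypes(),
                "count_t0": self.count_t0,
                "count_T": self.count_T,
                "frequency_t0": self.frequency_t0,
                "frequency_T": self.frequency_T,
                "S": self.S,
            }
        )


def selection_rates(
    counts_t0: GenotypeCounts,
    counts_T: GenotypeCounts,
    T: float = 1.0,
    environment: Environment | None = None,
) -> SelectionRateTable:
    """Selection rate of every genotype relative to EvoC."""
    if T <= 0:
        raise ValidationError("competition duration T must be positive")
    c0 = np.asarray(counts_t0.counts, dtype=np.int64)
    cT = np.asarray(counts_T.counts, dtype=np.int64)
    if c0.shape != (N_GENOTYPES,) or cT.shape != (N_GENOTYPES,):
        raise ValidationError("counts must cover all 512 genotypes")
    if c0[REFERENCE_INDEX] == 0 or cT[REFERENCE_INDEX] == 0:
        raise ValidationError(
            "reference genotype EvoC absent at a time point; selection rate undefined"
        )
    f0 = c0 / c0.sum()
    fT = cT / cT.sum()
    ref_log_ratio = np.log(fT[REFERENCE_INDEX] / f0[REFERENCE_INDEX])
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (np.log(fT / f0) - ref_log_ratio) / T
    s[(c0 == 0) | (cT == 0)] = np.nan
    s[REFERENCE_INDEX] = 0.0
    return SelectionRateTable(
        sample_id=counts_t0.sample_id,
        count_t0=c0,
        count_T=cT,
        frequency_t0=f0,
        frequency_T=fT,
        S=s,
        T=T,
        environment=environment,
    )


def build_landscape(
    tables: Sequence[SelectionRateTable], environment: Environment
) -> FitnessLandscape:
    """Average replicate selection-rate tables into one landscape."""
    for table in tables:
        if table.environment is not None and table.environment != environment:
            raise ValidationError("replicate tables come from different environments")
    replicates = [FitnessLandscape(environment, t.S.copy()) for t in tables]
    return merge_replicates(replicates)


def replicate_correlation(
    table_a: SelectionRateTable | FitnessLandscape,
    table_b: SelectionRateTable | FitnessLandscape,
) -> tuple[float, int]:
    """Pearson r between two replicates over genotypes quantified in both."""
    a = table_a.S if isinstance(table_a, SelectionRateTable) else table_a.values
    b = table_b.S if isinstance(table_b, SelectionRateTable) else table_b.values
    shared = np.isfinite(a) & np.isfinite(b)
    n = int(shared.sum())
    if n < 3:
        raise ValidationError(f"only {n} genotypes shared; need >= 3 for a correlation")
    r = stats.pearsonr(a[shared], b[shared]).statistic
    return float(r), n


def read_table(path) -> SelectionRateTable:
    from .core import ENVIRONMENTS

    meta: dict[str, str] = {}
    with open(path) as handle:
        pos = handle.tell()
        while True:
            line = handle.readline()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key] = val
                pos = handle.tell()
            else:
                handle.seek(pos)
                break
        frame = pd.read_csv(handle, sep="\t", na_values="NA", dtype={"genotype": str})
    order = frame.set_index("genotype").loc[all_genotypes()]
    env = ENVIRONMENTS.get(meta.get("environment", ""))
    return SelectionRateTable(
        sample_id=meta.get("sample", ""),
        count_t0=order["count_t0"].to_numpy(np.int64),
        count_T=order["count_T"].to_numpy(np.int64),
        frequency_t0=order["frequency_t0"].to_numpy(float),
        frequency_T=order["frequency_T"].to_numpy(float),
        S=order["S"].to_numpy(float),
        T=float(meta.get("T", 1.0)),
        environment=env,
    )


def write_table(table: SelectionRateTable, path) -> None:
    frame = table.to_frame()
    with open(path, "w") as handle:
        handle.write(f"#sample={table.sample_id}\n")
        if table.environment is not None:
            handle.write(f"#environment={table.environment.id}\n")
        handle.write(f"#T={table.T:.12g}\n")
        frame.to_csv(handle, sep="\t", index=False, float_format="%.12g", na_rep="NA")
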