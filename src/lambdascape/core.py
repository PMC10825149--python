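"""Genotype encoding, landscape containers, environment geometry, and TSV I/O.

The combinatorial library covers all combinations of nine biallelic mutation
sites in the phage lambda host-recognition gene *J*, giving 2**9 = 512
genotypes.  A genotype is written as a 9-character string of 0/1 with the
leftmost character denoting site 1; the all-zero string is the ancestral
generalist EvoC, the reference for all selection rates.

A :class:`FitnessLandscape` maps each genotype to a selection rate ``S``
(log fold-change in frequency relative to EvoC per competition unit, where
one unit is the 4-hour competition experiment).  Genotypes whose selection
rate could not be quantified are stored as NaN ("missing").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_SITES = 9
N_GENOTYPES = 2**N_SITES
WILDTYPE = "0" * N_SITES  # the EvoC ancestor

__all__ = [
    "N_SITES",
    "N_GENOTYPES",
    "WILDTYPE",
    "MutationSite",
    "Environment",
    "ENVIRONMENTS",
    "FitnessLandscape",
    "encode_genotype",
    "decode_genotype",
    "genotype_index",
    "genotype_from_index",
    "all_genotypes",
    "hamming_distance",
    "read_landscape",
    "write_landscape",
    "fill_missing",
    "merge_replicates",
    "read_sites",
    "write_sites",
    "multiplicity_of_infection",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


# ---------------------------------------------------------------------------
# mutation-site metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationSite:
    """One biallelic mutation site within the J amplicon.

    ``index`` is the 1-based site number (1..9, ordered along the gene);
    ``nucleotide_position`` is the 1-based position of the site in the
    reference amplicon; ``ref_allele``/``alt_allele`` are single nucleotides.
    """

    index: int
    nucleotide_position: int
    ref_allele: str
    alt_allele: str
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.index <= N_SITES:
            raise ValidationError(f"site index {self.index} outside 1..{N_SITES}")
        if self.nucleotide_position < 1:
            raise ValidationError("nucleotide_position must be 1-based positive")
        for allele in (self.ref_allele, self.alt_allele):
            if len(allele) != 1 or allele.upper() not in "ACGT":
                raise ValidationError(f"allele {allele!r} is not a single nucleotide")
        if self.ref_allele.upper() == self.alt_allele.upper():
            raise ValidationError("ref and alt alleles must differ")


def validate_sites(sites: Sequence[MutationSite]) -> tuple[MutationSite, ...]:
    """Check that site metadata covers sites 1..9 with increasing positions."""
    ordered = tuple(sorted(sites, key=lambda s: s.index))
    indices = [s.index for s in ordered]
    if indices != list(range(1, N_SITES + 1)):
        raise ValidationError(f"site indices {indices} do not cover 1..{N_SITES}")
    positions = [s.nucleotide_position for s in ordered]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValidationError("nucleotide positions must be strictly increasing")
    return ordered


# ---------------------------------------------------------------------------
# genotype encoding
# ---------------------------------------------------------------------------


def encode_genotype(mutations_present: Iterable[int]) -> str:
    """Canonical 0/1 string for the genotype carrying the given sites.

    The leftmost character is site 1.  The empty set encodes EvoC.
    """
    bits = ["0"] * N_SITES
    for index in mutations_present:
        if not 1 <= int(index) <= N_SITES:
            raise ValidationError(f"site index {index} outside 1..{N_SITES}")
        bits[int(index) - 1] = "1"
    return "".join(bits)


def decode_genotype(key: str) -> frozenset[int]:
    """Set of mutated site indices encoded by ``key``."""
    _check_key(key)
    return frozenset(i + 1 for i, c in enumerate(key) if c == "1")


def _check_key(key: str) -> None:
    if len(key) != N_SITES or any(c not in "01" for c in key):
        raise ValidationError(f"malformed genotype string {key!r}")


def genotype_index(key: str) -> int:
    """Integer index of a genotype: site ``i`` contributes bit ``i-1``."""
    _check_key(key)
    return int(key[::-1], 2)


def genotype_from_index(index: int) -> str:
    if not 0 <= index < N_GENOTYPES:
        raise ValidationError(f"genotype index {index} outside 0..{N_GENOTYPES - 1}")
    return format(index, f"0{N_SITES}b")[::-1]


def all_genotypes() -> list[str]:
    """All 512 genotype strings in index order (EvoC first)."""
    return [genotype_from_index(i) for i in range(N_GENOTYPES)]


def hamming_distance(a: str, b: str) -> int:
    """Number of sites at which two genotypes differ (0..9)."""
    _check_key(a)
    _check_key(b)
    return sum(x != y for x, y in zip(a, b))


# Bit matrix over all genotypes: row g, column s-1 is 1 iff site s mutated.
def genotype_bit_matrix() -> np.ndarray:
    idx = np.arange(N_GENOTYPES)[:, None]
    return ((idx >> np.arange(N_SITES)[None, :]) & 1).astype(np.uint8)


# ---------------------------------------------------------------------------
# environments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Environment:
    """One competition environment in which a landscape was measured.

    ``axis_coordinate`` is the landscape-axis position: the abundance-weighted
    population specialization index of the measurement condition (pure-OmpF
    hosts at +1, pure-LamB hosts at -1, mixed-host conditions placed by the
    90% competitor's SI).
    """

    id: str
    hosts: str
    competitor: str
    axis_coordinate: float


ENVIRONMENTS: dict[str, Environment] = {
    "A": Environment("A", "OmpF_only", "EvoC", +1.0),
    "B": Environment("B", "mixed", "L_specialist", +0.7),
    "C": Environment("C", "mixed", "EvoC", 0.0),
    "D": Environment("D", "mixed", "O_specialist", -0.9),
    "E": Environment("E", "LamB_only", "EvoC", -1.0),
}


# ---------------------------------------------------------------------------
# fitness landscapes
# ---------------------------------------------------------------------------


@dataclass
class FitnessLandscape:
    """Per-environment map genotype -> selection rate, NaN = unobserved."""

    environment: Environment
    values: np.ndarray = field(
        default_factory=lambda: np.full(N_GENOTYPES, np.nan)
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_GENOTYPES,):
            raise ValidationError(
                f"landscape needs {N_GENOTYPES} values, got {self.values.shape}"
            )

    @classmethod
    def from_dict(
        cls, environment: Environment, mapping: Mapping[str, float]
    ) -> "FitnessLandscape":
        values = np.full(N_GENOTYPES, np.nan)
        for key, s in mapping.items():
            values[genotype_index(key)] = s
        return cls(environment, values)

    def __getitem__(self, key: str) -> float:
        return float(self.values[genotype_index(key)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FitnessLandscape):
            return NotImplemented
        return self.environment == other.environment and np.array_equal(
            self.values, other.values, equal_nan=True
        )

    @property
    def observed_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"genotype": all_genotypes(), "selection_rate": self.values}
        )


def fill_missing(landscape: FitnessLandscape, floor: float = -10.0) -> FitnessLandscape:
    """Assign ``floor`` to unobserved genotypes (default -10).

    Genotypes never seen at the end of a competition were too unfit to
    quantify; the floor makes them uniformly (and severely) unfit instead of
    undefined, so that every genotype has a rate for phenotyping and
    simulation.
    """
    values = landscape.values.copy()
    values[~np.isfinite(values)] = floor
    return replace(landscape, values=values)


def merge_replicates(landscapes: Sequence[FitnessLandscape]) -> FitnessLandscape:
    """Average replicate landscapes genotype-wise over observed values.

    A genotype missing in some replicates contributes only its observed
    values (missing is not zero); one missing in all replicates stays missing.
    """
    if not landscapes:
        raise ValidationError("no landscapes to merge")
    env = landscapes[0].environment
    if any(l.environment != env for l in landscapes):
        raise ValidationError("cannot merge landscapes from different environments")
    stack = np.vstack([l.values for l in landscapes])
    observed = np.isfinite(stack)
    totals = np.where(observed, stack, 0.0).sum(axis=0)
    counts = observed.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
    return FitnessLandscape(env, mean)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def write_landscape(landscape: FitnessLandscape, path: str | Path) -> None:
    """Write a landscape TSV with environment metadata header lines."""
    env = landscape.environment
    lines = [
        "# genotype string: leftmost character = site 1; 0 = EvoC allele",
        f"#environment={env.id}",
        f"#competitor={env.competitor}",
        f"#hosts={env.hosts}",
        f"#axis={_FLOAT_FMT % env.axis_coordinate}",
        "genotype\tselection_rate",
    ]
    for key, s in zip(all_genotypes(), landscape.values):
        text = "NA" if not math.isfinite(s) else _FLOAT_FMT % s
        lines.append(f"{key}\t{text}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_landscape(path: str | Path) -> FitnessLandscape:
    meta: dict[str, str] = {}
    values = np.full(N_GENOTYPES, np.nan)
    seen: set[str] = set()
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            fields = line.split("\t")
            if fields[0] == "genotype":
                continue
            if len(fields) != 2:
                raise ValidationError(f"malformed landscape row {line!r}")
            key, text = fields
            _check_key(key)
            if key in seen:
                raise ValidationError(f"duplicate genotype row {key!r}")
            seen.add(key)
            values[genotype_index(key)] = np.nan if text == "NA" else float(text)
    try:
        env = Environment(
            id=meta["environment"],
            hosts=meta["hosts"],
            competitor=meta["competitor"],
            axis_coordinate=float(meta["axis"]),
        )
    except KeyError as exc:
        raise ValidationError(f"landscape file missing header field {exc}") from exc
    return FitnessLandscape(env, values)


def write_sites(sites: Sequence[MutationSite], path: str | Path) -> None:
    ordered = validate_sites(sites)
    lines = ["index\tnucleotide_position\tref_allele\talt_allele\tlabel"]
    for s in ordered:
        lines.append(
            f"{s.index}\t{s.nucleotide_position}\t{s.ref_allele}\t{s.alt_allele}\t{s.label}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_sites(path: str | Path) -> tuple[MutationSite, ...]:
    sites = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("index"):
            raise ValidationError("sites TSV must start with an 'index' header")
        for line in handle:
            if not line.strip():
                continue
            idx, pos, ref, alt, *rest = line.rstrip("\n").split("\t")
            label = rest[0] if rest else ""
            sites.append(MutationSite(int(idx), int(pos), ref, alt, label))
    return validate_sites(sites)


# ---------------------------------------------------------------------------
# experiment-design arithmetic
# ---------------------------------------------------------------------------


def multiplicity_of_infection(total_pfu: float, total_cfu: float) -> float:
    """Phage particles per host cell at the start of a competition."""
    if total_cfu <= 0:
        raise ValidationError("total_cfu must be positive")
    return total_pfu / total_cfu
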