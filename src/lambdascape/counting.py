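"""UMI-consensus genotype calling and tabulation over the 512 library alleles.

Sequencing errors are corrected by collapsing all reads sharing a unique
molecular barcode (UMI) into a consensus: a barcode must be observed by at
least ``min_reads`` independent reads (default 3), the consensus base at
every position is the strict-majority base across those reads, and any
position without a strict majority discards the barcode as ambiguous.
Consensus sequences carrying any substitution outside the nine programmed
sites are tallied as off-target and excluded, so counts cover only the
programmed 512 mutation combinations.

Every UMI ends up in exactly one bucket -- a genotype count or one of the
discard tallies (``too_few_reads``, ``ambiguous_consensus``,
``off_target_genotype``) -- so kept + discarded always equals the number of
distinct barcodes observed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .core import (
    N_GENOTYPES,
    N_SITES,
    MutationSite,
    ValidationError,
    genotype_from_index,
    validate_sites,
)
from .synthetic import DEFAULT_SITES, REFERENCE_AMPLICON, ReadArrays, ReadRecord

# per-UMI call codes (negative = discarded)
TOO_FEW_READS = -1
AMBIGUOUS_CONSENSUS = -2
OFF_TARGET_GENOTYPE = -3


@dataclass
class GenotypeCounts:
    """Unique-barcode counts per genotype for one sample/time point."""

    sample_id: str
    timepoint: str
    counts: np.ndarray = field(
        default_factory=lambda: np.zeros(N_GENOTYPES, dtype=np.int64)
    )
    discarded: dict[str, int] = field(
        default_factory=lambda: {
            "too_few_reads": 0,
            "ambiguous_consensus": 0,
            "off_target_genotype": 0,
        }
    )

    @property
    def total_umis(self) -> int:
        return int(self.counts.sum()) + sum(self.discarded.values())


def consensus_by_umi(arrays: ReadArrays, min_reads: int = 3) -> np.ndarray:
    """Per-UMI genotype call (index 0..511) or a negative discard code.

    Implements the consensus rules described in the module docstring on the
    compact array representation; fully vectorised so millions of barcodes
    are called in seconds.
    """
    if min_reads < 1:
        raise ValidationError("min_reads must be >= 1")
    k = np.asarray(arrays.umi_reads)
    if (k < 1).any():
        raise ValidationError("every UMI must have at least one read")
    n_umis = len(k)
    if n_umis == 0:
        return np.empty(0, dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(k)[:-1]])

    calls = np.empty(n_umis, dtype=np.int64)
    too_few = k < min_reads
    calls[too_few] = TOO_FEW_READS

    # base-code counts per UMI per programmed site
    codes = arrays.site_codes
    per_code = np.stack(
        [
            np.add.reduceat((codes == c).astype(np.int32), offsets, axis=0)
            for c in range(4)
        ]
    )  # (4, n_umis, 9)
    maxc = per_code.max(axis=0)
    strict = 2 * maxc > k[:, None]  # strict majority exists at the site
    consensus_code = per_code.argmax(axis=0)  # valid where strict

    ambiguous = ~strict.all(axis=1)
    off_target = (strict & (consensus_code >= 2)).any(axis=1)

    # off-site events: consensus at a position is non-reference iff one
    # error base reaches a strict majority of the UMI's reads; positions
    # where neither the reference nor any error base has a strict majority
    # make the whole consensus ambiguous.
    if len(arrays.off_read) > 0:
        read_umi = np.repeat(np.arange(n_umis), k)
        ev_umi = read_umi[arrays.off_read]
        length = arrays.amplicon_length
        key3 = (ev_umi * length + arrays.off_pos) * 3 + arrays.off_base
        uniq3, c3 = np.unique(key3, return_counts=True)
        key2 = uniq3 // 3
        uniq2, inv2 = np.unique(key2, return_inverse=True)
        m = np.zeros(len(uniq2), dtype=np.int64)  # total error reads per (umi,pos)
        np.add.at(m, inv2, c3)
        best = np.zeros(len(uniq2), dtype=np.int64)  # largest single-base count
        np.maximum.at(best, inv2, c3)
        pos_umi = uniq2 // length
        kk = k[pos_umi]
        ref_majority = 2 * (kk - m) > kk
        err_majority = 2 * best > kk
        off_target_pos = err_majority
        ambiguous_pos = ~ref_majority & ~err_majority
        off_target[pos_umi[off_target_pos]] = True
        ambiguous[pos_umi[ambiguous_pos]] = True

    # ambiguity takes precedence over off-target (no callable consensus)
    keep = ~too_few
    calls[keep & ambiguous] = AMBIGUOUS_CONSENSUS
    calls[keep & ~ambiguous & off_target] = OFF_TARGET_GENOTYPE

    ok = keep & ~ambiguous & ~off_target
    bits = (consensus_code == 1).astype(np.int64)
    genotype = bits @ (1 << np.arange(N_SITES, dtype=np.int64))
    calls[ok] = genotype[ok]
    return calls


def count_genotypes(
    calls: np.ndarray, sample_id: str = "", timepoint: str = ""
) -> GenotypeCounts:
    """Tabulate per-UMI calls into genotype counts and discard tallies."""
    calls = np.asarray(calls)
    counts = np.bincount(calls[calls >= 0], minlength=N_GENOTYPES).astype(np.int64)
    discarded = {
        "too_few_reads": int((calls == TOO_FEW_READS).sum()),
        "ambiguous_consensus": int((calls == AMBIGUOUS_CONSENSUS).sum()),
        "off_target_genotype": int((calls == OFF_TARGET_GENOTYPE).sum()),
    }
    return GenotypeCounts(sample_id, timepoint, counts, discarded)


def count_sample(
    arrays: ReadArrays,
    min_reads: int = 3,
    sample_id: str = "",
    timepoint: str = "",
) -> GenotypeCounts:
    return count_genotypes(consensus_by_umi(arrays, min_reads), sample_id, timepoint)


# ---------------------------------------------------------------------------
# FASTQ ingestion
# ---------------------------------------------------------------------------


def parse_fastq(path: str | Path) -> list[ReadRecord]:
    """Read amplicon records; the UMI is parsed from the ``UMI:`` name tag."""
    records = []
    with pysam.FastxFile(str(path)) as handle:
        for entry in handle:
            name = entry.name
            if "UMI:" not in name:
                raise ValidationError(f"read {name!r} has no UMI: tag in its name")
            umi = name.rsplit("UMI:", 1)[1]
            if not 5 <= len(umi) <= 12:
                raise ValidationError(f"UMI {umi!r} length outside 5..12")
            records.append(ReadRecord(name=name, umi=umi, sequence=entry.sequence))
    return records


def records_to_arrays(
    records: Sequence[ReadRecord],
    sites: Sequence[MutationSite] = DEFAULT_SITES,
    reference: str = REFERENCE_AMPLICON,
) -> ReadArrays:
    """Convert full reads to the array representation by positional comparison.

    Reads are assumed positionally aligned to the reference amplicon
    (substitution-only error model); a read of a different length is an
    input error.
    """
    sites = validate_sites(sites)
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    length = len(reference)
    site_pos = np.array([s.nucleotide_position - 1 for s in sites])

    order: dict[str, int] = {}
    for rec in records:
        if len(rec.sequence) != length:
            raise ValidationError(
                f"read {rec.name!r} length {len(rec.sequence)} != reference {length}"
            )
        order.setdefault(rec.umi, len(order))
    n_umis = len(order)
    groups: list[list[ReadRecord]] = [[] for _ in range(n_umis)]
    for rec in records:
        groups[order[rec.umi]].append(rec)

    umi_reads = np.array([len(g) for g in groups], dtype=np.int64)
    seqs = np.frombuffer(
        "".join(r.sequence for g in groups for r in g).encode(), dtype=np.uint8
    ).reshape(-1, length)

    # site codes: 0 ref, 1 alt, 2/3 the remaining two bases (fixed per site)
    codes = np.empty((len(seqs), N_SITES), dtype=np.uint8)
    for s, site in enumerate(sites):
        base = seqs[:, site_pos[s]]
        ref_b = ord(site.ref_allele.upper())
        alt_b = ord(site.alt_allele.upper())
        others = [b for b in b"ACGT" if b not in (ref_b, alt_b)]
        codes[:, s] = 0
        codes[base == alt_b, s] = 1
        codes[base == others[0], s] = 2
        codes[base == others[1], s] = 3

    mismatch = seqs != ref[None, :]
    mismatch[:, site_pos] = False
    off_read, off_pos = np.nonzero(mismatch)
    # off_base: index of the observed base among the three non-reference bases
    off_base = np.empty(len(off_read), dtype=np.uint8)
    for i, (r, p) in enumerate(zip(off_read, off_pos)):
        others = [b for b in b"ACGT" if b != ref[p]]
        observed = seqs[r, p]
        off_base[i] = others.index(observed) if observed in others else 0

    return ReadArrays(
        umi_reads=umi_reads,
        site_codes=codes,
        off_read=off_read.astype(np.int64),
        off_pos=off_pos.astype(np.int64),
        off_base=off_base,
        amplicon_length=length,
    )


def count_fastq(
    fastq_t0: str | Path,
    fastq_t4: str | Path,
    sites: Sequence[MutationSite] = DEFAULT_SITES,
    reference: str = REFERENCE_AMPLICON,
    min_reads: int = 3,
    sample_id: str = "",
) -> tuple[GenotypeCounts, GenotypeCounts]:
    """End-to-end FASTQ -> genotype counts for a paired t0/t4 sample."""
    out = []
    for path, timepoint in ((fastq_t0, "t0"), (fastq_t4, "t4")):
        arrays = records_to_arrays(parse_fastq(path), sites, reference)
        out.append(count_sample(arrays, min_reads, sample_id, timepoint))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_counts(gc: GenotypeCounts, path: str | Path) -> None:
    lines = [
        f"#sample={gc.sample_id}",
        f"#timepoint={gc.timepoint}",
        "genotype\tumi_count",
    ]
    for i, c in enumerate(gc.counts):
        lines.append(f"{genotype_from_index(i)}\t{int(c)}")
    Path(path).write_text("\n".join(lines) + "\n")
    summary = dict(gc.discarded)
    summary["kept"] = int(gc.counts.sum())
    summary["total_umis"] = gc.total_umis
    Path(str(path) + ".summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )


def read_counts(path: str | Path) -> GenotypeCounts:
    from .core import genotype_index

    meta: dict[str, str] = {}
    counts = np.zeros(N_GENOTYPES, dtype=np.int64)
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line == "genotype\tumi_count":
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
                continue
            key, c = line.split("\t")
            counts[genotype_index(key)] = int(c)
    discarded = {"too_few_reads": 0, "ambiguous_consensus": 0, "off_target_genotype": 0}
    summary_path = Path(str(path) + ".summary.json")
    if summary_path.exists():
        loaded = json.loads(summary_path.read_text())
        for key in discarded:
            discarded[key] = int(loaded.get(key, 0))
    return GenotypeCounts(meta.get("sample", ""), meta.get("timepoint", ""), counts, discarded)
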